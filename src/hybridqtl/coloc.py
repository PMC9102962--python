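"""DEG identification and colocalization with significant SNPs.

Differential expression between a hybrid and each parent is tested per
gene by a pooled-variance two-sample t-test on log2(expression + 1)
with Benjamini-Hochberg adjustment (groups have equal, small replicate
numbers and a shared noise model, where pooling the variance keeps the
full 2(n-1) degrees of freedom); genes below FDR 0.05 against BOTH
parents are the common DEGs.  A common DEG whose annotated position
lies within 20 Mb (inclusive) of any significant SNP for a trait is a
candidate gene for that trait, and candidates found in a reference
trait-gene catalog are prioritized first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW = 20_000_000
DEFAULT_FDR = 0.05


def de_test(
    expr: pd.DataFrame, group_a: str, group_b: str, fdr: float = DEFAULT_FDR
) -> pd.DataFrame:
    """Per-gene differential expression between two replicate groups.

    ``expr`` is a tidy table with columns gene/chrom/pos plus sample
    columns named ``{group}_{replicate}``.  Pooled-variance t on
    log2(x + 1), BH-adjusted; a gene with zero variance and equal means
    in both groups gets p = 1.
    """
    cols_a = [c for c in expr.columns if c.startswith(f"{group_a}_")]
    cols_b = [c for c in expr.columns if c.startswith(f"{group_b}_")]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two replicates per group")
    A = np.log2(expr[cols_a].to_numpy(dtype=float) + 1.0)
    B = np.log2(expr[cols_b].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_ind(A, B, axis=1, equal_var=True)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    degenerate = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    # zero variance but different means: infinitely strong evidence
    p = np.where(degenerate & (mean_a != mean_b), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = expr[["gene", "chrom", "pos"]].copy()
    out["log2_fc"] = mean_a - mean_b
    out["p_value"] = p
    out["fdr"] = p_adj
    out["deg"] = p_adj < fdr
    out["direction"] = np.sign(out["log2_fc"]).astype(int)
    return out


def common_degs(degs_vs_parent1: pd.DataFrame, degs_vs_parent2: pd.DataFrame) -> pd.DataFrame:
    """Genes differentially expressed against BOTH parents."""
    d1 = degs_vs_parent1[degs_vs_parent1["deg"]]
    d2 = degs_vs_parent2[degs_vs_parent2["deg"]]
    shared = set(d1["gene"]) & set(d2["gene"])
    out = d1[d1["gene"].isin(shared)].copy()
    out = out.merge(
        d2[["gene", "log2_fc", "fdr"]], on="gene", suffixes=("_p1", "_p2")
    )
    return out.reset_index(drop=True)


def colocalize(
    degs: pd.DataFrame, scan: pd.DataFrame, window: int = DEFAULT_WINDOW,
    trait: str = "",
) -> pd.DataFrame:
    """Candidate genes: DEGs within ``window`` bp (inclusive) of a
    significant SNP; distance is the minimum over significant SNPs on
    the gene's chromosome."""
    known_chroms = set(scan["chrom"].dropna())
    unknown = set(degs["chrom"]) - known_chroms
    if unknown:
        raise ValueError(
            f"DEG chromosome labels absent from the scan map: {sorted(unknown)[:5]}"
        )
    sig = scan[scan["significant"]].reset_index(drop=True)
    rows = []
    for _, gene in degs.iterrows():
        on_chrom = sig[sig["chrom"] == gene["chrom"]]
        if on_chrom.empty:
            continue
        dist = (on_chrom["pos"] - gene["pos"]).abs()
        j = dist.idxmin()
        if dist[j] <= window:
            rows.append({
                "gene": gene["gene"], "chrom": gene["chrom"],
                "pos": int(gene["pos"]),
                "nearest_snp": on_chrom.at[j, "marker"],
                "distance": int(dist[j]), "trait": trait,
            })
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "pos", "nearest_snp", "distance", "trait"]
    )


def prioritize(
    candidates: pd.DataFrame, reference_genes: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Flag candidates present in the trait's reference gene catalog and
    sort flagged-first, then by distance to the nearest significant SNP.

    ``reference_genes`` has columns ``trait`` and ``gene``.
    """
    ref = reference_genes[reference_genes["trait"] == trait]["gene"]
    if ref.empty:
        warnings.warn(f"reference gene list empty for trait {trait!r}", stacklevel=2)
    out = candidates.copy()
    out["in_reference"] = out["gene"].isin(set(ref))
    out = out.sort_values(
        ["in_reference", "distance"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
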