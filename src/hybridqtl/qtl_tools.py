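"""QTL-level summaries of association scans.

Significant SNPs within 20 Mb of each other on the same chromosome are
taken to tag one QTL (single-linkage chaining with an inclusive gap
rule).  QTL from different populations are "common" when their
intervals lie on the same chromosome and overlap or fall within the
same 20-Mb window.  Favorable-genotype accumulation counts, per
individual, the significant markers at which it carries the genotype
class with the highest predicted value a*Z + d*W.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .genotype_qc import GenotypeMatrix
from .mta import compute_pve, encode_marker

DEFAULT_WINDOW = 20_000_000  # bp; "SNPs within 20 Mb tag one QTL"


def merge_significant_snps(
    scan: pd.DataFrame, window: int = DEFAULT_WINDOW, population: str = "",
    trait: str = "",
) -> pd.DataFrame:
    """Cluster significant SNPs into QTL intervals per chromosome.

    Consecutive significant SNPs join one QTL while the gap to the
    previous member is <= ``window`` (inclusive); the interval spans the
    member positions and the peak is the highest-scoring member.
    """
    if "significant" not in scan.columns:
        raise ValueError("scan has no significance flags")
    sig = scan[scan["significant"]].sort_values(["chrom", "pos"])
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        cluster = []
        for _, snp in grp.iterrows():
            if cluster and snp["pos"] - cluster[-1]["pos"] > window:
                rows.append(_close_cluster(cluster, chrom, population, trait))
                cluster = []
            cluster.append(snp)
        if cluster:
            rows.append(_close_cluster(cluster, chrom, population, trait))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "peak_marker", "peak_score",
                 "n_snps", "members", "trait", "population"],
    )


def _close_cluster(cluster, chrom, population, trait):
    sub = pd.DataFrame(cluster)
    peak = sub.loc[sub["score"].idxmax()]
    return {
        "chrom": chrom,
        "start": int(sub["pos"].min()),
        "end": int(sub["pos"].max()),
        "peak_marker": peak["marker"],
        "peak_score": float(peak["score"]),
        "n_snps": len(sub),
        "members": list(sub["marker"]),
        "trait": trait,
        "population": population,
    }


def find_common_qtl(
    qtl_sets: dict, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """QTL shared between populations.

    ``qtl_sets`` maps population label -> QTL interval frame.  Two QTL
    are common when on the same chromosome and their intervals overlap
    or are separated by at most ``window``.  One output row per
    cross-population pair, with the populations involved.
    """
    if len(qtl_sets) < 2:
        raise ValueError("need QTL sets from at least two populations")
    rows = []
    for (pop1, q1), (pop2, q2) in combinations(qtl_sets.items(), 2):
        for _, a in q1.iterrows():
            for _, b in q2.iterrows():
                if a["chrom"] != b["chrom"]:
                    continue
                gap = max(a["start"], b["start"]) - min(a["end"], b["end"])
                if gap <= window:
                    rows.append({
                        "chrom": a["chrom"],
                        "pop1": pop1, "start1": a["start"], "end1": a["end"],
                        "pop2": pop2, "start2": b["start"], "end2": b["end"],
                        "gap": max(int(gap), 0),
                    })
    return pd.DataFrame(
        rows,
        columns=["chrom", "pop1", "start1", "end1", "pop2", "start2", "end2",
                 "gap"],
    )


def favorable_genotype_scores(
    geno: GenotypeMatrix, scan: pd.DataFrame, blues: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Count favorable genotype classes per individual and correlate with
    the phenotype.

    The favorable class at a significant marker is the observed code
    whose predicted genotypic value a*Z + d*W is maximal (dominance can
    favor heterozygotes).  Returns the per-individual table and the
    Pearson correlation between count and BLUE.
    """
    sig = scan[scan["significant"]]
    if sig.empty:
        raise ValueError("no significant markers in scan")
    counts = pd.Series(0, index=geno.codes.index, dtype=int)
    for _, row in sig.iterrows():
        codes = geno.codes[row["marker"]].to_numpy(dtype=float)
        classes = np.unique(codes[~np.isnan(codes)])
        z, w = encode_marker(classes)
        value = row["a"] * z + row["d"] * w
        favorable = classes[np.argmax(value)]
        counts += (geno.codes[row["marker"]] == favorable).astype(int)
    pheno = blues.reindex(counts.index)
    if counts.std() > 0 and pheno.std() > 0:
        r = float(np.corrcoef(counts, pheno)[0, 1])
    else:
        r = 0.0
    table = pd.DataFrame({
        "individual": counts.index,
        "favorable_count": counts.to_numpy(),
        "phenotype": pheno.to_numpy(),
    })
    return table, r


def cross_population_pve(
    lps_sig: pd.DataFrame, tc_geno: GenotypeMatrix, tc_blues: pd.Series
) -> pd.DataFrame:
    """PVE in a testcross population of markers found significant in the
    line-per-se population (same sequential-SS decomposition)."""
    missing = [m for m in lps_sig["marker"] if m not in tc_geno.codes.columns]
    if missing:
        raise ValueError(f"markers absent from testcross matrix: {missing[:5]}")
    return compute_pve(tc_geno, tc_blues, lps_sig)
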