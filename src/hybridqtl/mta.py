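"""Marker-trait association for hybrid-containing populations.

Each marker's genotype code c in [0, 2] is split into an additive
indicator Z = c - 1 and a dominance indicator W = 1 - |c - 1|; for the
integer codes this is the classical A -> (+1, 0), H -> (0, 1),
B -> (-1, 0) encoding, and for fractional testcross codes it equals the
expectation of (Z, W) over the Mendelian progeny classes.

The scan uses a polygenic background: variance components for additive
and dominance kinship kernels (optionally the four pairwise epistatic
kernels as Hadamard products) are estimated once by REML under the
global null, and every marker is then tested by generalized least
squares against that fixed background covariance — the standard
"population parameters previously determined" approximation.  The
per-marker statistic is a likelihood-ratio test (overall residual scale
re-profiled per model) referred to chi-square with as many degrees of
freedom as the marker contributes estimable effect columns; the score
is -log10(p) and the genome-wide threshold is -log10(0.05 / m) for m
markers (Bonferroni on the -log10 scale).

Phenotypic variance explained (PVE) by the significant markers comes
from one joint linear model: sequential (Type-I) sums of squares per
marker, in descending-score order, divided by the total sum of squares
of the response about its mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from ._reml import MixedFit, reml_kernels
from .genotype_qc import GenotypeMatrix

BACKGROUND_SETS = {
    "ad": ("additive", "dominance"),
    "ad+epi": ("additive", "dominance", "aa", "ad", "da", "dd"),
}


def encode_marker(codes) -> tuple[np.ndarray, np.ndarray]:
    """Additive/dominance indicators (Z, W) for one marker's codes."""
    c = np.asarray(codes, dtype=float)
    if np.nanmin(c) < 0 or np.nanmax(c) > 2:
        raise ValueError("genotype codes must lie in [0, 2]")
    z = c - 1.0
    w = 1.0 - np.abs(z)
    return z, w


def encoding_matrices(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Stacked Z and W matrices (individuals x markers)."""
    z, w = encode_marker(geno.codes.to_numpy(dtype=float))
    return z, w


def build_kernels(geno: GenotypeMatrix) -> dict:
    """Background kinship kernels from the Z/W encodings.

    additive = Z Z' / m, dominance = W W' / m; the epistatic kernels are
    Hadamard products of the first-order ones (aa, ad, da, dd).  ``ad``
    and ``da`` coincide by commutativity and are kept as two names for
    interface symmetry.
    """
    if geno.n_markers < 2:
        raise ValueError("need at least two markers to build kernels")
    Z, W = encoding_matrices(geno)
    m = Z.shape[1]
    Ka = Z @ Z.T / m
    Kd = W @ W.T / m
    kernels = {
        "additive": Ka,
        "dominance": Kd,
        "aa": Ka * Ka,
        "ad": Ka * Kd,
        "da": Kd * Ka,
        "dd": Kd * Kd,
    }
    for name in ("additive", "dominance"):
        if np.allclose(kernels[name], kernels[name][0, 0]):
            warnings.warn(f"{name} kernel is degenerate (rank 0)", stacklevel=2)
    return kernels


def fit_null(y, kernels: dict, background: str = "ad") -> MixedFit:
    """REML variance components of the polygenic null model.

    ``background`` selects the kernel set: "ad" (additive + dominance,
    the default) or "ad+epi" (plus the four epistatic kernels).  The fit
    carries the full covariance matrix used by the scan.
    """
    if background not in BACKGROUND_SETS:
        raise ValueError(f"background must be one of {sorted(BACKGROUND_SETS)}")
    y = np.asarray(y, dtype=float)
    names = [n for n in BACKGROUND_SETS[background] if n in kernels]
    terms = [(n, kernels[n]) for n in names]
    # drop the duplicate da kernel (identical to ad) to keep V identifiable
    terms = [t for t in terms if t[0] != "da"]
    X = np.ones((y.shape[0], 1))
    fit = reml_kernels(y, X, terms)
    if not fit.converged:
        raise RuntimeError(
            f"null model REML did not converge (deviance {fit.reml_deviance:.4g}, "
            f"variances {fit.variances})"
        )
    return fit


def significance_threshold(m: int) -> float:
    """Genome-wide -log10(p) threshold: -log10(0.05 / m) for m markers."""
    if m < 1:
        raise ValueError("marker count must be >= 1")
    return float(-np.log10(0.05 / m))


def _marker_design(z: np.ndarray, w: np.ndarray):
    """Estimable effect columns for one marker.

    Returns (columns, has_a, has_d): Z is kept when non-constant, W when
    non-constant and not collinear with Z after centering (in a
    tester-0 testcross W = Z + 1 exactly, leaving one testable df).
    """
    cols, has_a, has_d = [], False, False
    if np.ptp(z) > 0:
        cols.append(z)
        has_a = True
    if np.ptp(w) > 0:
        if has_a:
            zc = z - z.mean()
            wc = w - w.mean()
            if abs(zc @ wc) < (1 - 1e-10) * np.linalg.norm(zc) * np.linalg.norm(wc):
                cols.append(w)
                has_d = True
        else:
            cols.append(w)
            has_d = True
    return cols, has_a, has_d


def scan_markers(
    geno: GenotypeMatrix,
    y: pd.Series,
    null_fit: MixedFit,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-marker GLS likelihood-ratio scan against the polygenic null.

    Returns a frame with marker, chrom, pos, a, d, df, score
    (-log10 p), the threshold used and a significance flag.  Markers
    with no estimable effect column (constant Z and W) get score 0 and
    ``testable = False``.
    """
    y = y.reindex(geno.codes.index)
    if y.isna().any():
        raise ValueError("phenotype missing for some genotyped individuals")
    yv = y.to_numpy(dtype=float)
    n = yv.shape[0]
    V = getattr(null_fit, "covariance", None)
    if V is None:
        V = null_fit.variances["residual"] * np.eye(n)
    L = np.linalg.cholesky(V)
    yt = scipy.linalg.solve_triangular(L, yv, lower=True)
    ones = scipy.linalg.solve_triangular(L, np.ones(n), lower=True)
    # null: intercept only
    b0 = (ones @ yt) / (ones @ ones)
    rss0 = float(np.sum((yt - ones * b0) ** 2))

    if threshold is None:
        threshold = significance_threshold(geno.n_markers)

    Z, W = encoding_matrices(geno)
    Linv = scipy.linalg.solve_triangular(L, np.eye(n), lower=True)
    Zt = Linv @ Z
    Wt = Linv @ W

    mm = geno.marker_map
    rows = []
    for j, marker in enumerate(geno.codes.columns):
        cols, has_a, has_d = _marker_design(Z[:, j], W[:, j])
        chrom = mm.at[marker, "chrom"] if marker in mm.index else None
        pos = int(mm.at[marker, "pos"]) if marker in mm.index else -1
        if not cols:
            rows.append((marker, chrom, pos, 0.0, 0.0, 0, 0.0, False, False))
            continue
        design = [ones]
        if has_a:
            design.append(Zt[:, j])
        if has_d:
            design.append(Wt[:, j])
        Xm = np.column_stack(design)
        beta, res, rank, _ = np.linalg.lstsq(Xm, yt, rcond=None)
        rss1 = float(res[0]) if res.size else float(np.sum((yt - Xm @ beta) ** 2))
        df = rank - 1
        if df <= 0 or rss1 <= 0:
            score, a, d = 0.0, 0.0, 0.0
        else:
            lrt = n * np.log(rss0 / rss1)
            p = scipy.stats.chi2.sf(max(lrt, 0.0), df)
            score = float(-np.log10(max(p, 1e-300)))
            a = float(beta[1]) if has_a else 0.0
            d = float(beta[2] if has_a else beta[1]) if has_d else 0.0
        rows.append(
            (marker, chrom, pos, a, d, int(df), score, score > threshold, True)
        )
    scan = pd.DataFrame(
        rows,
        columns=["marker", "chrom", "pos", "a", "d", "df", "score",
                 "significant", "testable"],
    )
    scan.attrs["threshold"] = float(threshold)
    scan["threshold"] = float(threshold)
    return scan


def compute_pve(
    geno: GenotypeMatrix, y: pd.Series, sig: pd.DataFrame
) -> pd.DataFrame:
    """Sequential (Type-I) PVE of significant markers from one joint model.

    ``sig`` is a scan-result frame (or subset) whose rows are the
    markers to fit; they are entered in descending score order (ties by
    chromosome then position), each contributing its Z column plus W
    when non-constant.  PVE_k = SSreg_k / SStol with SStol the total sum
    of squares of y about its mean; collinear later markers pick up ~0.
    """
    if sig.empty:
        raise ValueError("no significant markers supplied")
    y = y.reindex(geno.codes.index)
    yv = y.to_numpy(dtype=float)
    sstol = float(np.sum((yv - yv.mean()) ** 2))
    if sstol == 0:
        raise ValueError("response has zero variance")
    order = sig.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True]
    )["marker"].tolist()
    n = yv.shape[0]
    X = np.ones((n, 1))
    prev_ssres = sstol
    rows = []
    for marker in order:
        if marker not in geno.codes.columns:
            raise ValueError(f"marker {marker!r} absent from genotype matrix")
        z, w = encode_marker(geno.codes[marker].to_numpy(dtype=float))
        new_cols = [z]
        if np.ptp(w) > 0:
            new_cols.append(w)
        X = np.column_stack([X] + new_cols)
        beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
        ssres = float(np.sum((yv - X @ beta) ** 2))
        ssreg = max(prev_ssres - ssres, 0.0)
        prev_ssres = ssres
        rows.append({"marker": marker, "ss_reg": ssreg, "ss_tol": sstol,
                     "pve": ssreg / sstol})
    out = pd.DataFrame(rows)
    out.attrs["total_pve"] = float(out["pve"].sum())
    out.attrs["ss_tol"] = sstol
    return out
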