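"""Genotype quality control, encoding, imputation and testcross deduction.

Genotypes are numeric codes on a 0..2 dosage scale: in a line population
the minor-allele homozygote is 2, the major homozygote 0 and the
heterozygote 1.  Testcross progeny of a partially heterozygous parent
and a homozygous tester get *fractional* codes — the expectation of the
progeny dosage over Mendelian segregation — so a tester carrying the
0-allele maps parent codes {0,1,2} to {0, 0.5, 1} and a tester carrying
the 2-allele maps them to {1, 1.5, 2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: every genotype code that can legally appear in a matrix
ALLOWED_CODES = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class GenotypeMatrix:
    """Individuals-by-markers code matrix plus a physical marker map.

    ``codes``: DataFrame, index = individual ids, columns = marker ids,
    values in {0, 0.5, 1, 1.5, 2} or NaN for missing.
    ``marker_map``: DataFrame indexed by marker id with columns
    ``chrom`` (label) and ``pos`` (1-based bp).
    """

    codes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self):
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals)
        for c in ALLOWED_CODES:
            ok |= vals == c
        if not ok.all():
            bad = sorted(set(np.round(vals[~ok], 6).ravel()))
            raise ValueError(f"genotype codes outside {ALLOWED_CODES}: {bad[:5]}")
        if "chrom" not in self.marker_map or "pos" not in self.marker_map:
            raise ValueError("marker_map needs 'chrom' and 'pos' columns")
        known = self.codes.columns.isin(self.marker_map.index)
        # markers missing from the map are tolerated here; filter_snps
        # removes them as "no physical position"
        mapped = self.marker_map.loc[self.codes.columns[known]]
        for chrom, grp in mapped.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if (mapped["pos"] < 1).any():
            raise ValueError("physical positions must be >= 1 (1-based)")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        keep = [m for m in self.codes.columns if m in set(marker_ids)]
        return GenotypeMatrix(
            self.codes[keep], self.marker_map.loc[self.marker_map.index.isin(keep)]
        )


@dataclass
class QcReport:
    """Per-step marker removal counts; removed + retained = input count."""

    n_input: int
    removed_call_rate: int = 0
    removed_no_position: int = 0
    removed_missing_rate: int = 0
    removed_maf: int = 0
    n_imputed_cells: int = 0
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_call_rate
            + self.removed_no_position
            + self.removed_missing_rate
            + self.removed_maf
        )

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "removed_call_rate": self.removed_call_rate,
            "removed_no_position": self.removed_no_position,
            "removed_missing_rate": self.removed_missing_rate,
            "removed_maf": self.removed_maf,
            "n_imputed_cells": self.n_imputed_cells,
            "retained": self.retained,
        }
        return d


def minor_allele_frequencies(geno: GenotypeMatrix) -> pd.Series:
    """Per-marker MAF from allele dosages (code/2; heterozygotes count half)."""
    p = geno.codes.mean(axis=0, skipna=True) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_snps(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.97,
    missing_max: float = 0.05,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the four marker filters in their stated order.

    1. call rate below ``call_rate_min`` (call rate = fraction non-missing);
    2. no physical position in the marker map;
    3. missing rate above ``missing_max``;
    4. minor allele frequency below ``maf_min``.

    The call-rate and missing-rate filters are partially redundant; both
    are applied sequentially as two separate steps by design.
    """
    for thr in (call_rate_min, missing_max, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    report = QcReport(n_input=geno.n_markers)
    codes = geno.codes

    call_rate = codes.notna().mean(axis=0)
    keep = call_rate[call_rate >= call_rate_min].index
    report.removed_call_rate = codes.shape[1] - len(keep)
    codes = codes[keep]

    has_pos = codes.columns.isin(
        geno.marker_map.index[geno.marker_map["pos"].notna()]
    )
    report.removed_no_position = int((~has_pos).sum())
    codes = codes.loc[:, has_pos]

    missing = codes.isna().mean(axis=0)
    keep = missing[missing <= missing_max].index
    report.removed_missing_rate = codes.shape[1] - len(keep)
    codes = codes[keep]

    p = codes.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf[maf >= maf_min].index
    report.removed_maf = codes.shape[1] - len(keep)
    codes = codes[keep]

    report.retained = codes.shape[1]
    if report.retained == 0:
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    out = GenotypeMatrix(
        codes, geno.marker_map.loc[geno.marker_map.index.isin(codes.columns)]
    )
    return out, report


def encode_genotypes(
    alleles: pd.DataFrame, marker_map: pd.DataFrame
) -> GenotypeMatrix:
    """Encode two-letter allele calls into dosage codes.

    ``alleles`` holds strings like ``"AA"``, ``"AG"`` (order irrelevant)
    or NaN.  The minor allele (population frequency < 0.5) homozygote is
    coded 2, the major homozygote 0, heterozygotes 1.  At an exact 50/50
    tie the lexicographically smaller allele is taken as major.
    """
    coded = {}
    for marker in alleles.columns:
        calls = alleles[marker]
        obs = calls.dropna()
        counts: dict[str, int] = {}
        for call in obs:
            for a in str(call):
                counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(
                f"marker {marker!r} has {len(counts)} alleles; biallelic required"
            )
        if not counts:
            coded[marker] = pd.Series(np.nan, index=alleles.index)
            continue
        # major = more frequent; tie -> lexicographically smaller label
        order = sorted(counts, key=lambda a: (-counts[a], a))
        major = order[0]
        col = pd.Series(np.nan, index=alleles.index, dtype=float)
        for idx, call in calls.items():
            if pd.isna(call):
                continue
            col[idx] = sum(a != major for a in str(call))
        coded[marker] = col
    codes = pd.DataFrame(coded, index=alleles.index)[alleles.columns]
    return GenotypeMatrix(codes, marker_map)


def _allowed_set(codes: pd.DataFrame) -> np.ndarray:
    vals = codes.to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0 or np.all(vals == np.round(vals)):
        return np.array([0.0, 1.0, 2.0])
    if vals.max() <= 1.0:
        return np.array([0.0, 0.5, 1.0])
    if vals.min() >= 1.0:
        return np.array([1.0, 1.5, 2.0])
    return np.array(ALLOWED_CODES)


def impute_missing(geno: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Fill missing cells with the per-marker mean code, rounded to the
    nearest legal code of the matrix (ties round down).

    Returns the imputed matrix and the number of cells filled.  A marker
    with every value missing is an error.
    """
    codes = geno.codes.copy()
    allowed = _allowed_set(codes)
    n_missing = int(codes.isna().sum().sum())
    if n_missing == 0:
        return GenotypeMatrix(codes, geno.marker_map), 0
    all_missing = codes.columns[codes.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"markers with all values missing: {list(all_missing)[:5]}")
    means = codes.mean(axis=0, skipna=True)
    imputed = allowed[
        np.argmin(np.abs(means.to_numpy()[:, None] - allowed[None, :]), axis=1)
    ]
    fill = pd.Series(imputed, index=codes.columns)
    codes = codes.fillna(fill)
    return GenotypeMatrix(codes, geno.marker_map), n_missing


def deduce_testcross_genotypes(
    parents: GenotypeMatrix, tester: pd.Series
) -> GenotypeMatrix:
    """Deduce testcross-progeny codes from parent codes and a homozygous tester.

    The deduced code is the Mendelian expectation of the progeny dosage:
    (parent code + tester code) / 2.  A tester carrying the 0-allele maps
    {0, 1, 2} to {0, 0.5, 1}; a tester carrying the 2-allele maps them to
    {1, 1.5, 2}.  Heterozygous tester loci (code 1) are rejected: the
    deduction rule is undefined there.
    """
    tester = tester.reindex(parents.codes.columns)
    if tester.isna().any():
        missing = list(tester.index[tester.isna()])[:5]
        raise ValueError(f"tester codes missing for markers: {missing}")
    bad = tester.index[~tester.isin([0.0, 2.0])]
    if len(bad):
        raise ValueError(
            f"tester must be homozygous (codes 0 or 2) at every marker; "
            f"offending markers: {list(bad)[:5]}"
        )
    deduced = (parents.codes + tester) / 2.0
    return GenotypeMatrix(deduced, parents.marker_map)


def snp_density(
    marker_map: pd.DataFrame, window: float | None = None
) -> pd.DataFrame:
    """Marker density (SNP/Mb) per chromosome and overall.

    Covered length per chromosome is its maximum marker position.  When
    ``window`` (bp) is given, a per-window marker count table is attached
    as the ``windows`` attribute of the result.
    """
    if marker_map.empty:
        raise ValueError("empty marker map")
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        mb = grp["pos"].max() / 1e6
        rows.append({"chrom": chrom, "n_snps": len(grp), "length_mb": mb,
                     "density": len(grp) / mb})
    per_chrom = pd.DataFrame(rows)
    overall = per_chrom["n_snps"].sum() / per_chrom["length_mb"].sum()
    out = pd.concat(
        [per_chrom, pd.DataFrame([{"chrom": "overall",
                                   "n_snps": per_chrom["n_snps"].sum(),
                                   "length_mb": per_chrom["length_mb"].sum(),
                                   "density": overall}])],
        ignore_index=True,
    )
    if window is not None:
        wrows = []
        for chrom, grp in marker_map.groupby("chrom", sort=False):
            edges = np.arange(0, grp["pos"].max() + window, window)
            counts, _ = np.histogram(grp["pos"], bins=edges)
            for i, c in enumerate(counts):
                wrows.append({"chrom": chrom, "start": int(edges[i]) + 1,
                              "end": int(edges[i + 1]), "n_snps": int(c)})
        out.attrs["windows"] = pd.DataFrame(wrows)
    return out
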