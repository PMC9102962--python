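"""Plain-text interchange formats.

Genotypes travel as TSV (rows = individuals, columns = marker ids,
codes as decimals, missing = "NA"); marker maps as TSV with 1-based
positions; phenotypes as long CSV; gene positions as BED (0-based,
half-open — converted to the internal 1-based convention on read);
QC reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .genotype_qc import GenotypeMatrix, QcReport


def write_genotypes(geno: GenotypeMatrix, geno_path, map_path) -> None:
    geno.codes.to_csv(geno_path, sep="\t", na_rep="NA", index_label="individual")
    mm = geno.marker_map.reset_index()
    mm.columns = ["marker", "chrom", "pos"]
    mm.to_csv(map_path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> GenotypeMatrix:
    codes = pd.read_csv(geno_path, sep="\t", index_col="individual", na_values="NA")
    codes.index.name = None
    mm = pd.read_csv(map_path, sep="\t").set_index("marker")
    return GenotypeMatrix(codes, mm)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_blues(blues: pd.Series, path) -> None:
    blues.rename("blue").to_csv(path, index_label="genotype")


def read_blues(path) -> pd.Series:
    df = pd.read_csv(path, index_col="genotype")
    return df["blue"]


def write_qc_report(report: QcReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_scan(scan: pd.DataFrame, path) -> None:
    scan.to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_positions_bed(genes: pd.DataFrame, path) -> None:
    """Gene point positions as BED: chrom, start (0-based), end, name."""
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["pos"].astype(int) - 1,
        "end": genes["pos"].astype(int),
        "name": genes["gene"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_positions_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    return pd.DataFrame({
        "gene": bed["name"],
        "chrom": bed["chrom"],
        "pos": bed["start"].astype(int) + 1,  # back to 1-based
    })


def write_qtl(qtl: pd.DataFrame, path) -> None:
    out = qtl.copy()
    if "members" in out:
        out["members"] = out["members"].map(lambda ms: ",".join(map(str, ms)))
    out.to_csv(path, sep="\t", index=False)
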