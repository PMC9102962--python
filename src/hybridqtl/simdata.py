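"""Synthetic BC1F3:4 breeding populations with known ground truth.

The generator emulates the study design end to end: two fully divergent
inbred founders (a donor crossed once into a recurrent parent), gene
dropping through F1 -> BC1 -> two selfing generations to the BC1F3 plant
that is genotyped, testcrosses of every family to homozygous testers,
planted QTL with additive and dominance effects, multi-environment
incomplete-block phenotype trials, and replicated hybrid/parent
expression profiles with planted differentially expressed genes.

Meiosis uses a Haldane (no-interference) crossover model: the crossover
count per chromosome is Poisson with mean equal to the chromosome map
length in Morgans (bp x cM/Mb / 1e8 at the configured recombination
density), with crossover positions uniform along the chromosome.

Mendelian expectations under this pedigree: donor-allele frequency
1/2 (F1) -> 1/4 (BC1, unchanged by selfing); heterozygosity 1/2 (BC1)
halved by each selfing -> 1/8 at BC1F3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix, deduce_testcross_genotypes

# approximate maize B73 chromosome lengths, Mb
_MAIZE_CHROM_MB = (301, 238, 232, 242, 218, 169, 177, 181, 157, 151)


@dataclass(frozen=True)
class Qtl:
    """A planted causal locus: marker position, additive effect ``a``
    (half the homozygote difference), dominance effect ``d`` and trait."""

    chrom: str
    pos: int
    a: float
    d: float = 0.0
    trait: str = "HKW"


@dataclass
class SimConfig:
    """Full generative specification of a simulated study.

    Defaults reproduce the real study's conditions: 481 BC1F3:4
    families, ten maize-scale chromosomes at ~7.5 SNP/Mb and 1 cM/Mb,
    four environments with two replicates of ten incomplete blocks, and
    variance components giving an entry-mean heritability of 0.8 for
    the kernel-weight-like default trait.
    """

    n_chromosomes: int = 10
    chrom_lengths_bp: tuple = tuple(int(mb * 1e6) for mb in _MAIZE_CHROM_MB)
    snps_per_chrom: tuple = tuple(int(round(mb * 7.5)) for mb in _MAIZE_CHROM_MB)
    cm_per_mb: float = 1.0
    n_families: int = 481
    qtl_spec: list = None
    # (sigma2_g, sigma2_gxe, sigma2_eps): genetic, GxE and plot-residual
    # variances.  sigma2_g scales the planted-QTL genetic values so the
    # realized genetic variance equals it.
    sigma2_g: float = 1.0
    sigma2_gxe: float = 0.5
    sigma2_eps: float = 1.0
    # nuisance strata variances (environment main effect, replicate in
    # environment, block in replicate)
    sigma2_env: float = 1.0
    sigma2_rep: float = 0.25
    sigma2_block: float = 0.25
    n_environments: int = 4
    n_replicates: int = 2
    n_blocks: int = 10
    mu: float = 30.0
    tester_genotypes: dict = None
    monomorphic_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if len(self.chrom_lengths_bp) != self.n_chromosomes:
            raise ValueError("chrom_lengths_bp length != n_chromosomes")
        if len(self.snps_per_chrom) != self.n_chromosomes:
            raise ValueError("snps_per_chrom length != n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        if any(m < 1 for m in self.snps_per_chrom):
            raise ValueError("each chromosome needs at least one SNP")
        if min(self.sigma2_g, self.sigma2_gxe, self.sigma2_eps) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_environments < 1 or self.n_replicates < 1:
            raise ValueError("need n_environments >= 1 and n_replicates >= 1")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.qtl_spec is None:
            self.qtl_spec = self._default_qtl()
        mm = self.marker_map()
        for q in self.qtl_spec:
            sel = mm[(mm["chrom"] == q.chrom) & (mm["pos"] == q.pos)]
            if sel.empty:
                raise ValueError(
                    f"QTL at {q.chrom}:{q.pos} does not coincide with a marker"
                )

    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def marker_positions(self) -> list:
        """Evenly spaced 1-based marker positions per chromosome."""
        out = []
        for L, m in zip(self.chrom_lengths_bp, self.snps_per_chrom):
            pos = np.round(np.linspace(1, L, m)).astype(np.int64)
            out.append(np.unique(pos))
        return out

    def marker_map(self) -> pd.DataFrame:
        rows = []
        for chrom, pos in zip(self.chrom_names(), self.marker_positions()):
            for i, p in enumerate(pos):
                rows.append((f"{chrom}_{p}", chrom, int(p)))
        mm = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
        return mm.set_index("marker")

    def _default_qtl(self) -> list:
        """Eight QTL of decaying effect on the first chromosomes, some with
        dominance — a sparse oligogenic architecture for the default trait."""
        a_vals = (1.0, 0.8, 0.8, 0.6, 0.6, 0.4, 0.4, 0.3)
        d_vals = (0.5, 0.0, 0.4, 0.0, 0.3, 0.0, 0.2, 0.0)
        qtl = []
        positions = self.marker_positions()
        names = self.chrom_names()
        for i in range(min(8, self.n_chromosomes)):
            pos = positions[i]
            qtl.append(
                Qtl(names[i], int(pos[len(pos) // 2]), a_vals[i], d_vals[i])
            )
        return qtl

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# founders and meiosis

def simulate_founders(config: SimConfig):
    """Two fully homozygous, fully divergent founder genomes.

    Haplotypes are per-chromosome 0/1 vectors (1 = donor allele); the
    donor founder carries all ones, the recurrent parent all zeros.
    A configured ``monomorphic_fraction`` of markers is made identical
    in both founders (donor allele forced to 0) for QC testing.
    """
    positions = config.marker_positions()
    donor = [np.ones(len(p), dtype=np.int8) for p in positions]
    recurrent = [np.zeros(len(p), dtype=np.int8) for p in positions]
    if config.monomorphic_fraction > 0:
        rng = np.random.default_rng(config.seed + 101)
        for hap in donor:
            mono = rng.random(hap.shape[0]) < config.monomorphic_fraction
            hap[mono] = 0
    return donor, recurrent


def simulate_gamete(parent, config: SimConfig, rng: np.random.Generator):
    """One recombinant gamete from a diploid parent (pair of haplotype
    lists), under the Haldane no-interference crossover model."""
    hap_a, hap_b = parent
    positions = config.marker_positions()
    gamete = []
    for chrom_idx, pos in enumerate(positions):
        length_bp = config.chrom_lengths_bp[chrom_idx]
        morgans = length_bp * config.cm_per_mb / 1e6 / 100.0
        n_cross = rng.poisson(morgans)
        start = rng.integers(2)
        if n_cross == 0:
            src = hap_a[chrom_idx] if start == 0 else hap_b[chrom_idx]
            gamete.append(src.copy())
            continue
        xovers = np.sort(rng.uniform(0, length_bp, size=n_cross))
        which = (start + np.searchsorted(xovers, pos)) % 2
        gamete.append(
            np.where(which == 0, hap_a[chrom_idx], hap_b[chrom_idx]).astype(np.int8)
        )
    return gamete


# ---------------------------------------------------------------------------
# population gene dropping

def simulate_bc1f3_population(config: SimConfig) -> GenotypeMatrix:
    """Gene-drop a BC1F3 line-per-se population.

    Pedigree per family: (donor x recurrent) F1, backcrossed once to the
    recurrent parent, then selfed twice; the single BC1F3 plant per
    family is genotyped.  Codes count donor alleles (recurrent
    homozygote = 0), which matches minor-allele=2 coding because the
    donor allele segregates at frequency 1/4.
    """
    rng = config.rng()
    donor, recurrent = simulate_founders(config)
    f1 = (donor, recurrent)
    names = config.chrom_names()
    positions = config.marker_positions()
    rows = np.empty((config.n_families, sum(len(p) for p in positions)), dtype=float)
    for fam in range(config.n_families):
        bc1 = (simulate_gamete(f1, config, rng), recurrent)
        bc1f2 = (
            simulate_gamete(bc1, config, rng),
            simulate_gamete(bc1, config, rng),
        )
        bc1f3 = (
            simulate_gamete(bc1f2, config, rng),
            simulate_gamete(bc1f2, config, rng),
        )
        rows[fam] = np.concatenate(
            [h1 + h2 for h1, h2 in zip(bc1f3[0], bc1f3[1])]
        )
    marker_ids = [
        f"{c}_{p}" for c, pos in zip(names, positions) for p in pos
    ]
    ids = [f"F{str(i + 1).zfill(4)}" for i in range(config.n_families)]
    codes = pd.DataFrame(rows, index=ids, columns=marker_ids)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes = codes.mask(mask)
    return GenotypeMatrix(codes, config.marker_map())


def default_testers(config: SimConfig) -> dict:
    """Two homozygous testers with allele codes drawn fairly per marker."""
    if config.tester_genotypes is not None:
        return config.tester_genotypes
    rng = np.random.default_rng(config.seed + 202)
    mm = config.marker_map()
    return {
        name: pd.Series(
            2.0 * rng.integers(0, 2, size=len(mm)), index=mm.index
        )
        for name in ("tester1", "tester2")
    }


def simulate_testcross(
    population: GenotypeMatrix, tester: pd.Series
) -> GenotypeMatrix:
    """Testcross genotype codes by the Mendelian deduction rule; the
    tester must be homozygous (codes in {0, 2}) at every marker."""
    return deduce_testcross_genotypes(population, tester)


# ---------------------------------------------------------------------------
# phenotypes

@dataclass
class PhenotypeSim:
    """Simulated trial records plus the generative truth behind them."""

    records: pd.DataFrame
    genetic_values: pd.Series
    realized: dict


def genetic_values(population: GenotypeMatrix, qtl_spec, trait: str = None) -> pd.Series:
    """Sum over QTL of a*(code-1) + d*(1-|code-1|), unscaled."""
    g = np.zeros(population.n_individuals)
    mm = population.marker_map
    for q in qtl_spec:
        if trait is not None and q.trait != trait:
            continue
        sel = mm[(mm["chrom"] == q.chrom) & (mm["pos"] == q.pos)]
        if sel.empty:
            raise ValueError(f"QTL at {q.chrom}:{q.pos} not on the marker map")
        code = population.codes[sel.index[0]].to_numpy(dtype=float)
        z = code - 1.0
        w = 1.0 - np.abs(z)
        g += q.a * z + q.d * w
    return pd.Series(g, index=population.codes.index)


def simulate_phenotypes(
    population: GenotypeMatrix, config: SimConfig, trait: str = "HKW"
) -> PhenotypeSim:
    """Plot-level multi-environment incomplete-block trial records.

    y = mu + g_i + tau_k + (g tau)_ik + delta_km + beta_mb + eps, with
    every non-genetic effect drawn from a zero-mean normal at its
    configured variance.  Genetic values come from the planted QTL and
    are rescaled so their population variance equals sigma2_g (when
    sigma2_g > 0 and the QTL segregate).
    """
    rng = np.random.default_rng(config.seed + 303)
    g = genetic_values(population, config.qtl_spec, trait)
    vg = float(g.var(ddof=0))
    if config.sigma2_g > 0 and vg > 0:
        g = g * np.sqrt(config.sigma2_g / vg)
    ids = list(population.codes.index)
    n_g = len(ids)
    n, r, nb = config.n_environments, config.n_replicates, config.n_blocks

    env_eff = rng.normal(0, np.sqrt(config.sigma2_env), n)
    gxe_eff = rng.normal(0, np.sqrt(config.sigma2_gxe), (n_g, n))
    rep_eff = rng.normal(0, np.sqrt(config.sigma2_rep), (n, r))
    blk_eff = rng.normal(0, np.sqrt(config.sigma2_block), (n, r, nb))

    rows = []
    gv = g.to_numpy()
    for k in range(n):
        env = f"E{k + 1}"
        for m in range(r):
            # incomplete blocks: genotypes shuffled into nb blocks per replicate
            order = rng.permutation(n_g)
            blocks = np.array_split(order, nb)
            for b, members in enumerate(blocks):
                for i in members:
                    eps = rng.normal(0, np.sqrt(config.sigma2_eps))
                    y = (
                        config.mu
                        + gv[i]
                        + env_eff[k]
                        + gxe_eff[i, k]
                        + rep_eff[k, m]
                        + blk_eff[k, m, b]
                        + eps
                    )
                    rows.append(
                        (ids[i], env, f"R{m + 1}", f"B{b + 1}", y, trait)
                    )
    records = pd.DataFrame(
        rows,
        columns=["genotype", "environment", "replicate", "block", "value", "trait"],
    )
    realized = {
        "sigma2_g": float(g.var(ddof=0)),
        "sigma2_gxe": config.sigma2_gxe,
        "sigma2_eps": config.sigma2_eps,
        "n_environments": n,
        "n_replicates": r,
    }
    return PhenotypeSim(records=records, genetic_values=g, realized=realized)


# ---------------------------------------------------------------------------
# expression profiles

@dataclass(frozen=True)
class DegSpec:
    """A planted differentially expressed gene.

    ``versus`` controls which parents the hybrid differs from: "both"
    (a true hybrid/parent DEG), or "parent1"/"parent2" (parent-specific
    shift, which must NOT survive the common-DEG intersection).
    """

    gene: str
    chrom: str
    pos: int
    fold_change: float = 4.0
    versus: str = "both"


def simulate_expression_profiles(
    config: SimConfig,
    planted_degs,
    n_genes: int = 200,
    baseline_mean: float = 50.0,
    cv: float = 0.10,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Replicated expression table for one hybrid and its two parents.

    Returns a tidy frame with gene/chrom/pos plus sample columns
    ``hybrid_1..n``, ``parent1_1..n``, ``parent2_1..n``.  Non-planted
    genes share one mean across groups; a planted gene's hybrid mean is
    ``fold_change`` times the corresponding parent mean(s).  Values are
    lognormal around the group mean at the given coefficient of
    variation (at least three replicates per group).
    """
    if n_reps < 3:
        raise ValueError("need at least three biological replicates")
    rng = np.random.default_rng(config.seed + 404)
    chroms = config.chrom_names()
    lengths = dict(zip(chroms, config.chrom_lengths_bp))
    planted = list(planted_degs)
    n_fill = n_genes - len(planted)
    if n_fill < 0:
        raise ValueError("n_genes smaller than the planted DEG list")
    genes = [(d.gene, d.chrom, d.pos) for d in planted]
    for j in range(n_fill):
        chrom = chroms[j % len(chroms)]
        pos = int(rng.integers(1, lengths[chrom]))
        genes.append((f"gene{j + 1:04d}", chrom, pos))

    sigma = np.sqrt(np.log1p(cv**2))
    groups = ("hybrid", "parent1", "parent2")
    data = {}
    base = baseline_mean * np.exp(rng.normal(0, 0.8, size=len(genes)))
    means = {grp: base.copy() for grp in groups}
    for i, d in enumerate(planted):
        if d.versus == "both":
            means["hybrid"][i] = base[i] * d.fold_change
        elif d.versus in ("parent1", "parent2"):
            means[d.versus][i] = base[i] * d.fold_change
        else:
            raise ValueError(f"unknown DegSpec.versus: {d.versus!r}")
    for grp in groups:
        for rep in range(n_reps):
            noise = np.exp(rng.normal(0, sigma, size=len(genes)) - sigma**2 / 2)
            data[f"{grp}_{rep + 1}"] = means[grp] * noise
    out = pd.DataFrame(genes, columns=["gene", "chrom", "pos"])
    for col, vals in data.items():
        out[col] = vals
    return out
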