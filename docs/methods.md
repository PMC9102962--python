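# Methods

This note records the models implemented in `hybridqtl`, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical decisions that shape the results.

## Populations and the simulator

The object of study is a maize line-per-se (LPS) population of BC1F3:4
families — donor crossed once into a recurrent parent, the BC1 selfed
twice, the BC1F3 plant genotyped and its selfed family phenotyped —
plus two testcross (TC) populations made by crossing every BC1F3 plant
to a common homozygous tester. Under this pedigree the donor allele
segregates at frequency 1/4 and heterozygosity is 1/8 (BC1 value 1/2
halved by each selfing); these closed-form expectations are the
simulator's primary correctness oracles.

`simdata` gene-drops each family independently. Meiosis follows a
Haldane no-interference model: crossovers per chromosome are Poisson
with mean equal to the map length in Morgans, positions uniform. The
map is physical-position driven at a configurable density (default
1 cM/Mb, a standard genome-wide average for maize); no interference,
mutation, or selection is modeled. Families are represented by the
genotype of the single BC1F3 plant — the generation that is actually
genotyped — and family-mean sampling noise of the F3:4 plots is folded
into the residual variance. Marker positions are evenly spaced along
each chromosome so that marker grids are reproducible across seeds.

Default `SimConfig` values mirror the study conditions: 481 families,
ten chromosomes at maize scale (~150–300 Mb) with ≈7.5 SNP/Mb
(≈15.4k markers), four environments × two replicates × ten incomplete
blocks, and variance components σ_g² = 1, σ_gτ² = 0.5, σ_ε² = 1, which
give an entry-mean H² of 0.8, matching the kernel-weight trait class.
Tests and the statistical checks run smaller configurations (tens of
markers, hundreds of families) chosen so each check's Monte-Carlo error
is well below its tolerance.

Planted-QTL genetic values are computed as Σ_q a_q·Z + d_q·W and then
rescaled so their realized population variance equals the configured
σ_g². This makes configured heritabilities exact generative truths
rather than approximations, which is what parameter-recovery tests
need. Nuisance strata (environment, replicate, block) have their own
configurable variances; with only a handful of levels their realized
single-draw variance is not individually recoverable, and tests treat
them accordingly.

The expression simulator draws per-gene baselines lognormally around a
configurable mean and multiplies planted differentially expressed
genes' hybrid (or single-parent) means by a fold change; replicate
noise is lognormal at a configured coefficient of variation (default
10%, three replicates). It emulates normalized abundance tables only —
no read counts, library-size effects, or length biases — so passing
tests demonstrate the colocalization logic, not RNA-seq inference on
real data.

## Genotype QC

Four marker filters run in a fixed order: call rate ≥ 97%, physical
position present, missing rate ≤ 5%, minor allele frequency ≥ 0.05.
The first and third are partially redundant; both are kept as separate
sequential steps so the removal accounting matches the stated
protocol. MAF uses allele dosages (code/2, heterozygotes counting
half) on the line-population matrix; fractional testcross codes never
enter QC because testcross genotypes are deduced *after* filtering.

Imputation is deliberately simple and deterministic: the per-marker
mean code rounded to the nearest legal code, where the legal set is
inferred from the matrix (integer {0,1,2}; tester-0 {0,0.5,1};
tester-2 {1,1.5,2}). Haplotype-aware imputation is out of scope —
imputation quality is not an endpoint of this pipeline.

Testcross deduction is the Mendelian expectation of the progeny
dosage, (parent + tester)/2: a tester carrying the 0 allele maps
parent codes {0,1,2} to {0, 0.5, 1}; a 2-allele tester maps them to
{1, 1.5, 2}. Heterozygous tester loci are rejected because the rule
is undefined there. At an exact 50/50 allele-frequency tie during
encoding, the lexicographically smaller allele is taken as major.
Coordinates are 1-based internally; BED output converts to 0-based
half-open at the boundary.

## Mixed models and REML

All variance components are estimated by REML with hand-rolled,
dependency-light machinery (two fitters in `_reml`):

- **Sparse variance-component models** (BLUEs, heritability): the
  profiled penalized-least-squares formulation over variance ratios
  γ_i = σ_i²/σ_ε². Each evaluation factorizes the sparse penalized
  normal-equations system once (its log-determinant equals the sum of
  the two determinant terms in the REML criterion); L-BFGS-B over
  log γ with a Nelder-Mead fallback. Ratios below 1e-6 are clamped to
  zero on exit (boundary REML).
- **Kernel models** (polygenic scan background): the residual scale is
  profiled out analytically and the criterion is optimized over kernel
  variance ratios; one Cholesky of V₀ = I + Σ γ_c K_c per evaluation.

For BLUEs, genotype enters as dummies without an intercept so the
estimates are directly μ + g_i; environment, G×E, replicate-in-
environment and block-in-replicate are random. Terms that collapse to
a single level, or whose partition duplicates another term's (e.g.
G×E in a single-environment design), are dropped before fitting.
Degenerate designs with no residual degrees of freedom fall back to
genotype means with a warning. The single-random-effect case is
cross-checked against statsmodels MixedLM in the test suite. BLUEs
are fitted jointly across environments (not per-environment first),
and the n in H² is the realized environment count of the records.

A note on attainable accuracy: with n environments and r replicates
the correlation between an entry mean and the true genetic value is
bounded by the entry-mean reliability, √(nrσ_g²/(nrσ_g² + nσ_gτ² +
σ_ε²)) — about 0.94 at n=4, r=2, σ_g²=σ_ε²=1, σ_gτ²=0. Recovery tests
assert against this ceiling rather than an arbitrary round number.

## Association scan

Markers are encoded as Z = c − 1 (additive) and W = 1 − |c − 1|
(dominance); for integer codes this is the classical (+1,0)/(0,1)/
(−1,0) scheme, and for fractional testcross codes it equals the
expectation of (Z, W) over the Mendelian progeny classes, so line and
testcross populations share one model. Background kernels are
K_a = ZZᵀ/m and K_d = WWᵀ/m; epistatic kernels are Hadamard products
(K_aa = K_a∘K_a, etc.). The default background is additive +
dominance; epistatic kernels sit behind the `background="ad+epi"`
flag because main effects are the identification target. The `da`
kernel is identical to `ad` by commutativity and is dropped from the
fit to keep the covariance identifiable.

The background is estimated once under the global null and reused for
every marker (the "population parameters previously determined"
approximation). Each marker's test whitens the data with the null
covariance and compares intercept-only versus intercept + marker
columns by a likelihood-ratio statistic with the overall residual
scale re-profiled per model (LRT = n·ln(RSS₀/RSS₁) on whitened data).
This makes the scan reduce *exactly* to the ordinary-regression ML
likelihood ratio when the background variance is zero. The chi-square
reference uses df equal to the marker's estimable columns: 2 normally,
1 when W is constant or collinear with Z — which happens structurally
in a tester-0 testcross, where W = Z + 1. The genome-wide threshold is
−log10(0.05/m).

PVE uses one joint regression of the response on all significant
markers' columns, entered in descending score order (ties by genomic
coordinate), with sequential Type-I sums of squares divided by the
total sum of squares about the mean. Total-about-mean (rather than
model SS) is used as the denominator so per-marker PVE and the total
are bounded by 1; collinear later markers legitimately pick up ~0.

Null calibration: the family-wise positive rate at the Bonferroni
threshold over repeated null scans stays at or below nominal. REML
background estimates on null traits pile at zero with a heavy upper
tail (a boundary-estimation property), so their location is summarized
by the median in calibration checks.

## Prediction benchmark

`mixed_solve` is ridge-regression BLUP with the spectral REML device:
the marker covariance is diagonalized on the fixed-effect complement
and the restricted likelihood is a one-dimensional function of
λ = σ_ε²/σ_u². At a fixed λ the BLUP coincides with the closed-form
ridge solution (MᵀM + λI)⁻¹Mᵀ(y − Xβ), which the tests verify to
1e-8. A constant response returns a zero-effect fit rather than an
error, the natural degenerate limit.

Cross-validation draws fold partitions per repeat from a single seeded
generator; prediction accuracy per repeat is the Pearson correlation
between observed values and pooled out-of-fold predictions (every
individual predicted exactly once per repeat). MAS.Random redraws its
marker subset every repeat, giving an honest null for the subset-size
comparison. Pooled out-of-fold correlation carries a small systematic
*negative* bias under a null trait — each fold is predicted from its
complement, whose mean anti-correlates with the fold's — so "no
signal" checks assert the absence of positive accuracy rather than
exact zero. Model comparisons use the unpaired two-sided Wilcoxon
rank-sum test on repeat-level accuracies; a subset with no usable
(non-constant) marker column yields accuracy 0 with a flag, and
singular MAS designs fall back to minimum-norm least squares with a
warning.

## QTL tools and colocalization

Significant SNPs chain into QTL by single-linkage with an inclusive
20-Mb adjacent-gap rule (transitive, matching "within 20 Mb ... one
QTL"); fixed binning was rejected because it splits clusters at
arbitrary boundaries. The same 20 Mb serves as the common-QTL window
across populations and the DEG colocalization window — it is the one
linkage distance the design states. Whether the distance should be
measured pairwise-adjacent or diameter-bounded is ambiguous;
adjacent-gap chaining is implemented.

The favorable genotype at a significant marker is the observed code
class maximizing the predicted genotypic value a·Z + d·W — with
dominance this can be the heterozygote, which matters in testcross
populations. Cross-population PVE re-runs the sequential decomposition
on the target population's genotypes and BLUEs using the source
population's significant marker list.

Differential expression uses a pooled-variance two-sample t-test on
log2(x+1) with Benjamini–Hochberg control at FDR 0.05. Pooling (rather
than Welch) keeps the full 2(n−1) degrees of freedom, which matters at
three replicates per group where Welch's approximation can drop to
df ≈ 2 and miss planted four-fold changes; the groups share a noise
model by design, so equal variances hold. Genes with zero variance and
equal means get p = 1. A gene's position is its annotated start; DEG
sets against the two parents are intersected before colocalization,
and candidates found in the reference trait-gene list sort first, then
by distance to the nearest significant SNP.

## Problem sizes

The statistical test suite uses: 2,000 families for Mendelian
simulator checks; 400 individuals × 1,000 markers with 200 null scans
and 50 power replicates for scan calibration; 300 individuals × 600
markers with 20 cross-validation repeats for prediction checks. These
sizes put Monte-Carlo standard errors comfortably inside each
assertion's tolerance while keeping the suite fast.

## Known limitations

- No genotyping-error model beyond random missingness; no mutation,
  selection, or segregation distortion.
- The scan's fixed-background approximation slightly miscalibrates
  very strong single-QTL architectures (as all P3D-style methods do).
- Per-pair epistatic effect testing is not implemented; epistasis
  enters only as background variance.
- DEG detection is a two-group location test on abundance tables, not
  a count-model RNA-seq analysis.
- BED interfaces carry point positions (gene starts), not gene bodies.
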