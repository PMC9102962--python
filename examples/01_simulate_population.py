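"""Simulate a BC1F3:4 line-per-se population and its two testcrosses.

Gene-drops 300 families through donor x recurrent -> F1 -> BC1 -> two
selfings, then deduces testcross genotypes against two homozygous
testers.  The printed donor-allele frequency and heterozygosity should
sit near their Mendelian expectations of 0.25 and 0.125.
"""

import numpy as np

from hybridqtl import simdata

cfg = simdata.SimConfig(
    n_chromosomes=3,
    chrom_lengths_bp=(200_000_000, 180_000_000, 160_000_000),
    snps_per_chrom=(150, 130, 120),
    n_families=300,
    seed=1,
)
pop = simdata.simulate_bc1f3_population(cfg)
codes = pop.codes.to_numpy()
print(f"population: {pop.n_individuals} families x {pop.n_markers} SNPs")
print(f"donor allele frequency: {codes.mean() / 2:.3f}  (expected 0.25)")
print(f"heterozygosity:         {(codes == 1).mean():.3f}  (expected 0.125)")

testers = simdata.default_testers(cfg)
tc = simdata.simulate_testcross(pop, testers["tester1"])
frac = np.isin(tc.codes.to_numpy(), (0.5, 1.5)).mean()
print(f"testcross fractional codes: {frac:.3f} of cells "
      "(deduced from heterozygous parents)")
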