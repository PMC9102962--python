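"""Generative correctness of the breeding-population simulator."""

import numpy as np
import pandas as pd
import pytest

from hybridqtl import simdata
from hybridqtl.simdata import DegSpec, Qtl, SimConfig


def small_config(**kw):
    base = dict(
        n_chromosomes=2,
        chrom_lengths_bp=(200_000_000, 150_000_000),
        snps_per_chrom=(30, 20),
        n_families=150,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_founders_divergent_and_homozygous(self):
        cfg = small_config()
        donor, recurrent = simdata.simulate_founders(cfg)
        for d, r in zip(donor, recurrent):
            assert np.all(d == 1) and np.all(r == 0)

    def test_marker_count_forced_by_config(self):
        cfg = SimConfig(
            n_chromosomes=10,
            chrom_lengths_bp=(200_000_000,) * 10,
            snps_per_chrom=(1500,) * 10,
            n_families=5,
            qtl_spec=[],
            seed=0,
        )
        assert len(cfg.marker_map()) == 15_000

    def test_invalid_chromosome_spec_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=1, chrom_lengths_bp=(0,),
                      snps_per_chrom=(10,), qtl_spec=[])
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=2, chrom_lengths_bp=(1000,),
                      snps_per_chrom=(10,), qtl_spec=[])


class TestGamete:
    def test_homozygous_parent_transmits_itself(self, rng):
        cfg = small_config()
        donor, _ = simdata.simulate_founders(cfg)
        gamete = simdata.simulate_gamete((donor, donor), cfg, rng)
        for g, d in zip(gamete, donor):
            assert np.array_equal(g, d)

    def test_mean_crossovers_matches_poisson_map_length(self):
        # 200 Mb at 1 cM/Mb = 2 Morgans -> Poisson(2) crossover count.
        # Count realized switch points in F1 gametes as a lower-level proxy:
        # draw the Poisson counts directly through a controlled generator.
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_bp=(200_000_000,),
                        snps_per_chrom=(400,), n_families=1, qtl_spec=[], seed=0)
        rng = np.random.default_rng(99)
        donor, recurrent = simdata.simulate_founders(cfg)
        n_draws = 10_000
        switches = np.empty(n_draws)
        for i in range(n_draws):
            g = simdata.simulate_gamete((donor, recurrent), cfg, rng)[0]
            switches[i] = np.sum(np.abs(np.diff(g)))
        # observed switch count underestimates crossovers only through
        # double-crossovers between adjacent markers (negligible at 0.5 Mb
        # spacing); 3-SE band around the Poisson(2) mean
        se = np.sqrt(2.0 / n_draws)
        assert abs(switches.mean() - 2.0) < 3 * se + 0.02

    def test_zero_length_map_never_recombines(self, rng):
        cfg = small_config(cm_per_mb=0.0)
        donor, recurrent = simdata.simulate_founders(cfg)
        for _ in range(20):
            g = simdata.simulate_gamete((donor, recurrent), cfg, rng)
            for chrom in g:
                assert np.all(chrom == chrom[0])


class TestPopulation:
    def test_codes_legal_and_deterministic(self):
        cfg = small_config()
        pop1 = simdata.simulate_bc1f3_population(cfg)
        pop2 = simdata.simulate_bc1f3_population(small_config())
        assert set(np.unique(pop1.codes.to_numpy())) <= {0.0, 1.0, 2.0}
        pd.testing.assert_frame_equal(pop1.codes, pop2.codes)

    def test_donor_frequency_and_heterozygosity(self):
        # Mendelian pedigree expectation: donor allele 1/4, het 1/8
        cfg = small_config(n_families=800, seed=11)
        pop = simdata.simulate_bc1f3_population(cfg)
        codes = pop.codes.to_numpy()
        fam_freq = codes.mean(axis=1) / 2.0
        fam_het = (codes == 1).mean(axis=1)
        se_f = fam_freq.std(ddof=1) / np.sqrt(len(fam_freq))
        se_h = fam_het.std(ddof=1) / np.sqrt(len(fam_het))
        assert abs(fam_freq.mean() - 0.25) < 3 * se_f
        assert abs(fam_het.mean() - 0.125) < 3 * se_h

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            small_config(n_families=0)

    def test_missingness_injection(self):
        cfg = small_config(missing_rate=0.1, seed=5)
        pop = simdata.simulate_bc1f3_population(cfg)
        frac = pop.codes.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15


class TestTestcross:
    def test_deduction_rule_and_expectation_oracle(self):
        cfg = small_config()
        pop = simdata.simulate_bc1f3_population(cfg)
        tester = pd.Series(0.0, index=pop.marker_map.index)
        tc = simdata.simulate_testcross(pop, tester)
        # oracle: enumerate parent gametes; progeny dosage = parent allele
        # + tester allele; deduced code is the Mendelian mean
        def mean_progeny(parent_code, tester_code):
            parent_alleles = {0: [0, 0], 1: [0, 1], 2: [1, 1]}[parent_code]
            t = tester_code // 2
            return np.mean([a + t for a in parent_alleles])

        for pc in (0, 1, 2):
            expected = mean_progeny(pc, 0)
            got = tc.codes.to_numpy()[pop.codes.to_numpy() == pc]
            assert np.all(got == expected)

    def test_homozygous_parents_give_integer_like_codes(self):
        cfg = small_config()
        pop = simdata.simulate_bc1f3_population(cfg)
        hom = pop.codes.where(pop.codes != 1, 0.0)  # force out heterozygotes
        hom_pop = simdata.GenotypeMatrix if False else pop
        tester = pd.Series(0.0, index=pop.marker_map.index)
        from hybridqtl.genotype_qc import GenotypeMatrix
        tc = simdata.simulate_testcross(GenotypeMatrix(hom, pop.marker_map), tester)
        assert set(np.unique(tc.codes.to_numpy())) <= {0.0, 1.0}

    def test_heterozygous_tester_rejected(self, tiny_pop):
        tester = pd.Series(1.0, index=tiny_pop.marker_map.index)
        with pytest.raises(ValueError, match="homozygous"):
            simdata.simulate_testcross(tiny_pop, tester)


class TestPhenotypes:
    def test_noiseless_additive_model_is_exact(self):
        cfg = small_config(
            sigma2_g=0.0, sigma2_gxe=0.0, sigma2_eps=0.0, sigma2_env=0.0,
            sigma2_rep=0.0, sigma2_block=0.0, mu=0.0,
            n_environments=1, n_replicates=1, n_blocks=2,
        )
        qtl = [Qtl("chr1", cfg.marker_map()["pos"].iloc[10], 1.0, 0.0)]
        cfg.qtl_spec = qtl
        pop = simdata.simulate_bc1f3_population(cfg)
        sim = simdata.simulate_phenotypes(pop, cfg)
        marker = f"chr1_{qtl[0].pos}"
        expected = pop.codes[marker] - 1.0
        got = sim.records.set_index("genotype")["value"]
        assert np.allclose(got.reindex(expected.index), expected)

    def test_dominance_favors_heterozygotes(self):
        cfg = small_config()
        qtl = [Qtl("chr1", cfg.marker_map()["pos"].iloc[5], 0.0, 1.0)]
        pop = simdata.simulate_bc1f3_population(cfg)
        g = simdata.genetic_values(pop, qtl)
        marker = f"chr1_{qtl[0].pos}"
        codes = pop.codes[marker]
        assert g[codes == 1].mean() > g[codes != 1].mean()

    def test_variance_decomposition_under_balanced_design(self):
        # strata with few levels (environment, replicate, block) are left
        # at zero: their single-realization variance is not estimable
        cfg = small_config(n_families=400, seed=21, sigma2_env=0.0,
                           sigma2_rep=0.0, sigma2_block=0.0)
        pop = simdata.simulate_bc1f3_population(cfg)
        sim = simdata.simulate_phenotypes(pop, cfg)
        total = sim.records["value"].var(ddof=1)
        expected = cfg.sigma2_g + cfg.sigma2_gxe + cfg.sigma2_eps
        assert abs(total - expected) / expected < 0.1

    def test_qtl_off_map_rejected(self, tiny_pop):
        with pytest.raises(ValueError, match="not on the marker map"):
            simdata.genetic_values(tiny_pop, [Qtl("chr1", 12345, 1.0)])


class TestExpression:
    def test_null_fold_change_produces_no_planted_signal(self):
        cfg = small_config()
        degs = [DegSpec("g1", "chr1", 1_000_000, fold_change=1.0)]
        expr = simdata.simulate_expression_profiles(cfg, degs, n_genes=60)
        from hybridqtl.coloc import de_test
        res = de_test(expr, "hybrid", "parent1")
        assert res["deg"].sum() <= 2  # BH keeps false positives near zero

    def test_planted_degs_recovered(self):
        cfg = small_config()
        degs = [DegSpec(f"deg{i}", "chr1", (i + 1) * 10_000_000, fold_change=4.0)
                for i in range(5)]
        expr = simdata.simulate_expression_profiles(cfg, degs, n_genes=80)
        from hybridqtl.coloc import common_degs, de_test
        d1 = de_test(expr, "hybrid", "parent1")
        d2 = de_test(expr, "hybrid", "parent2")
        found = set(common_degs(d1, d2)["gene"])
        assert {d.gene for d in degs} <= found

    def test_requires_three_replicates(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            simdata.simulate_expression_profiles(cfg, [], n_reps=2)
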