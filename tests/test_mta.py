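"""Additive/dominance encoding, kernels, the GLS scan and PVE."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from hybridqtl import mta, simdata
from hybridqtl._reml import MixedFit, reml_kernels
from hybridqtl.genotype_qc import GenotypeMatrix


def matrix_from_codes(codes: np.ndarray) -> GenotypeMatrix:
    n, m = codes.shape
    cols = [f"m{j}" for j in range(m)]
    mm = pd.DataFrame(
        {"chrom": "chr1", "pos": [(j + 1) * 1_000_000 for j in range(m)]},
        index=pd.Index(cols, name="marker"),
    )
    return GenotypeMatrix(
        pd.DataFrame(codes, columns=cols,
                     index=[f"I{i}" for i in range(n)], dtype=float), mm
    )


def ols_lrt_scores(codes, y):
    """Ordinary-regression ML likelihood-ratio oracle (no background)."""
    n = len(y)
    rss0 = np.sum((y - y.mean()) ** 2)
    scores = []
    for j in range(codes.shape[1]):
        z = codes[:, j] - 1.0
        w = 1.0 - np.abs(z)
        cols = [np.ones(n)]
        if np.ptp(z) > 0:
            cols.append(z)
        zc, wc = z - z.mean(), w - w.mean()
        denom = np.linalg.norm(zc) * np.linalg.norm(wc)
        if np.ptp(w) > 0 and (np.ptp(z) == 0 or abs(zc @ wc) < (1 - 1e-10) * denom):
            cols.append(w)
        X = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = np.sum((y - X @ beta) ** 2)
        df = rank - 1
        if df == 0:
            scores.append(0.0)
            continue
        lrt = n * np.log(rss0 / rss1)
        scores.append(-np.log10(scipy.stats.chi2.sf(lrt, df)))
    return np.array(scores)


class TestEncode:
    @pytest.mark.parametrize("code,zw", [
        (2.0, (1.0, 0.0)), (1.0, (0.0, 1.0)), (0.0, (-1.0, 0.0)),
        (0.5, (-0.5, 0.5)), (1.5, (0.5, 0.5)),
    ])
    def test_encoding_table(self, code, zw):
        z, w = mta.encode_marker([code])
        assert (z[0], w[0]) == zw

    def test_fractional_code_is_progeny_expectation(self):
        # Aa x aa progeny: half aa (Z=-1, W=0), half Aa (Z=0, W=1)
        z, w = mta.encode_marker([0.5])
        assert z[0] == np.mean([-1.0, 0.0])
        assert w[0] == np.mean([0.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mta.encode_marker([2.5])

    @given(st.lists(st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0]),
                    min_size=1, max_size=30))
    def test_bounds_invariant(self, codes):
        z, w = mta.encode_marker(codes)
        assert np.all((z >= -1) & (z <= 1))
        assert np.all((w >= 0) & (w <= 1))
        assert np.allclose(w, 1 - np.abs(z))


class TestKernels:
    def test_identical_individuals_identical_rows(self):
        geno = matrix_from_codes(np.tile([0.0, 1.0, 2.0, 1.0], (4, 1)))
        for K in mta.build_kernels(geno).values():
            assert np.allclose(K, K[0])

    def test_epistatic_kernel_matches_pairwise_column_oracle(self, rng):
        codes = rng.integers(0, 3, size=(5, 4)).astype(float)
        geno = matrix_from_codes(codes)
        kernels = mta.build_kernels(geno)
        Z = codes - 1.0
        m = Z.shape[1]
        # oracle: explicit product columns over all ordered marker pairs
        cols = np.column_stack(
            [Z[:, k] * Z[:, kp] for k in range(m) for kp in range(m)]
        )
        oracle = cols @ cols.T / m**2
        assert np.allclose(kernels["aa"], oracle)

    def test_ad_equals_da(self, tiny_pop):
        kernels = mta.build_kernels(tiny_pop)
        assert np.allclose(kernels["ad"], kernels["da"])

    def test_kernels_psd(self, tiny_pop):
        kernels = mta.build_kernels(tiny_pop)
        for name in ("additive", "dominance", "aa", "dd"):
            eigs = np.linalg.eigvalsh(kernels[name])
            assert eigs.min() > -1e-8


class TestFitNull:
    def test_pure_noise_gives_null_background(self, rng):
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_lengths_bp=(150_000_000, 150_000_000),
            snps_per_chrom=(60, 60), n_families=200, seed=31,
        )
        pop = simdata.simulate_bc1f3_population(cfg)
        kernels = mta.build_kernels(pop)
        ratios, resids = [], []
        for _ in range(10):
            y = rng.normal(size=pop.n_individuals)
            fit = mta.fit_null(pd.Series(y, index=pop.codes.index), kernels)
            total_bg = fit.variances["additive"] + fit.variances["dominance"]
            ratios.append(total_bg / np.var(y))
            resids.append(fit.variances["residual"] / np.var(y))
        # boundary REML: background estimates pile at zero with a heavy
        # upper tail, so the median is the meaningful location summary
        assert np.median(ratios) < 0.15
        assert abs(np.mean(resids) - 1.0) < 0.3

    def test_recovers_additive_variance_ratio(self, rng):
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_lengths_bp=(150_000_000, 150_000_000),
            snps_per_chrom=(150, 150), n_families=400, seed=32,
        )
        pop = simdata.simulate_bc1f3_population(cfg)
        kernels = mta.build_kernels(pop)
        Ka = kernels["additive"]
        L = np.linalg.cholesky(Ka + 1e-8 * np.eye(len(Ka)))
        y = L @ rng.normal(size=len(Ka)) + rng.normal(size=len(Ka))
        fit = mta.fit_null(pd.Series(y, index=pop.codes.index), kernels)
        ratio = fit.variances["additive"] / fit.variances["residual"]
        assert 0.5 < ratio < 2.0  # target 1.0, +-30% plus Monte-Carlo slack

    def test_identity_kernel_reduces_to_ols_variance(self, rng):
        y = rng.normal(size=80)
        X = np.ones((80, 1))
        fit = reml_kernels(y, X, [("identity", np.eye(80))])
        total = fit.variances["identity"] + fit.variances["residual"]
        assert np.isclose(total, y.var(ddof=1), rtol=1e-3)


class TestScan:
    def test_matches_ols_oracle_without_background(self, rng):
        codes = rng.integers(0, 3, size=(50, 20)).astype(float)
        geno = matrix_from_codes(codes)
        y = rng.normal(size=50)
        null = MixedFit(variances={"residual": float(np.var(y))},
                        fixed_effects=np.array([y.mean()]), n_obs=50)
        scan = mta.scan_markers(geno, pd.Series(y, index=geno.codes.index), null)
        oracle = ols_lrt_scores(codes, y)
        assert np.allclose(scan["score"].to_numpy(), oracle, atol=1e-6)

    def test_constant_marker_flagged_nontestable(self, rng):
        codes = rng.integers(0, 3, size=(30, 3)).astype(float)
        codes[:, 1] = 1.0
        geno = matrix_from_codes(codes)
        y = rng.normal(size=30)
        null = MixedFit(variances={"residual": 1.0},
                        fixed_effects=np.array([0.0]), n_obs=30)
        scan = mta.scan_markers(geno, pd.Series(y, index=geno.codes.index), null)
        assert not scan["testable"].iloc[1]
        assert scan["score"].iloc[1] == 0.0

    def test_testcross_collinear_encoding_gets_one_df(self):
        codes = np.array([[0.0], [0.5], [1.0], [0.5], [0.0], [1.0]])
        geno = matrix_from_codes(codes)
        y = pd.Series([0.1, 0.5, 1.2, 0.4, -0.1, 0.9], index=geno.codes.index)
        null = MixedFit(variances={"residual": float(np.var(y))},
                        fixed_effects=np.array([y.mean()]), n_obs=6)
        scan = mta.scan_markers(geno, y, null)
        assert scan["df"].iloc[0] == 1

    def test_detects_planted_qtl(self):
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_lengths_bp=(150_000_000, 150_000_000),
            snps_per_chrom=(80, 80), n_families=300, qtl_spec=[], seed=33,
        )
        # plant the QTL on the marker grid
        pos = cfg.marker_positions()[0]
        cfg.qtl_spec = [simdata.Qtl("chr1", int(pos[40]), 1.0, 0.0)]
        pop = simdata.simulate_bc1f3_population(cfg)
        g = simdata.genetic_values(pop, cfg.qtl_spec)
        rng = np.random.default_rng(8)
        y = pd.Series(
            (g / g.std() + rng.normal(0, 1, len(g))).to_numpy(),
            index=pop.codes.index,
        )
        kernels = mta.build_kernels(pop)
        null = mta.fit_null(y, kernels)
        scan = mta.scan_markers(pop, y, null)
        peak = scan.loc[scan["score"].idxmax()]
        assert peak["chrom"] == "chr1"
        assert abs(peak["pos"] - cfg.qtl_spec[0].pos) <= 5_000_000


class TestThreshold:
    @pytest.mark.parametrize("m,expected", [
        (15_386, 5.49), (20, 2.60), (1, 1.30),
    ])
    def test_closed_form(self, m, expected):
        assert round(mta.significance_threshold(m), 2) == expected

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            mta.significance_threshold(0)

    @given(st.integers(min_value=1, max_value=10**7))
    def test_strictly_increasing(self, m):
        assert (mta.significance_threshold(m + 1)
                > mta.significance_threshold(m))


class TestPve:
    def test_perfect_single_marker(self):
        codes = np.array([[0.0], [2.0], [0.0], [2.0]])
        geno = matrix_from_codes(codes)
        y = pd.Series(codes[:, 0] - 1.0, index=geno.codes.index)
        sig = pd.DataFrame({"marker": ["m0"], "chrom": ["chr1"],
                            "pos": [1], "score": [9.0]})
        pve = mta.compute_pve(geno, y, sig)
        assert pve["pve"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_markers_split_variance(self):
        # codes built so the three Z columns are exactly orthogonal;
        # y = sqrt(.3) z1 + sqrt(.3) z2 + sqrt(.4) z3: PVE = (.3, .3)
        base = np.array([
            [0, 0, 0], [0, 2, 2], [2, 0, 2], [2, 2, 0],
        ], dtype=float)
        codes = np.tile(base, (6, 1))
        geno = matrix_from_codes(codes)
        Z = codes - 1.0
        y = pd.Series(
            np.sqrt(0.3) * Z[:, 0] + np.sqrt(0.3) * Z[:, 1]
            + np.sqrt(0.4) * Z[:, 2],
            index=geno.codes.index,
        )
        sig = pd.DataFrame({"marker": ["m0", "m1"], "chrom": "chr1",
                            "pos": [1, 2], "score": [9.0, 8.0]})
        pve = mta.compute_pve(geno, y, sig)
        assert np.allclose(pve["pve"], [0.3, 0.3], atol=1e-10)
        assert pve.attrs["total_pve"] == pytest.approx(0.6)

    def test_duplicate_marker_gets_zero(self, rng):
        codes = rng.integers(0, 3, size=(40, 2)).astype(float)
        codes[:, 1] = codes[:, 0]
        geno = matrix_from_codes(codes)
        y = pd.Series(rng.normal(size=40) + codes[:, 0],
                      index=geno.codes.index)
        sig = pd.DataFrame({"marker": ["m0", "m1"], "chrom": "chr1",
                            "pos": [1, 2], "score": [9.0, 8.0]})
        pve = mta.compute_pve(geno, y, sig)
        assert pve["pve"].iloc[1] == pytest.approx(0.0, abs=1e-10)

    def test_total_bounded_by_one(self, tiny_pop, rng):
        y = pd.Series(rng.normal(size=tiny_pop.n_individuals),
                      index=tiny_pop.codes.index)
        sig = pd.DataFrame({
            "marker": list(tiny_pop.codes.columns[:10]),
            "chrom": "chr1", "pos": range(10),
            "score": np.linspace(9, 5, 10),
        })
        pve = mta.compute_pve(tiny_pop, y, sig)
        assert (pve["pve"] >= 0).all()
        assert pve.attrs["total_pve"] <= 1.0

    def test_empty_rejected(self, tiny_pop, rng):
        y = pd.Series(rng.normal(size=tiny_pop.n_individuals),
                      index=tiny_pop.codes.index)
        with pytest.raises(ValueError):
            mta.compute_pve(tiny_pop, y, pd.DataFrame(columns=["marker"]))
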