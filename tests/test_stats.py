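"""Statistics: Welch test against the closed-form oracle, star map, Fisher-z
correlation machinery, and expression binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from memratio import (DEFAULT_BIN_EDGES, ImageMeta, SyntheticCellSpec, assign_stars,
                      bin_coexpression, correlation_with_ci, generate_coexpression_population,
                      generate_dual_channel, group_error_bars, membrane_pearson,
                      welch_ttest)
from memratio.io import Image2D


def welch_oracle(a, b):
    """Closed-form Welch statistic and Satterthwaite df, by hand."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups(self):
        res = welch_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_against_hand_oracle(self):
        res = welch_ttest([1, 2, 3], [4, 5, 6])
        t, df, p = welch_oracle([1, 2, 3], [4, 5, 6])
        assert res.t_statistic == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)
        assert res.p_value == pytest.approx(0.021312, abs=1e-6)
        assert res.stars == "*"

    def test_unequal_variances_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 30))
            b = rng.normal(0.5, 3, size=rng.integers(3, 30))
            res = welch_ttest(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.t_statistic == pytest.approx(t, rel=1e-10)
            assert res.df == pytest.approx(df, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)
            assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2

    def test_null_rejection_rate(self):
        # type-I error at alpha = 0.05 over 10,000 simulated null datasets
        rng = np.random.default_rng(0)
        reps, n = 10_000, 30
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        # spot-check the vectorized scipy path agrees with our scalar API
        res0 = welch_ttest(a[0], b[0])
        assert res0.p_value == pytest.approx(p[0], rel=1e-12)
        rate = float((p < 0.05).mean())
        assert 0.045 <= rate <= 0.055

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        p = sps.ttest_ind(rng.normal(size=(10_000, 30)),
                          rng.normal(size=(10_000, 30)),
                          axis=1, equal_var=False).pvalue
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_unequal_means(self):
        res = welch_ttest([2.0, 2.0], [3.0, 3.0])
        assert res.p_value == 0.0 and res.stars == "***"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [2.0, 3.0])


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.03, "*"),          # inside the 0.01-0.05 star range
        (0.0005, "***"),
        (0.05, "ns"),         # upper boundary exclusive
        (0.01, "*"), (0.001, "**"), (0.0095, "**"),  # gap 0.009-0.01 closed
        (0.0, "***"), (1.0, "ns"),
    ])
    def test_map(self, p, expected):
        assert assign_stars(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_stars(1.5)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_total_function_no_gaps(self, p):
        assert assign_stars(p) in {"ns", "*", "**", "***"}


class TestErrorBars:
    def test_closed_form(self):
        assert group_error_bars([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2)

    def test_constant(self):
        assert group_error_bars([4.0, 4.0, 4.0]) == 0.0

    def test_is_half_sd(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        assert group_error_bars(v) == pytest.approx(v.std(ddof=1) / 2, rel=1e-12)


class TestMembranePearson:
    def _cell(self, seed=0):
        meta = ImageMeta(width=192, height=192)
        spec = SyntheticCellSpec(center=(96, 96), semi_axes=(44, 36),
                                 noise_model="none")
        return meta, spec

    def test_perfect_positive(self):
        meta, spec = self._cell()
        (ch1, _), gt = generate_dual_channel(spec, 0.5, meta, seed=0)
        ch2 = Image2D(2.0 * ch1.pixels, meta)
        res = membrane_pearson(ch1, ch2, gt.membrane_mask)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0, rel=1e-9)
        assert res.strength_label == "moderate-to-strong"

    def test_perfect_negative(self):
        meta, spec = self._cell()
        (ch1, _), gt = generate_dual_channel(spec, 0.5, meta, seed=0)
        ch2 = Image2D(-ch1.pixels + 1000.0, meta)
        res = membrane_pearson(ch1, ch2, gt.membrane_mask)
        assert res.r == pytest.approx(-1.0)

    def test_rho_07_labeled_strong(self):
        meta, spec = self._cell()
        (ch1, ch2), gt = generate_dual_channel(spec, 0.7, meta, seed=4)
        res = membrane_pearson(ch1, ch2, gt.membrane_mask)
        assert res.n >= 1000
        assert res.strength_label == "moderate-to-strong"
        assert res.ci95[0] < res.r < res.ci95[1]

    def test_zero_variance_rejected(self):
        meta, spec = self._cell()
        (ch1, _), gt = generate_dual_channel(spec, 0.5, meta, seed=0)
        flat = Image2D(np.full(meta.shape, 9.0), meta)
        with pytest.raises(ValueError, match="variance"):
            membrane_pearson(ch1, flat, gt.membrane_mask)

    def test_tiny_mask_rejected(self):
        meta, spec = self._cell()
        (ch1, ch2), _ = generate_dual_channel(spec, 0.5, meta, seed=0)
        mask = np.zeros(meta.shape, dtype=bool)
        mask[0, :5] = True
        with pytest.raises(ValueError, match="10"):
            membrane_pearson(ch1, ch2, mask)


class TestBinCoexpression:
    def test_paper_bin_assignment(self):
        tab = generate_coexpression_population(50, mc_slope=0.0, noise_sd=0.0, seed=0)
        tab.loc[:, "expression_level"] = 1.0
        tab.loc[0, "expression_level"] = 30_000.0  # falls in the third bin
        binned = bin_coexpression(tab)
        assert binned.n[2] == 1 and binned.mean_x[2] == 30_000.0

    def test_boundary_goes_to_upper_bin(self):
        tab = generate_coexpression_population(50, mc_slope=0.0, noise_sd=0.0, seed=0)
        tab.loc[:, "expression_level"] = 1.0
        tab.loc[0, "expression_level"] = 8000.0  # half-open: belongs to bin 2
        binned = bin_coexpression(tab)
        assert binned.n[1] == 1

    def test_last_edge_closed_and_overflow_excluded(self):
        tab = generate_coexpression_population(50, mc_slope=0.0, noise_sd=0.0, seed=0)
        tab.loc[:, "expression_level"] = 1.0
        tab.loc[0, "expression_level"] = 65_000.0
        tab.loc[1, "expression_level"] = 70_000.0
        binned = bin_coexpression(tab)
        assert binned.n[3] == 1
        assert binned.n_excluded == 1

    def test_partition_counts(self):
        tab = generate_coexpression_population(300, seed=7)
        binned = bin_coexpression(tab)
        assert binned.n.sum() + binned.n_excluded == len(tab)

    def test_negative_slope_strictly_decreasing_bin_means(self):
        tab = generate_coexpression_population(200, mc_slope=-2e-5, noise_sd=0.0,
                                               seed=2)
        binned = bin_coexpression(tab)
        assert np.all(np.diff(binned.mean_mc_ratio) < 0)

    def test_bad_edges_rejected(self):
        tab = generate_coexpression_population(50, seed=0)
        with pytest.raises(ValueError):
            bin_coexpression(tab, edges=[0, 100, 100, 200])


class TestCorrelationWithCI:
    def test_exact_negative_affine(self):
        x = np.arange(20.0)
        res = correlation_with_ci(x, -3.0 * x + 7.0)
        assert res.r == pytest.approx(-1.0)
        assert res.significant

    def test_null_ci_coverage(self):
        rng = np.random.default_rng(5)
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            res = correlation_with_ci(x, y)
            covered += res.ci95[0] <= 0.0 <= res.ci95[1]
        assert covered / reps >= 0.90

    def test_fisher_ci_coverage_at_known_rho(self):
        # nominal 95% within +/-2% over 1000 bivariate-normal datasets
        rng = np.random.default_rng(8)
        for rho in (0.0, 0.4, 0.7):
            covered = 0
            reps = 1000
            for _ in range(reps):
                z1 = rng.normal(size=100)
                z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=100)
                res = correlation_with_ci(z1, z2)
                covered += res.ci95[0] <= rho <= res.ci95[1]
            assert abs(covered / reps - 0.95) <= 0.02

    def test_coexpression_population_significant_negative(self):
        tab = generate_coexpression_population(200, mc_slope=-2e-5, noise_sd=0.1,
                                               seed=9)
        res = correlation_with_ci(tab["expression_level"], tab["mc_ratio"])
        assert res.r < 0 and res.significant
        assert res.ci95[1] < 0  # CI excludes zero as well

    def test_stderr_formula(self):
        tab = generate_coexpression_population(100, seed=1)
        res = correlation_with_ci(tab["expression_level"], tab["mc_ratio"])
        assert res.stderr_r == pytest.approx((1 - res.r**2) / np.sqrt(res.n - 1))

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_ci(np.ones(10), np.arange(10.0))
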