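"""CLC chi-square statistics, the Cauchy combination and the min-p null."""

import warnings

import numpy as np
import pytest
from scipy import stats

from ceclc import (
    cauchy_combine,
    ceclc_test,
    clc_minp_test,
    clc_statistic,
    component_pvalues,
    obrien_test,
    omnibus_test,
)

def clc_oracle(t, sigma, b):
    """Brute-force evaluation of (WT)^T (W Sigma W^T)^{-1} (WT), W = B^T Sigma^{-1}."""
    t = np.asarray(t, float)
    b = np.asarray(b, float)
    s_inv = np.linalg.inv(sigma)
    w = b.T @ s_inv
    wt = w @ t
    return float(wt @ np.linalg.solve(w @ sigma @ w.T, wt))


def random_summary(rng, k=5, n=60):
    y = rng.standard_normal((n, k))
    sigma = np.corrcoef(y, rowvar=False)
    t = rng.standard_normal(k)
    return t, sigma


class TestClcStatistic:
    def test_single_trait_is_squared_statistic(self):
        res = clc_statistic(np.array([1.7]), np.array([[1.0]]), np.array([[1]]))
        assert res.statistic == pytest.approx(1.7**2)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(1.7**2, 1))

    def test_identity_membership_is_omnibus_quadratic_form(self, rng):
        t, sigma = random_summary(rng)
        res = clc_statistic(t, sigma, np.eye(5, dtype=int))
        expected = float(t @ np.linalg.solve(sigma, t))
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df == 5

    def test_two_trait_single_cluster_against_matrix_oracle(self):
        t = np.array([2.0, 2.0])
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.ones((2, 1), dtype=int)
        res = clc_statistic(t, sigma, b)
        assert res.statistic == pytest.approx(clc_oracle(t, sigma, b), rel=1e-12)
        # closed form: (1^T S t)^2 / (1^T S 1) with S = Sigma^{-1}
        s = np.linalg.inv(sigma)
        assert res.statistic == pytest.approx(
            (np.ones(2) @ s @ t) ** 2 / (np.ones(2) @ s @ np.ones(2)), rel=1e-12
        )
        assert res.df == 1

    def test_general_membership_against_matrix_oracle(self, rng):
        for _ in range(25):
            t, sigma = random_summary(rng, k=6)
            labels = rng.integers(0, 3, 6)
            labels[:3] = [0, 1, 2]  # ensure all three clusters occupied
            b = np.zeros((6, 3), dtype=int)
            b[np.arange(6), labels] = 1
            res = clc_statistic(t, sigma, b)
            assert res.statistic == pytest.approx(clc_oracle(t, sigma, b), rel=1e-9)
            assert res.df == 3
            assert res.statistic >= 0

    def test_duplicate_traits_ridged_but_finite(self, rng):
        y0 = rng.standard_normal(40)
        y = np.column_stack([y0, y0, rng.standard_normal(40)])
        sigma = np.corrcoef(y, rowvar=False)
        t = np.array([1.0, 1.0, 0.5])
        with pytest.warns(RuntimeWarning, match="ridge"):
            p = component_pvalues(t, sigma)
        assert np.all(np.isfinite(p)) and np.all((p > 0) & (p <= 1))


class TestComponentPvalues:
    def test_single_trait(self):
        p = component_pvalues(np.array([2.0]), np.array([[1.0]]))
        assert p.shape == (1,)
        assert p[0] == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_length_and_range(self, rng):
        t, sigma = random_summary(rng, k=7)
        p = component_pvalues(t, sigma)
        assert p.shape == (7,)
        assert np.all((p > 0) & (p <= 1))

    def test_marginal_uniformity_under_null(self, rng):
        # each p_L is marginally uniform when T ~ MVN(0, sigma)
        k, draws = 5, 5000
        sigma = np.corrcoef(rng.standard_normal((200, k)), rowvar=False)
        chol = np.linalg.cholesky(sigma)
        ps = np.empty((draws, k))
        for i in range(draws):
            t = chol @ rng.standard_normal(k)
            ps[i] = component_pvalues(t, sigma)
        for L in range(k):
            assert stats.kstest(ps[:, L], "uniform").pvalue > 0.001


class TestCauchyCombine:
    def test_all_half_maps_to_half(self):
        assert cauchy_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_single_p_is_identity(self):
        for p in (0.01, 0.3, 0.77, 0.999):
            assert cauchy_combine([p]) == pytest.approx(p, rel=1e-10)

    def test_two_value_worked_example(self):
        # direct evaluation of the two printed formulas
        expected_stat = (np.tan((0.5 - 0.01) * np.pi) + np.tan(0.0)) / 2
        expected_p = 0.5 - np.arctan(expected_stat) / np.pi
        assert cauchy_combine([0.01, 0.5]) == pytest.approx(expected_p, rel=1e-12)

    def test_monotone_in_each_component(self):
        base = cauchy_combine([0.2, 0.6])
        assert cauchy_combine([0.1, 0.6]) < base
        assert cauchy_combine([0.2, 0.5]) < base

    def test_small_p_guard_is_continuous_and_monotone(self):
        ps = [1e-14, 1e-15, 1e-16, 1e-17]
        combined = [cauchy_combine([p, 0.5]) for p in ps]
        assert all(np.diff(combined) < 0)
        assert all(0 < c < 1e-13 for c in combined)

    def test_exact_zero_and_one_are_guarded(self):
        with pytest.warns(RuntimeWarning, match="exactly 0"):
            p0 = cauchy_combine([0.0, 0.5])
        assert 0 < p0 < 1e-200
        with pytest.warns(RuntimeWarning, match="exactly 1"):
            p1 = cauchy_combine([1.0, 0.5])
        assert 0 < p1 <= 1

    def test_weights_must_be_simplex(self):
        with pytest.raises(ValueError):
            cauchy_combine([0.2, 0.4], weights=[0.9, 0.9])
        with pytest.raises(ValueError):
            cauchy_combine([0.2, 0.4], weights=[-0.5, 1.5])
        assert cauchy_combine([0.2, 0.4], weights=[1.0, 0.0]) == pytest.approx(0.2)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([0.5, 1.2])
        with pytest.raises(ValueError):
            cauchy_combine([-0.1])


class TestCeclc:
    def test_single_trait_reduces_to_chi2(self):
        t = np.array([2.3])
        res = ceclc_test(t, np.array([[1.0]]))
        assert res.p_value == pytest.approx(stats.chi2.sf(2.3**2, 1), rel=1e-10)
        assert res.component_p.shape == (1,)

    def test_matches_straight_line_reimplementation(self, rng):
        # end-to-end oracle with explicit matrix algebra and scipy clustering
        import scipy.cluster.hierarchy as sch
        from scipy.spatial.distance import squareform

        t, sigma = random_summary(rng, k=3)
        z = sch.linkage(squareform(1 - sigma, checks=False), method="average")
        stat_terms = []
        for L in (1, 2, 3):
            lab = sch.fcluster(z, t=L, criterion="maxclust") - 1
            b = np.zeros((3, L))
            b[np.arange(3), lab] = 1
            p_l = stats.chi2.sf(clc_oracle(t, sigma, b), df=L)
            stat_terms.append(np.tan((0.5 - p_l) * np.pi))
        expected = 0.5 - np.arctan(np.mean(stat_terms)) / np.pi
        res = ceclc_test(t, sigma)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_no_random_draws(self, monkeypatch):
        # the ceCLC p-value is closed-form: poison every RNG entry point
        def poisoned(*a, **k):
            raise AssertionError("ceclc_test must not draw random numbers")

        monkeypatch.setattr(np.random, "default_rng", poisoned)
        monkeypatch.setattr(np.random, "standard_normal", poisoned)
        monkeypatch.setattr(np.random, "normal", poisoned)
        monkeypatch.setattr(np.random, "rand", poisoned)
        rng = np.random.Generator(np.random.PCG64(5))
        t = rng.standard_normal(4)
        sigma = np.corrcoef(rng.standard_normal((50, 4)), rowvar=False)
        res = ceclc_test(t, sigma)
        assert 0 < res.p_value <= 1

    def test_deterministic(self, rng):
        t, sigma = random_summary(rng)
        r1, r2 = ceclc_test(t, sigma), ceclc_test(t, sigma)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic


class TestMinpClc:
    def test_single_trait_minp_matches_chi2_within_mc_error(self, rng):
        t = np.array([2.0])
        res = clc_minp_test(t, np.array([[1.0]]), n_mc=20000, seed=1)
        exact = stats.chi2.sf(4.0, 1)
        assert res.statistic == pytest.approx(exact, rel=1e-12)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(res.p_value - exact) < 4 * se

    def test_null_statistic_gives_pvalue_one(self, rng):
        # T = 0 makes every p_L = 1, so no simulated minimum can fall below
        t = np.zeros(3)
        sigma = np.corrcoef(rng.standard_normal((50, 3)), rowvar=False)
        res = clc_minp_test(t, sigma, n_mc=1500, seed=2)
        assert res.p_value == 1.0

    def test_self_consistent_across_replicate_counts(self, rng):
        t = np.array([1.8, -0.7])
        sigma = np.eye(2)
        p_small = clc_minp_test(t, sigma, n_mc=2000, seed=3).p_value
        p_big = clc_minp_test(t, sigma, n_mc=100000, seed=4).p_value
        se = np.sqrt(p_big * (1 - p_big) / 2000)
        assert abs(p_small - p_big) < 3 * se

    def test_reproducible_given_seed(self, rng):
        t, sigma = random_summary(rng)
        a = clc_minp_test(t, sigma, n_mc=1000, seed=11)
        b = clc_minp_test(t, sigma, n_mc=1000, seed=11)
        assert a.p_value == b.p_value

    def test_too_few_replicates_rejected_or_warned(self, rng):
        t, sigma = random_summary(rng)
        with pytest.raises(ValueError):
            clc_minp_test(t, sigma, n_mc=50, seed=0)
        with pytest.warns(RuntimeWarning, match="granularity"):
            clc_minp_test(t, sigma, n_mc=200, seed=0)

    def test_rank_correlation_with_ceclc_under_null(self, rng):
        # both aggregate the same p_L vector, so their orderings must agree
        k = 5
        sigma = np.corrcoef(rng.standard_normal((100, k)), rowvar=False)
        chol = np.linalg.cholesky(sigma)
        p_ce, p_minp = [], []
        for i in range(200):
            t = chol @ rng.standard_normal(k)
            p_ce.append(ceclc_test(t, sigma).p_value)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p_minp.append(clc_minp_test(t, sigma, n_mc=500, seed=i).p_value)
        rho = stats.spearmanr(p_ce, p_minp).statistic
        assert rho > 0.8


class TestSpecialCases:
    def test_obrien_identity_sigma_closed_form(self):
        t = np.array([1.0, 2.0, -0.5])
        res = obrien_test(t, np.eye(3))
        assert res.statistic == pytest.approx(t.sum() ** 2 / 3, rel=1e-12)
        assert res.df == 1

    def test_omnibus_identity_sigma_closed_form(self):
        t = np.array([1.0, 2.0, -0.5])
        res = omnibus_test(t, np.eye(3))
        assert res.statistic == pytest.approx(float(t @ t), rel=1e-12)
        assert res.df == 3

    def test_single_trait_special_cases(self):
        t = np.array([1.3])
        assert obrien_test(t, np.eye(1)).statistic == pytest.approx(1.69)
        assert omnibus_test(t, np.eye(1)).statistic == pytest.approx(1.69)

    def test_equal_their_clc_special_cases_bitwise(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            t, sigma = random_summary(rng, k=k, n=40)
            ob = obrien_test(t, sigma)
            cl1 = clc_statistic(t, sigma, np.ones((k, 1), dtype=int))
            assert ob.statistic == cl1.statistic and ob.p_value == cl1.p_value
            om = omnibus_test(t, sigma)
            clk = clc_statistic(t, sigma, np.eye(k, dtype=int))
            assert om.statistic == clk.statistic and om.p_value == clk.p_value


class TestCeclcCdfUnderMvn:
    def test_empirical_cdf_near_nominal_at_common_levels(self, rng):
        # T ~ MVN(0, sigma) with fixed sigma: the ceCLC p-value's CDF at
        # 0.01 / 0.05 / 0.1 within 3 binomial SDs over 5000 draws
        k, draws = 10, 5000
        sigma = np.corrcoef(rng.standard_normal((300, k)), rowvar=False)
        chol = np.linalg.cholesky(sigma)
        ts = rng.standard_normal((draws, k)) @ chol.T
        ps = np.array([ceclc_test(ts[i], sigma).p_value for i in range(draws)])
        for a in (0.01, 0.05, 0.1):
            rate = (ps <= a).mean()
            assert abs(rate - a) < 3 * np.sqrt(a * (1 - a) / draws)


class TestChiSquareNesting:
    def test_component_statistics_follow_chi2_under_mvn(self, rng):
        # fixed random partition per L; 5000 draws; KS at alpha = 0.001
        k, draws = 6, 5000
        sigma = np.corrcoef(rng.standard_normal((150, k)), rowvar=False)
        chol = np.linalg.cholesky(sigma)
        ts = rng.standard_normal((draws, k)) @ chol.T
        for L in (1, 2, 3, 6):
            labels = (rng.permutation(k) * L // k).astype(int)
            labels = np.sort(labels)
            perm = rng.permutation(k)
            labels = labels[perm]  # random but fixed partition with L blocks
            b = np.zeros((k, L), dtype=int)
            b[np.arange(k), labels] = 1
            vals = np.array([clc_statistic(ts[i], sigma, b).statistic
                             for i in range(draws)])
            assert stats.kstest(vals, "chi2", args=(L,)).pvalue > 0.001
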