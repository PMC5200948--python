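"""Dirichlet-multinomial density, moments, parameterizations and proportion MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmusage import dm
from dmusage.data import DMParameters, GeneCounts

from conftest import enumerate_compositions


def product_form_log_pmf(y, pi, theta):
    """Independent oracle: the ascending-product form of the DM pmf.

    f(y) = C(m; y) * prod_j prod_{r=1}^{y_j} [pi_j (1-theta) + (r-1) theta]
                   / prod_{r=1}^{m} [(1-theta) + (r-1) theta]
    evaluated by direct looping, no log-gamma identities.
    """
    y = np.asarray(y)
    m = int(y.sum())
    coef = math.lgamma(m + 1) - sum(math.lgamma(int(v) + 1) for v in y)
    num = 0.0
    for pij, yj in zip(pi, y):
        for r in range(1, int(yj) + 1):
            num += math.log(pij * (1 - theta) + (r - 1) * theta)
    den = sum(math.log((1 - theta) + (r - 1) * theta) for r in range(1, m + 1))
    return coef + num - den


class TestDensity:
    @pytest.mark.parametrize("m,q,pi,gp", [
        (4, 3, (0.5, 0.3, 0.2), 10.0),
        (6, 2, (0.7, 0.3), 0.5),
        (5, 4, (0.4, 0.3, 0.2, 0.1), 3.0),
        (8, 3, (1 / 3, 1 / 3, 1 / 3), 1e4),
    ])
    def test_pmf_normalizes(self, m, q, pi, gp):
        total = sum(np.exp(dm.dm_log_pmf(np.array(y), np.array(pi), gp))
                    for y in enumerate_compositions(m, q))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_category_is_certain(self):
        assert dm.dm_log_pmf(np.array([5]), np.array([1.0]), 7.0) == pytest.approx(0.0)

    def test_large_concentration_approaches_multinomial(self):
        y = np.array([3, 2, 1])
        pi = np.array([0.5, 0.3, 0.2])
        assert dm.dm_log_pmf(y, pi, 1e12) == pytest.approx(
            dm.multinomial_log_pmf(y, pi), abs=1e-6)

    def test_theta_zero_is_exactly_multinomial(self):
        pi = np.array([0.5, 0.3, 0.2])
        for y in enumerate_compositions(6, 3):
            y = np.array(y)
            diff = abs(np.exp(dm.dm_log_pmf_theta(y, pi, 0.0))
                       - np.exp(dm.multinomial_log_pmf(y, pi)))
            assert diff < 1e-12

    def test_theta_form_hand_value(self):
        # y=(2,1), pi=(1/2,1/2), theta=0: multinomial 3 * (1/2)^3 = 0.375
        assert dm.dm_log_pmf_theta(np.array([2, 1]), np.array([0.5, 0.5]), 0.0) \
            == pytest.approx(np.log(0.375))

    @pytest.mark.parametrize("y,theta", [((1, 1), 0.5), ((3, 0), 0.2), ((2, 4), 0.9)])
    def test_log_gamma_form_matches_product_form(self, y, theta):
        pi = np.array([0.4, 0.6])
        got = dm.dm_log_pmf_theta(np.array(y), pi, theta)
        assert got == pytest.approx(product_form_log_pmf(y, pi, theta), abs=1e-12)

    def test_invalid_arguments_rejected(self):
        pi = np.array([0.5, 0.5])
        with pytest.raises(ValueError):
            dm.dm_log_pmf(np.array([-1, 2]), pi, 1.0)
        with pytest.raises(ValueError):
            dm.dm_log_pmf(np.array([1, 2]), np.array([0.5, 0.6]), 1.0)
        with pytest.raises(ValueError):
            dm.dm_log_pmf(np.array([1, 2]), pi, 0.0)
        with pytest.raises(ValueError):
            dm.dm_log_pmf_theta(np.array([1, 2]), pi, 1.0)


class TestMoments:
    def test_inflation_factor_hand_value(self):
        mom = dm.dm_moments(11, np.array([0.5, 0.5]), 9.0)
        assert mom.inflation_factor == pytest.approx(2.0)  # (11+9)/(1+9)

    def test_multinomial_limit(self):
        pi = np.array([0.5, 0.3, 0.2])
        mom = dm.dm_moments(50, pi, 1e12)
        assert mom.inflation_factor == pytest.approx(1.0, abs=1e-9)
        expected = 50 * (np.diag(pi) - np.outer(pi, pi))
        np.testing.assert_allclose(mom.covariance, expected, rtol=1e-9)

    def test_covariance_rows_sum_to_zero(self):
        mom = dm.dm_moments(100, np.array([0.5, 0.3, 0.2]), 10.0)
        np.testing.assert_allclose(mom.covariance.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(mom.covariance, mom.covariance.T)

    def test_monte_carlo_agreement(self, rng):
        # empirical covariance of DM draws vs the closed form, 3-SE tolerance
        m, pi, gp, n = 100, np.array([0.5, 0.3, 0.2]), 10.0, 40_000
        draws = np.vstack([rng.multinomial(m, rng.dirichlet(gp * pi))
                           for _ in range(n)])
        mom = dm.dm_moments(m, pi, gp)
        se_mean = np.sqrt(np.diag(mom.covariance) / n)
        np.testing.assert_array_less(np.abs(draws.mean(0) - mom.mean), 3 * se_mean)
        emp_cov = np.cov(draws.T)
        # variance-of-variance approx 2 sigma^4 / n for near-Gaussian summaries
        se_var = np.sqrt(2.0 / n) * np.abs(np.diag(mom.covariance))
        np.testing.assert_array_less(
            np.abs(np.diag(emp_cov) - np.diag(mom.covariance)), 3 * se_var + 1e-9)


class TestParameterization:
    def test_hand_example(self):
        params = dm.convert_parameterization(np.array([2.0, 2.0]))
        np.testing.assert_allclose(params.proportions_by_group["all"], [0.5, 0.5])
        assert params.concentration == pytest.approx(4.0)
        assert params.dispersion == pytest.approx(0.2)

    def test_gamma_plus_one_gives_theta_half(self):
        params = dm.convert_parameterization(np.array([0.25, 0.75]))
        assert params.dispersion == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=6))
    def test_round_trip_identity(self, gamma):
        gamma = np.array(gamma)
        params = dm.convert_parameterization(gamma)
        back = dm.gamma_from_parameters(params)
        np.testing.assert_allclose(back, gamma, rtol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dm.convert_parameterization(np.array([1.0, 0.0]))


class TestGeneLogLikelihood:
    def test_single_sample_equals_pmf(self):
        gene = GeneCounts("g", ["a", "b"], ["s1"], np.array([[3], [2]]))
        pi = np.array([0.6, 0.4])
        params = DMParameters({"A": pi}, 5.0)
        got = dm.gene_log_likelihood(gene, {"s1": "A"}, params)
        assert got == pytest.approx(dm.dm_log_pmf(np.array([3, 2]), pi, 5.0))

    def test_additivity_under_duplication(self, small_gene, two_group_design):
        params = DMParameters({"A": np.array([0.5, 0.3, 0.2]),
                               "B": np.array([0.4, 0.4, 0.2])}, 20.0)
        ll = dm.gene_log_likelihood(small_gene, two_group_design, params)
        doubled = GeneCounts("g2", small_gene.feature_ids,
                             small_gene.sample_ids + [f"{s}x" for s in small_gene.sample_ids],
                             np.hstack([small_gene.counts, small_gene.counts]))
        design2 = dict(two_group_design)
        design2.update({f"{s}x": g for s, g in two_group_design.items()})
        assert dm.gene_log_likelihood(doubled, design2, params) == pytest.approx(2 * ll)

    def test_identical_groups_equal_pooled(self, small_gene, two_group_design):
        pi = np.array([0.5, 0.3, 0.2])
        split = DMParameters({"A": pi, "B": pi}, 10.0)
        pooled = DMParameters({"all": pi}, 10.0)
        a = dm.gene_log_likelihood(small_gene, two_group_design, split)
        b = dm.gene_log_likelihood(small_gene, {s: "all" for s in small_gene.sample_ids}, pooled)
        assert a == pytest.approx(b)

    def test_zero_total_samples_dropped(self, small_gene):
        padded = GeneCounts("g", small_gene.feature_ids,
                            small_gene.sample_ids + ["empty"],
                            np.hstack([small_gene.counts, np.zeros((3, 1), dtype=int)]))
        params = DMParameters({"A": np.array([0.5, 0.3, 0.2])}, 10.0)
        design = {s: "A" for s in padded.sample_ids}
        base = dm.gene_log_likelihood(small_gene, {s: "A" for s in small_gene.sample_ids}, params)
        assert dm.gene_log_likelihood(padded, design, params) == pytest.approx(base)

    def test_missing_group_raises(self, small_gene, two_group_design):
        params = DMParameters({"A": np.array([0.5, 0.3, 0.2])}, 10.0)
        with pytest.raises(ValueError):
            dm.gene_log_likelihood(small_gene, two_group_design, params)


class TestEstimateProportions:
    def test_symmetric_counts_give_half(self):
        counts = np.array([[7, 3, 11], [7, 3, 11]])
        gene = GeneCounts("g", ["a", "b"], ["s1", "s2", "s3"], counts)
        fit = dm.estimate_proportions(gene, {s: "A" for s in gene.sample_ids}, 5.0)
        np.testing.assert_allclose(fit.proportions["A"], [0.5, 0.5], atol=1e-6)

    def test_multinomial_limit_matches_pooled_proportions(self, small_gene):
        grouping = {s: "A" for s in small_gene.sample_ids}
        fit = dm.estimate_proportions(small_gene, grouping, 1e8)
        pooled = small_gene.counts.sum(1) / small_gene.counts.sum()
        np.testing.assert_allclose(fit.proportions["A"], pooled, atol=1e-4)

    def test_beats_barycentric_grid(self, rng):
        # MLE must dominate every point of a 200-step simplex grid
        counts = rng.multinomial(80, [0.5, 0.3, 0.2], size=4).T
        gene = GeneCounts("g", ["a", "b", "c"], [f"s{i}" for i in range(4)], counts)
        grouping = {s: "A" for s in gene.sample_ids}
        fit = dm.estimate_proportions(gene, grouping, 50.0)
        steps = np.linspace(1e-4, 1 - 1e-4, 200)
        best_grid = -np.inf
        for p1 in steps:
            for p2 in steps:
                if p1 + p2 >= 1 - 1e-4:
                    continue
                pi = np.array([p1, p2, 1 - p1 - p2])
                best_grid = max(best_grid, dm._loglik_matrix(counts, pi, 50.0))
        assert fit.loglik >= best_grid - 1e-6

    def test_never_worse_than_initialization(self, rng):
        for _ in range(10):
            counts = rng.multinomial(30, rng.dirichlet(np.ones(3)), size=3).T
            gene = GeneCounts("g", ["a", "b", "c"], ["s1", "s2", "s3"], counts)
            grouping = {s: "A" for s in gene.sample_ids}
            fit = dm.estimate_proportions(gene, grouping, 10.0)
            init = dm._pooled_init(counts)
            assert fit.loglik >= dm._loglik_matrix(counts, init, 10.0) - 1e-9

    def test_feature_relabeling_permutes_estimates(self, small_gene):
        grouping = {s: "A" for s in small_gene.sample_ids}
        fit = dm.estimate_proportions(small_gene, grouping, 25.0)
        perm = [2, 0, 1]
        permuted = GeneCounts("g", [small_gene.feature_ids[i] for i in perm],
                              small_gene.sample_ids, small_gene.counts[perm])
        fit_p = dm.estimate_proportions(permuted, grouping, 25.0)
        np.testing.assert_allclose(fit_p.proportions["A"],
                                   fit.proportions["A"][perm], atol=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-8)
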