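"""Covariance estimation, the marginal/conditional LLR statistic, and the
permutation machinery."""

import math

import numpy as np
import pytest
from scipy import stats

import sourceset as ss
from sourceset import synthetic_sim as sim
from sourceset.llr_testing import (
    EstimatorInfeasibleError,
    _group_covariances,
    chisq_df,
    choose_ridge_eps,
    estimate_cov,
    llr_conditional,
    llr_marginal,
    permutation_statistics,
)


class TestEstimateCov:
    def test_one_gene_hand_computation(self, tiny_data):
        est = estimate_cov(tiny_data, ("g",), "mle")
        assert est.sigma_1[0, 0] == pytest.approx(1.0)
        assert est.sigma_2[0, 0] == pytest.approx(1.0)
        # grand mean 0: pooled = (0 + 4 + 0 + 4)/4 = 2
        assert est.sigma_pooled[0, 0] == pytest.approx(2.0)

    def test_identical_samples_give_equal_estimates(self):
        block = np.array([[1.0, 2.0, -1.0], [0.5, 1.5, 2.5]])
        data = ss.TwoSampleData(
            matrix=np.hstack([block, block]),
            genes=("a", "b"),
            condition=np.array([0, 0, 0, 1, 1, 1]),
        )
        est = estimate_cov(data, ("a", "b"), "mle")
        np.testing.assert_allclose(est.sigma_pooled, est.sigma_1)
        np.testing.assert_allclose(est.sigma_pooled, est.sigma_2)

    def test_ridge_eigenvalue_floor_on_rank_deficient_data(self):
        rng = np.random.default_rng(0)
        data = ss.TwoSampleData(
            matrix=rng.standard_normal((6, 6)),
            genes=tuple("abcdef"),
            condition=np.array([0, 0, 0, 1, 1, 1]),
        )
        est = estimate_cov(data, tuple("abcdef"), "ridge")
        assert est.ridge_eps > 0
        for m in (est.sigma_pooled, est.sigma_1, est.sigma_2):
            assert np.linalg.eigvalsh(m)[0] >= est.ridge_eps - 1e-12

    def test_mle_infeasible_names_component(self):
        rng = np.random.default_rng(1)
        data = ss.TwoSampleData(
            matrix=rng.standard_normal((3, 6)),
            genes=("a", "b", "c"),
            condition=np.array([0, 0, 0, 1, 1, 1]),
        )
        with pytest.raises(EstimatorInfeasibleError, match="'a', 'b', 'c'"):
            estimate_cov(data, ("a", "b", "c"), "mle")


class TestLLRStatistic:
    def test_one_gene_value(self, tiny_data):
        lam = llr_marginal(tiny_data, ("g",), "mle")
        assert lam == pytest.approx(4 * math.log(2), abs=1e-12)

    def test_identical_samples_zero(self):
        block = np.array([[1.0, 2.0, 0.0], [0.5, 1.5, 1.0]])
        data = ss.TwoSampleData(
            matrix=np.hstack([block, block]),
            genes=("a", "b"),
            condition=np.array([0, 0, 0, 1, 1, 1]),
        )
        assert llr_marginal(data, ("a", "b"), "mle") == pytest.approx(0.0, abs=1e-10)

    def test_empty_set_zero(self, tiny_data):
        assert llr_marginal(tiny_data, (), "mle") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_under_mle(self, seed):
        rng = np.random.default_rng(seed)
        data = ss.TwoSampleData(
            matrix=rng.standard_normal((3, 24)),
            genes=("a", "b", "c"),
            condition=np.repeat([0, 1], 12),
        )
        assert llr_marginal(data, ("a", "b", "c"), "mle") >= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_loglikelihood_oracle(self, seed):
        """lambda(A) from log-determinants equals -2 (pooled - per-condition)
        Gaussian log-likelihood evaluated density-by-density."""
        rng = np.random.default_rng(seed)
        d = 1 + seed % 3
        n1, n2 = 9, 12
        x = rng.standard_normal((d, n1 + n2)) + rng.uniform(-1, 1, (d, 1))
        cond = np.array([0] * n1 + [1] * n2)
        data = ss.TwoSampleData(matrix=x, genes=tuple(range(d)), condition=cond)
        lam = llr_marginal(data, tuple(range(d)), "mle")

        pooled, s1, s2 = _group_covariances(x, cond)
        ll0 = stats.multivariate_normal.logpdf(x.T, x.mean(axis=1), pooled,
                                               allow_singular=False).sum()
        ll1 = stats.multivariate_normal.logpdf(
            x[:, :n1].T, x[:, :n1].mean(axis=1), s1).sum()
        ll2 = stats.multivariate_normal.logpdf(
            x[:, n1:].T, x[:, n1:].mean(axis=1), s2).sum()
        assert lam == pytest.approx(-2 * (ll0 - ll1 - ll2), abs=1e-8)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1000.0])
    def test_scale_equivariance_under_mle(self, scale):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 30))
        cond = np.repeat([0, 1], 15)
        base = ss.TwoSampleData(matrix=x, genes=("a", "b", "c"), condition=cond)
        scaled = ss.TwoSampleData(matrix=scale * x, genes=("a", "b", "c"),
                                  condition=cond)
        for nodes in [("a",), ("a", "b"), ("a", "b", "c")]:
            assert llr_marginal(scaled, nodes, "mle") == pytest.approx(
                llr_marginal(base, nodes, "mle"), rel=1e-9)

    def test_conditional_definitions(self, null_data):
        data = null_data(n=25, seed=5)
        lam_c = llr_marginal(data, (5, 6), "mle")
        assert llr_conditional(data, (5, 6), (), "mle") == pytest.approx(lam_c)
        assert llr_conditional(data, (5, 6), (5, 6), "mle") == 0.0
        lam_s = llr_marginal(data, (5,), "mle")
        assert llr_conditional(data, (5, 6), (5,), "mle") == pytest.approx(
            lam_c - lam_s)

    @pytest.mark.parametrize("seed", range(10))
    def test_conditional_nonnegative_under_null_mle(self, null_data, seed):
        data = null_data(n=25, seed=100 + seed)
        assert llr_conditional(data, (5, 8, 9, 10), (5,), "mle") >= -1e-10


class TestChisqDf:
    @pytest.mark.parametrize("p,s,df", [(4, 1, 12), (1, 0, 2), (2, 1, 3)])
    def test_parameter_counting(self, p, s, df):
        assert chisq_df(p, s) == df

    @pytest.mark.parametrize("p,s", [(2, 2), (1, 1), (2, 3), (0, 0), (3, -1)])
    def test_invalid_sizes(self, p, s):
        with pytest.raises(ValueError):
            chisq_df(p, s)


class TestPermutationStatistics:
    def test_seeded_determinism(self, null_data, fixture_dg):
        data = null_data(n=10, seed=3)
        cat = ss.enumerate_components(fixture_dg)
        a = permutation_statistics(data, cat, B=50, seed=9, estimator="ridge")
        b = permutation_statistics(data, cat, B=50, seed=9, estimator="ridge")
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.perm_stats, tb.perm_stats)
            assert ta.p_permutation == tb.p_permutation

    def test_addone_pvalue_bounds(self, null_data, fixture_dg):
        data = null_data(n=10, seed=4)
        cat = ss.enumerate_components(fixture_dg)
        B = 39
        for t in permutation_statistics(data, cat, B=B, seed=1, estimator="ridge"):
            count = int(np.sum(t.perm_stats >= t.lambda_conditional))
            assert t.p_permutation == pytest.approx((1 + count) / (1 + B))
            assert 0 < t.p_permutation <= 1

    def test_conditional_is_clique_minus_separator(self, null_data, fixture_dg):
        data = null_data(n=25, seed=6)
        cat = ss.enumerate_components(fixture_dg)
        for t in permutation_statistics(data, cat, B=10, seed=2, estimator="mle"):
            assert t.lambda_conditional == pytest.approx(
                t.lambda_marginal_clique - t.lambda_marginal_sep)
            if not t.separator:
                assert t.lambda_marginal_sep == 0.0

    def test_warns_when_B_exceeds_label_assignments(self, ref_spec, caplog):
        import logging

        data = sim.sample(ref_spec, ref_spec, 2, 2, seed=0)
        cat = ss.enumerate_components(ss.fixture_graph())
        with caplog.at_level(logging.WARNING, logger="sourceset"):
            tests = permutation_statistics(data, cat, B=20, seed=0,
                                           estimator="ridge")
        assert any("label assignments" in r.getMessage() for r in caplog.records)
        assert len(tests) == cat.m

    def test_null_permutation_pvalues_dominate_uniform(self, ref_spec, fixture_dg):
        """Under exchangeable null data the permutation p-value of a fixed
        component is stochastically >= uniform (at resolution 1/(B+1))."""
        cat = ss.enumerate_components(fixture_dg)
        B, R = 79, 200
        pvals = []
        for r in range(R):
            data = sim.sample(ref_spec, ref_spec, 10, 10, seed=1000 + r)
            tests = permutation_statistics(data, cat, B=B, seed=r,
                                           estimator="ridge")
            pvals.append(tests[0].p_permutation)
        pvals = np.array(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            mc = 2 * math.sqrt(t * (1 - t) / R)
            assert np.mean(pvals <= t) <= t + 1 / (B + 1) + mc


class TestAsymptoticCalibration:
    def _pvalue_matrix(self, ref_spec, fixture_dg, n, R):
        cat = ss.enumerate_components(fixture_dg)
        pmat = np.empty((R, cat.m))
        for r in range(R):
            data = sim.sample(ref_spec, ref_spec, n, n, seed=20_000 + r)
            tests = permutation_statistics(data, cat, B=1, seed=r,
                                           estimator="mle")
            pmat[r] = [t.p_asymptotic for t in tests]
        return cat, pmat

    def test_null_asymptotic_pvalues_uniform_mle_n25(self, ref_spec, fixture_dg):
        """KS distance of the asymptotic p-values from U(0,1) stays below 0.1
        over 500 null datasets at n = 25 for components up to dimension 3.

        The p* = 4 clique needs more samples for the chi-square reference to
        settle (finite-sample LLR inflation) and is checked at n = 100 below.
        """
        cat, pmat = self._pvalue_matrix(ref_spec, fixture_dg, 25, 500)
        for j, (_, c, _) in enumerate(cat.components):
            if len(c) <= 3:
                assert stats.kstest(pmat[:, j], "uniform").statistic < 0.1

    def test_null_asymptotic_pvalues_uniform_mle_n100(self, ref_spec, fixture_dg):
        """At n = 100 every component's asymptotic p-value is uniform
        (KS < 0.1 over 500 null datasets), including the p* = 4 clique."""
        cat, pmat = self._pvalue_matrix(ref_spec, fixture_dg, 100, 500)
        for j in range(cat.m):
            assert stats.kstest(pmat[:, j], "uniform").statistic < 0.1

    def test_null_ridge_rejection_rate_conservative(self, ref_spec, fixture_dg):
        """Per-component rejection at nominal 0.05 under ridge stays within a
        simultaneous Monte-Carlo bound (Bonferroni z over the m components)."""
        cat = ss.enumerate_components(fixture_dg)
        B, R = 99, 300
        reject = np.zeros(cat.m)
        for r in range(R):
            data = sim.sample(ref_spec, ref_spec, 10, 10, seed=40_000 + r)
            tests = permutation_statistics(data, cat, B=B, seed=r,
                                           estimator="ridge")
            reject += [t.p_permutation <= 0.05 for t in tests]
        z = stats.norm.isf(0.05 / cat.m)  # simultaneous over the m components
        bound = 0.05 + z * math.sqrt(0.05 * 0.95 / R)
        assert np.all(reject / R <= bound)


class TestRidgeRule:
    def test_eps_frozen_and_shared(self, ref_spec, fixture_dg):
        data = sim.sample(ref_spec, ref_spec, 5, 5, seed=8)
        cliques = list(fixture_dg.cliques)
        eps = choose_ridge_eps(data, cliques)
        assert eps > 0
        est = estimate_cov(data, (5, 8, 9, 10), "ridge", ridge_eps=eps)
        assert est.ridge_eps == eps

    def test_eps_scales_with_data_variance(self, ref_spec, fixture_dg):
        data = sim.sample(ref_spec, ref_spec, 5, 5, seed=8)
        scaled = ss.TwoSampleData(matrix=10 * data.matrix, genes=data.genes,
                                  condition=data.condition)
        cliques = list(fixture_dg.cliques)
        ratio = choose_ridge_eps(scaled, cliques) / choose_ridge_eps(data, cliques)
        assert ratio == pytest.approx(100.0, rel=0.5)
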