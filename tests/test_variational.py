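import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsbm import (
    BlockAssignment,
    ParameterBox,
    VariationalPosterior,
    WeightedGraph,
    WSBMParams,
    align_labels,
    complete_loglik,
    elbo,
    exact_loglik,
    fit_vem,
    permute_matrix,
    sample_wsbm,
    sufficient_stats,
    update_tau,
    update_theta_pi,
    ye_chen_update,
)
from wsbm.variational import FitConfig, SufficientStats

from conftest import random_params


class TestElbo:
    def test_one_hot_equals_completed_loglik(self, small_graph, small_params):
        graph, z = small_graph
        tau = z.onehot()
        expected = complete_loglik(graph, z, small_params) + np.log(
            small_params.theta
        )[z.z].sum()
        assert elbo(graph, tau, small_params) == pytest.approx(expected, abs=1e-9)

    def test_uniform_tau_hand_value(self):
        """Two isolated vertices, all pi = 1/2, uniform theta and tau.

        The pair term is 2 log(1/2) for the two non-edges; the entropy and
        mixing terms cancel exactly, so J = -2 log 2.
        """
        graph = WeightedGraph(X=np.zeros((2, 2)), Y=np.zeros((2, 2)))
        params = WSBMParams(
            theta=[0.5, 0.5],
            pi=np.full((2, 2), 0.5),
            alpha=np.ones((2, 2)),
            beta=np.ones((2, 2)),
        )
        tau = np.full((2, 2), 0.5)
        assert elbo(graph, tau, params) == pytest.approx(-2 * np.log(2), abs=1e-12)

    def test_lower_bounds_exact_loglik(self, small_params):
        graph, _ = sample_wsbm(small_params, 5, seed=21)
        L2 = exact_loglik(graph, small_params)
        rng = np.random.default_rng(0)
        for _ in range(10):
            tau = rng.dirichlet(np.ones(2), size=5)
            assert elbo(graph, tau, small_params) <= L2 + 1e-9


class TestUpdateTau:
    def test_isolated_vertex_returns_prior(self):
        graph = WeightedGraph(X=np.zeros((1, 1)), Y=np.zeros((1, 1)))
        params = WSBMParams(
            theta=[0.3, 0.7],
            pi=np.full((2, 2), 0.5),
            alpha=np.ones((2, 2)),
            beta=np.ones((2, 2)),
        )
        tau = update_tau(graph, np.full((1, 2), 0.5), params, damping=0.0)
        np.testing.assert_allclose(tau.tau[0], [0.3, 0.7], atol=1e-9)

    def test_single_block_fixed_point(self, small_graph):
        graph, _ = small_graph
        params = WSBMParams(theta=[1.0], pi=[[0.5]], alpha=[[2.0]], beta=[[1.0]])
        tau = update_tau(graph, np.ones((graph.n, 1)), params)
        np.testing.assert_array_equal(tau.tau, np.ones((graph.n, 1)))

    def test_recovers_labels_in_separated_setting(self, two_class):
        graph, z = sample_wsbm(two_class, 100, seed=2)
        tau = update_tau(graph, z.onehot(), two_class, damping=0.0)
        assert np.array_equal(tau.hard_assignment(), z.z)

    def test_rows_stay_on_simplex(self, small_graph, small_params):
        graph, _ = small_graph
        rng = np.random.default_rng(5)
        tau0 = rng.dirichlet(np.ones(2), size=graph.n)
        tau = update_tau(graph, tau0, small_params).tau
        assert np.all(tau >= 0) and np.all(tau <= 1)
        np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-12)


class TestUpdateThetaPi:
    def test_uniform_tau_gives_uniform_theta(self):
        graph = WeightedGraph(X=np.zeros((2, 2)), Y=np.zeros((2, 2)))
        theta, _ = update_theta_pi(graph, np.full((2, 2), 0.5))
        np.testing.assert_allclose(theta, [0.5, 0.5], atol=1e-12)

    def test_hard_tau_recovers_empirical_frequencies(self, small_params):
        graph, z = sample_wsbm(small_params, 30, seed=13)
        _, pi = update_theta_pi(graph, z.onehot())
        # independent direct count
        for q in range(2):
            for l in range(2):
                edges = pairs = 0
                for i in range(30):
                    for j in range(30):
                        if i != j and z.z[i] == q and z.z[j] == l:
                            pairs += 1
                            edges += graph.X[i, j] == 1
                assert pi[q, l] == pytest.approx(edges / pairs, abs=1e-10)

    def test_saturated_graph_is_zeta_clipped(self):
        n = 6
        X = np.ones((n, n)) - np.eye(n)
        graph = WeightedGraph(X=X, Y=X * 2.0)
        zeta = 1e-6
        _, pi = update_theta_pi(graph, np.full((n, 2), 0.5), zeta=zeta)
        np.testing.assert_allclose(pi, 1 - zeta, atol=1e-15)


class TestYeChen:
    def test_worked_value_two_weights(self):
        """Weights {1, e} with unit tau-weights: alpha = 2(1+e)/(e-1)."""
        e = np.e
        stats = SufficientStats(
            W=np.array([[2.0]]),
            U=np.array([[1.0 + e]]),
            V=np.array([[1.0]]),
            S=np.array([[e]]),
        )
        alpha, beta, flags = ye_chen_update(stats)
        assert alpha[0, 0] == pytest.approx(2 * (1 + e) / (e - 1), abs=1e-12)
        assert beta[0, 0] == pytest.approx(4 / (e - 1), abs=1e-12)
        assert not flags["degenerate"].any() and not flags["empty"].any()

    def test_identical_weights_take_fallback(self):
        # y = 2 for every edge: W S - V U = 0 exactly
        y = 2.0
        W = 5.0
        stats = SufficientStats(
            W=np.array([[W]]),
            U=np.array([[W * y]]),
            V=np.array([[W * np.log(y)]]),
            S=np.array([[W * y * np.log(y)]]),
        )
        box = ParameterBox()
        alpha, beta, flags = ye_chen_update(stats, box)
        assert flags["degenerate"][0, 0]
        assert alpha[0, 0] == box.alpha_C  # shape saturates at the box bound

    def test_empty_cell_gets_pooled_estimate(self):
        stats = SufficientStats(
            W=np.array([[2.0, 0.0], [0.0, 0.0]]),
            U=np.array([[1.0 + np.e, 0.0], [0.0, 0.0]]),
            V=np.array([[1.0, 0.0], [0.0, 0.0]]),
            S=np.array([[np.e, 0.0], [0.0, 0.0]]),
        )
        alpha, _, flags = ye_chen_update(stats)
        assert flags["empty"][0, 1]
        assert alpha[0, 1] == pytest.approx(alpha[0, 0])

    def test_consistency_on_iid_gamma_draws(self):
        """Strong consistency: the estimator concentrates at (2, 1)."""
        rng = np.random.default_rng(42)
        m, reps = 10**5, 20
        a_hat, b_hat = [], []
        for _ in range(reps):
            y = rng.gamma(2.0, 1.0, size=m)
            stats = SufficientStats(
                W=np.array([[float(m)]]),
                U=np.array([[y.sum()]]),
                V=np.array([[np.log(y).sum()]]),
                S=np.array([[(y * np.log(y)).sum()]]),
            )
            alpha, beta, _ = ye_chen_update(stats)
            a_hat.append(alpha[0, 0])
            b_hat.append(beta[0, 0])
        se_a = np.std(a_hat, ddof=1) / np.sqrt(reps)
        se_b = np.std(b_hat, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(a_hat) - 2.0) < 3 * se_a + 1e-3
        assert abs(np.mean(b_hat) - 1.0) < 3 * se_b + 1e-3


class TestFitVem:
    def test_single_block_matches_exact_loglik(self, small_graph):
        graph, _ = small_graph
        res = fit_vem(graph, 1, FitConfig(restarts=1), seed=0)
        assert res.params.theta[0] == pytest.approx(1.0)
        assert res.params.pi[0, 0] == pytest.approx(graph.density(), abs=1e-9)
        # with one block the bound is tight: J = L2 at the fitted params
        assert res.elbo == pytest.approx(
            exact_loglik(graph, res.params), abs=1e-8
        )

    def test_elbo_trace_nondecreasing(self, two_class, quick_fit):
        graph, _ = sample_wsbm(two_class, 60, seed=3)
        res = fit_vem(graph, 2, quick_fit, seed=1)
        increments = np.diff(res.elbo_trace)
        assert increments.min() >= -1e-8

    def test_fit_is_deterministic_given_seed(self, two_class, quick_fit):
        graph, _ = sample_wsbm(two_class, 40, seed=8)
        r1 = fit_vem(graph, 2, quick_fit, seed=5)
        r2 = fit_vem(graph, 2, quick_fit, seed=5)
        np.testing.assert_array_equal(r1.tau, r2.tau)
        assert r1.elbo == r2.elbo

    def test_elbo_invariant_under_block_relabeling(self, small_params, quick_fit):
        """Permuting tau columns together with the parameters leaves J fixed."""
        graph, _ = sample_wsbm(small_params, 40, seed=17)
        res = fit_vem(graph, 2, quick_fit, seed=2)
        sigma = np.array([1, 0])
        J_perm = elbo(graph, res.tau[:, [1, 0]], small_params.permuted(sigma))
        J_orig = elbo(graph, res.tau, small_params)
        assert J_perm == pytest.approx(J_orig, abs=1e-9)

    def test_summary_mentions_key_quantities(self, two_class, quick_fit):
        graph, _ = sample_wsbm(two_class, 50, seed=4)
        res = fit_vem(graph, 2, quick_fit, seed=0)
        text = res.summary()
        assert "ELBO" in text and "theta" in text and "rate (beta)" in text


class TestAlignment:
    def test_identity_when_already_aligned(self, two_class):
        _, z = sample_wsbm(two_class, 30, seed=2)
        sigma = align_labels(z.z, z)
        np.testing.assert_array_equal(sigma, [0, 1])

    def test_recovers_transposition(self, two_class):
        _, z = sample_wsbm(two_class, 30, seed=2)
        swapped = 1 - z.z
        sigma = align_labels(swapped, z)
        np.testing.assert_array_equal(sigma, [1, 0])
        assert np.array_equal(sigma[swapped], z.z)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, size=20)
        ref = BlockAssignment(z=rng.integers(0, 3, size=20), Q=3)
        sigma = align_labels(labels, ref)
        best = min(
            int(np.sum(np.asarray(perm)[labels] != ref.z))
            for perm in itertools.permutations(range(3))
        )
        assert int(np.sum(sigma[labels] != ref.z)) == best

    def test_permute_matrix_convention(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = permute_matrix(M, np.array([1, 0]))
        np.testing.assert_array_equal(out, [[4.0, 3.0], [2.0, 1.0]])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6), q=st.integers(1, 3))
def test_update_tau_preserves_simplex_property(seed, q):
    """For arbitrary graphs and block counts the updated tau is a valid posterior."""
    rng = np.random.default_rng(seed)
    params = random_params(rng, q)
    graph, _ = sample_wsbm(params, 8, seed=seed)
    tau0 = rng.dirichlet(np.ones(q), size=8)
    tau = update_tau(graph, tau0, params)
    assert isinstance(tau, VariationalPosterior)
    np.testing.assert_allclose(tau.tau.sum(axis=1), 1.0, atol=1e-10)


def test_sufficient_stats_zero_mass_coupling(small_graph):
    graph, _ = small_graph
    tau = np.zeros((graph.n, 2))
    tau[:, 0] = 1.0
    stats = sufficient_stats(graph, tau)
    assert stats.W[1, 1] == 0
    assert stats.U[1, 1] == 0 and stats.V[1, 1] == 0 and stats.S[1, 1] == 0
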