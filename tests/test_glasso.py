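import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.core import ValidationError
from symptomnet.glasso import ebic, lambda_path


def admm_glasso(S, lam, rho=1.0, iters=4000):
    """Independent ADMM solver for the off-diagonal-penalized graphical
    lasso (generic convex-optimizer oracle, no coordinate descent)."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    offmask = ~np.eye(p, dtype=bool)
    for _ in range(iters):
        w, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta_eig = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        Theta = (Q * theta_eig) @ Q.T
        A = Theta + U
        Z = A.copy()
        Z[offmask] = np.sign(A[offmask]) * np.maximum(np.abs(A[offmask]) - lam / rho, 0)
        U = U + Theta - Z
    return Z


def random_correlation(p, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, 2 * p))
    C = A @ A.T / (2 * p)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


class TestGlassoFit:
    def test_saturation_gives_diagonal_precision(self):
        S = random_correlation(4, 0)
        lam = np.abs(S - np.eye(4)).max() + 0.01
        theta = sn.glasso_fit(S, lam)
        W = sn.partials_from_precision(theta)
        assert np.all(W == 0)

    def test_two_node_partial_equals_marginal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        theta = sn.glasso_fit(S, 1e-6, tol=1e-10)
        W = sn.partials_from_precision(theta)
        assert W[0, 1] == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("p,seed,lam", [(3, 1, 0.05), (5, 2, 0.05),
                                            (5, 3, 0.2), (4, 4, 0.1)])
    def test_matches_admm_oracle(self, p, seed, lam):
        S = random_correlation(p, seed)
        mine = sn.glasso_fit(S, lam, tol=1e-10)
        oracle = admm_glasso(S, lam)
        assert np.abs(mine - oracle).max() < 1e-5

    def test_tolerance_self_consistency(self):
        S = random_correlation(8, 5)
        a = sn.glasso_fit(S, 0.1, tol=1e-4)
        b = sn.glasso_fit(S, 0.1, tol=1e-6)
        wa, wb = sn.partials_from_precision(a), sn.partials_from_precision(b)
        assert np.abs(wa - wb).max() <= 1e-3

    def test_non_psd_input_rejected(self):
        V = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValidationError, match="positive semidefinite"):
            sn.glasso_fit(V, 0.1)

    def test_non_positive_penalty_rejected(self):
        with pytest.raises(ValidationError):
            sn.glasso_fit(np.eye(3), 0.0)


class TestPartialsFromPrecision:
    def test_diagonal_precision_gives_zero_weights(self):
        assert np.all(sn.partials_from_precision(np.diag([2.0, 3.0, 1.0])) == 0)

    def test_two_by_two_hand_value(self):
        theta = np.array([[1.0, -0.5], [-0.5, 1.0]])
        W = sn.partials_from_precision(theta)
        assert W[0, 1] == pytest.approx(0.5)

    def test_matches_recursive_partial_correlation_oracle(self):
        # textbook recursion: r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))
        R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        theta = np.linalg.inv(R)
        W = sn.partials_from_precision(theta)

        def partial(i, j, k):
            return (R[i, j] - R[i, k] * R[j, k]) / np.sqrt(
                (1 - R[i, k] ** 2) * (1 - R[j, k] ** 2)
            )

        assert W[0, 1] == pytest.approx(partial(0, 1, 2), abs=1e-12)
        assert W[0, 2] == pytest.approx(partial(0, 2, 1), abs=1e-12)
        assert W[1, 2] == pytest.approx(partial(1, 2, 0), abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValidationError):
            sn.partials_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEBIC:
    def test_empty_model_is_pure_deviance(self):
        S = random_correlation(4, 7)
        theta = np.diag(1.0 / np.diag(S))
        val = ebic(theta, S, n=200, gamma=0.5)
        sign, logdet = np.linalg.slogdet(theta)
        ll = 0.5 * 200 * (logdet - np.trace(S @ theta) + 4)
        assert val == pytest.approx(-2 * ll)

    def test_linear_in_gamma(self):
        S = random_correlation(5, 8)
        theta = sn.glasso_fit(S, 0.05)
        E = (np.abs(sn.partials_from_precision(theta)[np.triu_indices(5, 1)])
             > 1e-8).sum()
        d = ebic(theta, S, 100, 1.0) - ebic(theta, S, 100, 0.5)
        assert d == pytest.approx(4 * E * 0.5 * np.log(5))

    def test_identity_case_is_zero(self):
        assert ebic(np.eye(2), np.eye(2), n=100, gamma=0.5) == pytest.approx(0.0)


class TestEBICGlassoSelect:
    def test_identity_input_selects_empty_network(self):
        net = sn.ebicglasso_select(np.eye(6), n=500)
        assert net.n_edges() == 0

    def test_deterministic(self, block_table):
        S = sn.nearest_psd(sn.spearman_matrix(block_table))
        a = sn.ebicglasso_select(S, n=block_table.n)
        b = sn.ebicglasso_select(S, n=block_table.n)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.lambda_selected == b.lambda_selected

    def test_edge_count_non_increasing_in_gamma(self, block_table):
        S = sn.nearest_psd(sn.spearman_matrix(block_table))
        counts = [
            sn.ebicglasso_select(S, n=block_table.n, gamma=g).n_edges()
            for g in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_path_invariants(self, block_table):
        S = sn.nearest_psd(sn.spearman_matrix(block_table))
        lams = lambda_path(S.values, 25, 0.01)
        counts = []
        for lam in lams:
            theta = sn.glasso_fit(S.values, lam)
            assert np.linalg.eigvalsh(theta)[0] > 0
            W = sn.partials_from_precision(theta)
            assert np.abs(W).max() <= 1.0
            np.testing.assert_allclose(W, W.T, atol=1e-10)
            counts.append((np.abs(W[np.triu_indices(10, 1)]) > 1e-8).sum())
        # E non-increasing as lambda increases (path is decreasing here)
        assert all(a <= b + 1 for a, b in zip(counts, counts[1:]))


class TestDensity:
    @pytest.mark.parametrize("m,E,pct", [(18, 85, 55.56), (21, 114, 54.29)])
    def test_reference_density_values(self, m, E, pct):
        rng = np.random.default_rng(0)
        W = np.zeros((m, m))
        iu = np.triu_indices(m, 1)
        pick = rng.choice(len(iu[0]), size=E, replace=False)
        W[iu[0][pick], iu[1][pick]] = 0.3
        W = W + W.T
        net = sn.NetworkModel([f"n{i}" for i in range(m)], W)
        d = sn.density(net)
        assert d.n_edges == E
        assert round(d.percent, 2) == pct

    def test_empty_network_zero_density(self):
        net = sn.NetworkModel(["a", "b", "c"], np.zeros((3, 3)))
        assert sn.density(net).fraction == 0.0

    def test_single_node_rejected(self):
        net = sn.NetworkModel(["a"], np.zeros((1, 1)))
        with pytest.raises(ValidationError):
            sn.density(net)


class TestEstimateNetworks:
    def test_no_covariates_identical_networks(self, block_table,
                                              fast_net_config):
        un, adj = sn.estimate_networks(block_table, covariates=[],
                                       config=fast_net_config)
        np.testing.assert_array_equal(un.weights, adj.weights)

    def test_covariate_nodes_appended(self):
        truth = sn.make_cluster_precision(6, [3, 3], seed=1)
        rng = np.random.default_rng(2)
        cov = pd.DataFrame({
            "active": (rng.random(400) < 0.5).astype(int),
            "years": rng.lognormal(1.2, 0.8, 400),
            "otherwise": (rng.random(400) < 0.2).astype(int),
        })
        tab = sn.sample_likert(truth, 400, covariate_design=cov, seed=3)
        un, adj = sn.estimate_networks(
            tab, covariates=["active", "years", "otherwise"],
            config=sn.NetworkConfig(n_lambdas=30),
        )
        assert un.m == 6 and adj.m == 9
        assert sn.density(adj).possible == 9 * 8 // 2

    def test_confound_absorbed_by_covariate_node(self):
        # a covariate drives two items with no direct edge between them:
        # conditioning on it shrinks the spurious symptom-symptom edge
        truth = sn.make_cluster_precision(6, [3, 3], 0.20, 0.0, 0.0, seed=2)
        truth.covariate_effects = {"active_stage": {0: 0.8, 3: 0.8}}
        rng = np.random.default_rng(5)
        cov = pd.DataFrame(
            {"active_stage": (rng.random(1500) < 0.5).astype(int)})
        tab = sn.sample_likert(truth, 1500, covariate_design=cov, seed=6)
        un, adj = sn.estimate_networks(tab, covariates=["active_stage"],
                                       config=sn.NetworkConfig(n_lambdas=40))
        assert abs(adj.weights[0, 3]) <= abs(un.weights[0, 3])
        assert abs(un.weights[0, 3]) > 0.05  # the confounded edge exists

    def test_unknown_covariate_rejected(self, block_table):
        with pytest.raises(ValidationError, match="nope"):
            sn.estimate_networks(block_table, covariates=["nope"])
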