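import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.centrality import CentralityTable
from symptomnet.core import NetworkModel, ValidationError


def net_from_edges(m, edges, names=None):
    W = np.zeros((m, m))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return NetworkModel(names or [f"n{i}" for i in range(m)], W)


def floyd_warshall_centrality(W):
    """Brute-force oracle: all-pairs shortest paths with path counting
    on edge lengths 1/|w| (no Dijkstra, no library calls)."""
    m = W.shape[0]
    INF = np.inf
    D = np.full((m, m), INF)
    np.fill_diagonal(D, 0.0)
    counts = np.zeros((m, m))
    np.fill_diagonal(counts, 1.0)
    for i in range(m):
        for j in range(m):
            if i != j and W[i, j] != 0:
                D[i, j] = 1.0 / abs(W[i, j])
                counts[i, j] = 1.0
    # Floyd-Warshall with shortest-path multiplicity
    for k in range(m):
        for i in range(m):
            for j in range(m):
                if i == j or i == k or j == k:
                    continue
                alt = D[i, k] + D[k, j]
                if not np.isfinite(alt):
                    continue
                if alt < D[i, j] - 1e-12:
                    D[i, j] = alt
                    counts[i, j] = counts[i, k] * counts[k, j]
                elif np.isfinite(D[i, j]) and abs(alt - D[i, j]) <= 1e-12:
                    counts[i, j] += counts[i, k] * counts[k, j]
    closeness = np.zeros(m)
    for i in range(m):
        d = np.delete(D[i], i)
        finite = d[np.isfinite(d)]
        closeness[i] = (m - 1) / finite.sum() if finite.sum() > 0 else 0.0
    betweenness = np.zeros(m)
    for v in range(m):
        for s in range(m):
            for t in range(s + 1, m):
                if v in (s, t) or not np.isfinite(D[s, t]):
                    continue
                if abs(D[s, v] + D[v, t] - D[s, t]) <= 1e-12:
                    betweenness[v] += counts[s, v] * counts[v, t] / counts[s, t]
    return closeness, betweenness


class TestStrengthAndEI:
    def test_star_network(self):
        net = net_from_edges(5, [(0, j, 0.5) for j in range(1, 5)])
        s = sn.strength(net)
        assert s[0] == pytest.approx(2.0)
        np.testing.assert_allclose(s[1:], 0.5)

    def test_negative_weight_contributes_absolute_value(self):
        net = net_from_edges(3, [(0, 1, -0.3)])
        assert sn.strength(net)[0] == pytest.approx(0.3)

    def test_matches_rowsum_oracle(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(-0.5, 0.5, (18, 18))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        net = NetworkModel([f"n{i}" for i in range(18)], W)
        np.testing.assert_allclose(sn.strength(net), np.abs(W).sum(1))
        np.testing.assert_allclose(sn.expected_influence(net), W.sum(1))

    def test_ei_equals_strength_on_positive_network(self, block_table,
                                                    fast_net_config):
        net = sn.estimate_networks(block_table, config=fast_net_config)[0]
        if np.all(net.weights >= 0):
            np.testing.assert_allclose(
                sn.expected_influence(net), sn.strength(net)
            )

    def test_mixed_signs_cancel_in_ei_not_strength(self):
        net = net_from_edges(3, [(0, 1, 0.4), (0, 2, -0.4)])
        assert sn.expected_influence(net)[0] == pytest.approx(0.0)
        assert sn.strength(net)[0] == pytest.approx(0.8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        W = rng.uniform(-0.4, 0.4, (8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        net = NetworkModel(list("abcdefgh"), W)
        perm = rng.permutation(8)
        net2 = NetworkModel([net.node_names[i] for i in perm],
                            W[np.ix_(perm, perm)])
        np.testing.assert_allclose(sn.strength(net2), sn.strength(net)[perm])

    def test_removing_edge_never_increases_strength(self):
        net = net_from_edges(4, [(0, 1, 0.5), (1, 2, 0.3), (2, 3, 0.2)])
        s_before = sn.strength(net)
        W = net.weights.copy()
        W[1, 2] = W[2, 1] = 0.0
        s_after = sn.strength(NetworkModel(net.node_names, W))
        assert np.all(s_after <= s_before + 1e-12)


class TestShortestPathMetrics:
    def test_three_node_path_hand_dijkstra(self):
        # A-B-C with both edges 0.5: lengths 2 each, d(A,C)=4
        net = net_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)], names=list("ABC"))
        clo, bet, connected = sn.shortest_path_metrics(net)
        assert connected
        assert clo[0] == pytest.approx(2 / (2 + 4))
        assert clo[1] == pytest.approx(2 / (2 + 2))
        assert bet[1] == pytest.approx(1.0)
        assert bet[0] == bet[2] == 0.0

    def test_equal_weight_triangle_symmetry(self):
        net = net_from_edges(3, [(0, 1, 0.4), (1, 2, 0.4), (0, 2, 0.4)])
        clo, bet, _ = sn.shortest_path_metrics(net)
        np.testing.assert_allclose(clo, clo[0])
        np.testing.assert_allclose(bet, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.1, 0.6, (10, 10)) * (rng.random((10, 10)) < 0.4)
        W = np.triu(W, 1)
        W = W + W.T
        net = NetworkModel([f"n{i}" for i in range(10)], W)
        clo, bet, _ = sn.shortest_path_metrics(net)
        oc, ob = floyd_warshall_centrality(W)
        np.testing.assert_allclose(clo, oc, atol=1e-8)
        np.testing.assert_allclose(bet, ob, atol=1e-8)

    def test_disconnected_network_flagged(self):
        net = net_from_edges(4, [(0, 1, 0.5)])
        clo, bet, connected = sn.shortest_path_metrics(net)
        assert not connected
        assert clo[2] == 0.0  # isolated node

    def test_removing_edge_never_shortens_distances(self):
        from scipy.sparse.csgraph import dijkstra
        net = net_from_edges(5, [(0, 1, 0.5), (1, 2, 0.4), (0, 2, 0.1),
                                 (2, 3, 0.3), (3, 4, 0.5)])
        def dists(net):
            L = np.zeros((5, 5))
            mask = net.edge_mask()
            L[mask] = 1 / np.abs(net.weights[mask])
            return dijkstra(L, directed=False)
        d0 = dists(net)
        W = net.weights.copy()
        W[0, 2] = W[2, 0] = 0
        d1 = dists(NetworkModel(net.node_names, W))
        assert np.all(d1 >= d0 - 1e-12)


class TestStandardize:
    def test_two_nodes_hand_value(self):
        df = pd.DataFrame(
            {"strength": [1.0, 3.0], "closeness": [0.1, 0.2],
             "betweenness": [0.0, 1.0], "expected_influence": [1.0, 3.0]},
            index=["a", "b"],
        )
        out = sn.standardize(CentralityTable(table=df))
        np.testing.assert_allclose(
            out.z("strength"), [-np.sqrt(0.5), np.sqrt(0.5)]
        )

    def test_degenerate_index_flagged(self):
        df = pd.DataFrame(
            {"strength": [2.0, 2.0, 2.0], "closeness": [1, 2, 3.0],
             "betweenness": [0, 1, 2.0], "expected_influence": [2.0, 2.0, 2.0]},
            index=list("abc"),
        )
        out = sn.standardize(CentralityTable(table=df))
        assert np.all(out.z("strength") == 0)
        assert "strength" in out.flags["degenerate_indices"]

    def test_z_scores_standardized(self, block_table, fast_net_config):
        net = sn.estimate_networks(block_table, config=fast_net_config)[0]
        out = sn.centrality_table(net)
        for idx in ("strength", "closeness"):
            z = out.z(idx).to_numpy()
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestRankCoreSymptoms:
    def test_reference_strength_ordering(self):
        df = pd.DataFrame(
            {"strength": [4.489, 4.414, 1.0], "closeness": [1, 1, 1.0],
             "betweenness": [0, 0, 0.0], "expected_influence": [4, 4, 1.0]},
            index=["diarrhea", "weight_loss", "anemia"],
        )
        order, tied = sn.rank_core_symptoms(CentralityTable(table=df))
        assert order == ["diarrhea", "weight_loss", "anemia"]
        assert not tied

    def test_ties_break_lexicographically_with_flag(self):
        df = pd.DataFrame(
            {"strength": [2.0, 2.0], "closeness": [1, 1.0],
             "betweenness": [0, 0.0], "expected_influence": [2.0, 2.0]},
            index=["b_item", "a_item"],
        )
        order, tied = sn.rank_core_symptoms(CentralityTable(table=df))
        assert order == ["a_item", "b_item"]
        assert tied


class TestLayout:
    def test_two_nodes_separated_and_centered(self):
        net = net_from_edges(2, [(0, 1, 0.5)])
        lay = sn.fruchterman_reingold(net, seed=1, iterations=100)
        xy = lay.coords[["x", "y"]].to_numpy()
        assert np.linalg.norm(xy[0] - xy[1]) > 0.1
        assert np.abs(xy).max() <= 1.0

    def test_same_seed_identical(self, block_table, fast_net_config):
        net = sn.estimate_networks(block_table, config=fast_net_config)[0]
        a = sn.fruchterman_reingold(net, seed=5)
        b = sn.fruchterman_reingold(net, seed=5)
        pd.testing.assert_frame_equal(a.coords, b.coords)

    def test_clustered_nodes_sit_closer(self):
        # planted 2-cluster network: mean within-cluster distance below
        # mean between-cluster distance, averaged over seeds
        truth = sn.make_cluster_precision(8, [4, 4], 0.3, 0.0, 0.0, seed=0)
        net = NetworkModel([f"n{i}" for i in range(8)], truth.true_partials)
        ratios = []
        for seed in range(10):
            xy = sn.fruchterman_reingold(net, seed=seed).coords.to_numpy()
            within, between = [], []
            for i in range(8):
                for j in range(i + 1, 8):
                    d = np.linalg.norm(xy[i] - xy[j])
                    (within if (i < 4) == (j < 4) else between).append(d)
            ratios.append(np.mean(within) / np.mean(between))
        assert np.mean(ratios) < 1.0
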