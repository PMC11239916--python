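"""Graph metrics, thresholding, null model, and the threshold sweep."""

import numpy as np
import networkx as nx
import pytest

from fcnet import (
    ConnectivityMatrix,
    ThresholdedGraph,
    TopologyError,
    characteristic_path_length,
    clustering_coefficient,
    generate_null,
    node_degree,
    proportional_threshold,
    small_world_index,
    topology_curve,
)
from fcnet.topology import DEFAULT_TAUS

from conftest import random_connectivity


def _graph_from_edges(n, edges, weights=None, mode="binary"):
    w = np.zeros((n, n))
    for idx, (i, j) in enumerate(edges):
        val = 1.0 if weights is None else weights[idx]
        w[i, j] = w[j, i] = val
    return ThresholdedGraph(weights=w, tau=1.0, mode=mode)


def _complete(n, mode="binary"):
    w = np.ones((n, n)) - np.eye(n)
    return ThresholdedGraph(weights=w, tau=1.0, mode=mode)


class TestProportionalThreshold:
    def test_full_retention(self):
        cm = random_connectivity(8, seed=1)
        cm.z[cm.z <= 0] = 0.1  # make all candidates positive
        np.fill_diagonal(cm.z, 0.0)
        g = proportional_threshold(cm, 1.0)
        assert g.n_edges == 8 * 7 // 2

    def test_sort_and_slice_oracle(self):
        # K4 with weights 1..6; tau=1/3 keeps exactly the 6- and 5-edges.
        z = np.zeros((4, 4))
        vals = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for i in range(4):
            for j in range(i + 1, 4):
                z[i, j] = z[j, i] = next(vals)
        cm = ConnectivityMatrix("s", z, list("abcd"))
        g = proportional_threshold(cm, 1 / 3)
        kept = sorted(g.weights[np.triu_indices(4, 1)][
            g.weights[np.triu_indices(4, 1)] > 0])
        assert kept == [5.0, 6.0]

    def test_all_negative_is_an_error(self):
        z = -np.ones((3, 3))
        np.fill_diagonal(z, 0.0)
        cm = ConnectivityMatrix("s", z, list("abc"))
        with pytest.raises(TopologyError, match="no positive"):
            proportional_threshold(cm, 0.5)

    def test_absolute_ranking_recovers_negative_edges(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = -0.9
        z[0, 2] = z[2, 0] = 0.2
        z[1, 2] = z[2, 1] = 0.1
        cm = ConnectivityMatrix("s", z, list("abc"))
        g = proportional_threshold(cm, 1 / 3, negatives="abs")
        assert g.weights[0, 1] == pytest.approx(0.9)  # strongest by |z|

    def test_binary_mode_sets_unit_weights(self):
        cm = random_connectivity(6, seed=2)
        g = proportional_threshold(cm, 0.5, mode="binary")
        vals = np.unique(g.weights)
        assert set(vals) <= {0.0, 1.0}

    def test_edge_count_monotone_in_tau(self, connectivity_16):
        counts = [
            proportional_threshold(connectivity_16, tau, mode="binary").n_edges
            for tau in DEFAULT_TAUS
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_tie_breaking(self):
        z = np.full((4, 4), 0.5)
        np.fill_diagonal(z, 0.0)
        cm = ConnectivityMatrix("s", z, list("abcd"))
        g1 = proportional_threshold(cm, 0.5)
        g2 = proportional_threshold(cm, 0.5)
        np.testing.assert_array_equal(g1.weights, g2.weights)
        # ties broken by ascending (i, j): first 3 upper-tri slots survive
        iu = np.triu_indices(4, 1)
        kept = g1.weights[iu] > 0
        np.testing.assert_array_equal(kept, [True, True, True,
                                             False, False, False])


class TestNodeDegree:
    def test_complete_graph(self):
        np.testing.assert_array_equal(node_degree(_complete(4)), [3, 3, 3, 3])

    def test_star(self):
        g = _graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        np.testing.assert_array_equal(node_degree(g), [3, 1, 1, 1])

    def test_weighted_strength(self):
        g = _graph_from_edges(3, [(0, 1), (0, 2)], weights=[0.3, 0.5],
                              mode="weighted")
        assert node_degree(g)[0] == pytest.approx(0.8)


class TestClustering:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_fully_clustered(self, n):
        _, c = clustering_coefficient(_complete(n))
        assert c == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        g = _graph_from_edges(5, [(0, i) for i in range(1, 5)])
        _, c = clustering_coefficient(g)
        assert c == 0.0

    def test_ring_lattice_closed_form(self):
        # N=20, each node joined to m=2 neighbors per side:
        # C = 3(m-1)/(2(2m-1)) = 3/6 = 0.5
        n, m = 20, 2
        edges = [(i, (i + d) % n) for i in range(n) for d in range(1, m + 1)]
        g = _graph_from_edges(n, edges)
        metrics, c = clustering_coefficient(g)
        assert c == pytest.approx(0.5)
        # cross-check one node by exhaustive triangle enumeration
        adj = g.adjacency
        nbrs = np.flatnonzero(adj[0])
        tri = sum(adj[u, v] for ui, u in enumerate(nbrs)
                  for v in nbrs[ui + 1:])
        k = len(nbrs)
        assert metrics.c[0] == pytest.approx(2 * tri / (k * (k - 1)))

    def test_low_degree_nodes_have_zero_clustering(self):
        g = _graph_from_edges(4, [(0, 1)])
        metrics, _ = clustering_coefficient(g)
        assert metrics.c[0] == 0.0 and metrics.c[2] == 0.0

    def test_onnela_weighted_matches_networkx(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1.0, size=(10, 10))
        w = (w + w.T) / 2
        w[rng.uniform(size=(10, 10)) < 0.5] = 0.0
        w = np.triu(w, 1) + np.triu(w, 1).T
        g = ThresholdedGraph(weights=w, tau=1.0, mode="weighted")
        _, c = clustering_coefficient(g)
        gx = nx.from_numpy_array(w)
        expected = np.mean(list(nx.clustering(gx, weight="weight").values()))
        assert c == pytest.approx(expected, abs=1e-10)


class TestPathLength:
    def test_complete_graph_unit_path(self):
        assert characteristic_path_length(_complete(5)).l == pytest.approx(1.0)

    def test_three_node_path_enumeration(self):
        # path 1-2-3: ordered-pair distances (1,1,1,1,2,2) -> mean 4/3
        g = _graph_from_edges(3, [(0, 1), (1, 2)])
        assert characteristic_path_length(g).l == pytest.approx(4 / 3)

    def test_disjoint_edges_reachable_pairs_rule(self):
        g = _graph_from_edges(4, [(0, 1), (2, 3)])
        res = characteristic_path_length(g)
        assert res.l == pytest.approx(1.0)
        assert res.unreachable_pairs == 8  # of 12 ordered pairs

    def test_weighted_inverse_lengths(self):
        # strong edge (w=2) is shorter than weak edge (w=0.5)
        g = _graph_from_edges(3, [(0, 1), (1, 2)], weights=[2.0, 0.5],
                              mode="weighted")
        res = characteristic_path_length(g)
        # d01=0.5, d12=2, d02=2.5 -> mean = (0.5+2+2.5)/3
        assert res.l == pytest.approx((0.5 + 2.0 + 2.5) / 3)

    def test_edgeless_graph_rejected(self):
        g = ThresholdedGraph(weights=np.zeros((3, 3)), tau=1.0, mode="binary")
        with pytest.raises(TopologyError, match="edgeless"):
            characteristic_path_length(g)


class TestNullModel:
    def _er_graph(self, seed, n=30, p=0.3, mode="binary"):
        gx = nx.gnp_random_graph(n, p, seed=seed)
        w = nx.to_numpy_array(gx)
        if mode == "weighted":
            rng = np.random.default_rng(seed)
            vals = rng.uniform(0.2, 1.0, size=(n, n))
            vals = (vals + vals.T) / 2
            w = w * vals
        return ThresholdedGraph(weights=w, tau=1.0, mode=mode)

    def test_degree_sequence_and_weights_preserved(self):
        g = self._er_graph(seed=1, mode="weighted")
        null = generate_null(g, reps=1, seed=0)
        # regenerate the single replica through the public path and compare
        # the invariants on the ensemble statistics instead: rebuild replica
        # by running with reps and checking weights via a fresh draw
        # (invariants are asserted inside a custom loop below)
        from fcnet.topology import _double_edge_swap
        iu, ju = np.nonzero(np.triu(g.weights, 1))
        edges = np.column_stack([iu, ju])
        rng = np.random.default_rng(3)
        rewired, successes = _double_edge_swap(edges, g.n_nodes, rng,
                                               n_swaps=10 * len(edges),
                                               max_tries=100 * len(edges))
        assert successes > 0
        deg = np.zeros(g.n_nodes, int)
        for u, v in rewired:
            assert u != v
            deg[u] += 1
            deg[v] += 1
        np.testing.assert_array_equal(
            deg, (g.adjacency.sum(axis=1)).astype(int))
        # no duplicate edges
        keys = {(min(u, v), max(u, v)) for u, v in rewired}
        assert len(keys) == len(rewired)

    def test_identical_seed_identical_ensemble(self):
        g = self._er_graph(seed=2)
        a = generate_null(g, reps=5, seed=42)
        b = generate_null(g, reps=5, seed=42)
        np.testing.assert_array_equal(a.c_values, b.c_values)
        np.testing.assert_array_equal(a.l_values, b.l_values)

    def test_er_graph_is_its_own_null(self):
        # Random graphs rewire to statistically identical graphs.
        g = self._er_graph(seed=3, n=60, p=0.3)
        _, c_obs = clustering_coefficient(g)
        null = generate_null(g, reps=20, seed=7)
        assert abs(null.c_rand - c_obs) / c_obs < 0.10

    def test_star_falls_back_to_reshuffle_with_warning(self, caplog):
        g = _graph_from_edges(5, [(0, i) for i in range(1, 5)])
        import logging
        with caplog.at_level(logging.WARNING, logger="fcnet.topology"):
            null = generate_null(g, reps=2, seed=1)
        assert null.fallback_reshuffle_only
        assert any("fell back" in r.message for r in caplog.records)


class TestSmallWorldIndex:
    def test_self_comparison_gives_unit_ratios(self):
        from fcnet.topology import NullEnsemble
        null = NullEnsemble(reps=2, c_values=np.array([0.5, 0.5]),
                            l_values=np.array([2.0, 2.0]), seed=None)
        sw = small_world_index(0.5, 2.0, null)
        assert (sw.gamma, sw.lam, sw.sigma) == (1.0, 1.0, 1.0)

    def test_sigma_is_gamma_over_lambda(self):
        from fcnet.topology import NullEnsemble
        null = NullEnsemble(reps=1, c_values=np.array([0.25]),
                            l_values=np.array([2.0]), seed=None)
        sw = small_world_index(0.5, 2.0, null)
        assert sw.gamma == pytest.approx(2.0)
        assert sw.lam == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(2.0)

    def test_zero_null_means_rejected(self):
        from fcnet.topology import NullEnsemble
        null = NullEnsemble(reps=1, c_values=np.array([0.0]),
                            l_values=np.array([2.0]), seed=None)
        with pytest.raises(TopologyError, match="nonpositive"):
            small_world_index(0.5, 2.0, null)


class TestTopologyCurve:
    def test_default_grid_matches_protocol(self):
        np.testing.assert_allclose(
            DEFAULT_TAUS,
            [0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60])
        assert len(DEFAULT_TAUS) == 9

    def test_constant_curve_auc_rectangle(self):
        taus = np.linspace(0.2, 0.6, 9)
        assert np.trapezoid(np.full(9, 3.0), taus) == pytest.approx(0.4 * 3.0)

    def test_identity_curve_auc_closed_form(self):
        taus = np.linspace(0.2, 0.6, 9)
        assert np.trapezoid(taus, taus) == pytest.approx(
            (0.6**2 - 0.2**2) / 2)

    def test_curve_auc_consistency(self, connectivity_16):
        curve = topology_curve(connectivity_16, reps=0)
        assert curve.auc_c == pytest.approx(
            np.trapezoid(curve.c_curve, curve.taus))
        assert np.all(np.isnan(curve.sigma_curve))

    def test_determinism(self, connectivity_16):
        a = topology_curve(connectivity_16, reps=3, seed=9)
        b = topology_curve(connectivity_16, reps=3, seed=9)
        np.testing.assert_array_equal(a.sigma_curve, b.sigma_curve)
        np.testing.assert_array_equal(a.c_curve, b.c_curve)

    def test_sigma_equals_gamma_over_lambda_entrywise(self, connectivity_16):
        curve = topology_curve(connectivity_16, reps=3, seed=2)
        np.testing.assert_allclose(
            curve.sigma_curve, curve.gamma_curve / curve.lambda_curve)

    def test_errors_annotated_with_tau(self):
        z = -np.ones((4, 4))
        np.fill_diagonal(z, 0.0)
        cm = ConnectivityMatrix("s", z, list("abcd"))
        with pytest.raises(TopologyError, match="tau=0.2"):
            topology_curve(cm, reps=0)
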