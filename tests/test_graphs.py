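"""Tests for sparsity thresholding and binary graph metrics."""
import networkx as nx
import numpy as np
import pytest

import oracles as orc
from dfcstates import graphs as gr
from dfcstates import temporal as tm
from dfcstates import windows as dw


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return gr.BinaryGraph(a, sparsity=2 * len(edges) / (n * (n - 1)))


P3 = graph_from_edges(3, [(0, 1), (1, 2)])
STAR4 = graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
K3 = graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])
K4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


class TestStateNetwork:
    def make_zs(self, z):
        return dw.FisherZSeries("s", np.asarray(z), np.arange(len(z)))

    def test_single_window_is_identity_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        zs = self.make_zs([w, np.ones((3, 3)) - np.eye(3)])
        tl = tm.StateTimeline("s", np.array([1, 2]))
        net = gr.state_network(zs, tl, 1)
        assert np.array_equal(net.mean_z_matrix, w)
        assert net.n_windows_used == 1

    def test_two_window_mean(self):
        a = np.zeros((2, 2)); a[0, 1] = a[1, 0] = 0.2
        b = np.zeros((2, 2)); b[0, 1] = b[1, 0] = 0.4
        zs = self.make_zs([a, b])
        tl = tm.StateTimeline("s", np.array([1, 1]))
        assert gr.state_network(zs, tl, 1).mean_z_matrix[0, 1] == pytest.approx(0.3)

    def test_matches_loop_average_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(20, 5, 5))
        z = (z + z.transpose(0, 2, 1)) / 2
        zs = self.make_zs(z)
        labels = rng.integers(1, 3, size=20)
        tl = tm.StateTimeline("s", labels)
        net = gr.state_network(zs, tl, 2)
        acc = np.zeros((5, 5)); count = 0
        for w, lab in zip(z, labels):
            if lab == 2:
                acc += w; count += 1
        expected = acc / count
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(net.mean_z_matrix, expected, atol=1e-12)

    def test_absent_state_returns_sentinel(self):
        zs = self.make_zs(np.zeros((2, 3, 3)))
        tl = tm.StateTimeline("s", np.array([1, 1]))
        assert gr.state_network(zs, tl, 3) is None


class TestThresholdBySparsity:
    def test_top_k_selection(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(4, 4)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        g = gr.threshold_by_sparsity(w, 0.5)
        assert g.n_edges == 3
        iu = np.triu_indices(4, 1)
        kept = w[iu][g.adjacency[iu] == 1]
        assert set(np.round(kept, 12)) == set(np.round(np.sort(w[iu])[-3:], 12))

    def test_all_equal_weights_tie_policy(self):
        w = np.ones((4, 4)) - np.eye(4)
        g = gr.threshold_by_sparsity(w, 0.5)
        iu = np.triu_indices(4, 1)
        # row-major order: (0,1), (0,2), (0,3) retained
        assert g.adjacency[iu].tolist() == [1, 1, 1, 0, 0, 0]

    def test_absolute_value_ranking_option(self):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        w[iu] = [-0.9, 0.5, 0.1, 0.2, -0.1, 0.3]
        w = w + w.T
        signed = gr.threshold_by_sparsity(w, 1 / 3)
        assert signed.adjacency[0, 1] == 0  # -0.9 excluded under signed ranking
        absolute = gr.threshold_by_sparsity(w, 1 / 3, use_absolute=True)
        assert absolute.adjacency[0, 1] == 1  # |−0.9| is the largest edge

    def test_ordered_weights_k2(self):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        w[iu] = [6, 5, 4, 3, 2, 1]
        w = w + w.T
        g = gr.threshold_by_sparsity(w, 1 / 3)
        assert g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 1
        assert g.n_edges == 2


class TestDistancesAndEfficiency:
    def test_path_graph(self):
        d = gr.all_pairs_distances(P3)
        assert d[0, 2] == 2 and d[0, 1] == 1

    def test_disconnected_dyads(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        d = gr.all_pairs_distances(g)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_complete_graph_efficiency_one(self):
        assert gr.global_efficiency(K4) == pytest.approx(1.0)

    def test_empty_graph_efficiency_zero(self):
        assert gr.global_efficiency(np.zeros((5, 5), dtype=np.int8)) == 0.0

    def test_p3_hand_enumeration(self):
        assert gr.global_efficiency(P3) == pytest.approx(5 / 6)


class TestNodalMetrics:
    def test_triangle(self):
        assert gr.nodal_clustering(K3, 0) == 1.0
        assert gr.nodal_degree(K3, 0) == 2

    def test_star_center(self):
        assert gr.nodal_clustering(STAR4, 0) == 0.0
        assert gr.nodal_degree(STAR4, 0) == 4
        assert gr.nodal_local_efficiency(STAR4, 0) == 0.0

    def test_k4_local_efficiency(self):
        assert gr.nodal_local_efficiency(K4, 0) == pytest.approx(1.0)
        assert gr.local_efficiency(K4) == pytest.approx(1.0)

    def test_betweenness_examples(self):
        assert gr.betweenness(P3).tolist() == [0.0, 1.0, 0.0]
        assert gr.betweenness(STAR4, 0) == 6.0  # C(4,2) leaf pairs
        # normalization divides by (N-1)(N-2)/2 = 6 for the 5-node star
        assert gr.betweenness(STAR4, 0, normalized=True) == pytest.approx(1.0)


class TestOracleEquivalence:
    """Every metric equals its brute-force oracle on small graphs."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        a = nx.to_numpy_array(g).astype(np.int8)
        _assert_all_metrics_match(a)

    def test_atlas_sample(self):
        atlas = nx.graph_atlas_g()
        graphs = [g for g in atlas[10:300] if nx.is_connected(g)]
        for g in graphs[::5]:
            _assert_all_metrics_match(nx.to_numpy_array(g).astype(np.int8))


def _assert_all_metrics_match(a):
    finite_mine = gr.all_pairs_distances(a)
    finite_orc = orc.bf_distances(a)
    assert np.array_equal(np.isfinite(finite_mine), np.isfinite(finite_orc))
    assert np.array_equal(
        finite_mine[np.isfinite(finite_mine)], finite_orc[np.isfinite(finite_orc)]
    )
    assert gr.global_efficiency(a) == pytest.approx(orc.bf_global_efficiency(a), abs=1e-12)
    assert np.array_equal(gr.nodal_degree(a), orc.bf_degree(a))
    assert np.allclose(gr.nodal_clustering(a), orc.bf_clustering(a), atol=1e-12)
    assert np.allclose(
        gr.nodal_local_efficiency(a), orc.bf_nodal_local_efficiency(a), atol=1e-12
    )
    assert gr.local_efficiency(a) == pytest.approx(orc.bf_local_efficiency(a), abs=1e-12)
    assert np.allclose(gr.betweenness(a), orc.bf_betweenness(a), atol=1e-9)


class TestGraphInvariants:
    def test_global_efficiency_monotone_in_sparsity(self):
        # adding edges can only shorten shortest paths, so GE is
        # nondecreasing over nested thresholded graphs (LE is not: a new
        # neighbor with no ties to the rest of a neighborhood dilutes Ne)
        rng = np.random.default_rng(3)
        w = rng.normal(size=(12, 12)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        ge = []
        for s in np.arange(0.1, 0.85, 0.05):
            g = gr.threshold_by_sparsity(w, float(s))
            ge.append(gr.global_efficiency(g))
        assert np.all(np.diff(ge) >= -1e-12)

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(15, 15)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        for s in (0.1, 0.25, 0.4):
            g = gr.threshold_by_sparsity(w, s)
            assert gr.nodal_degree(g).sum() == 2 * g.n_edges

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_betweenness_equals_pair_separation(self, seed):
        t = nx.random_labeled_tree(9, seed=seed)
        a = nx.to_numpy_array(t).astype(np.int8)
        assert np.allclose(
            gr.betweenness(a), orc.bf_tree_betweenness_by_separation(a), atol=1e-9
        )


class TestSmallWorldness:
    def test_complete_graph_is_exactly_one(self):
        res = gr.small_worldness(K4, n_null=5, seed=0)
        assert res.gamma == 1.0 and res.lam == 1.0 and res.sigma == 1.0

    def test_watts_strogatz_ring_is_small_world(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=1)
        a = nx.to_numpy_array(g).astype(np.int8)
        res = gr.small_worldness(a, n_null=10, seed=2)
        assert res.sigma > 1.0
        assert res.component_coverage == 1.0

    def test_null_against_own_ensemble_is_near_one(self):
        # a graph drawn from the rewiring ensemble has no structure beyond
        # its degree sequence, so sigma averages to ~1; a single draw's
        # clustering fluctuates ~10%, hence the mean over several draws
        base = nx.gnm_random_graph(40, 120, seed=3)
        sigmas = []
        for i in range(5):
            rewired = base.copy()
            nx.double_edge_swap(rewired, nswap=1200, max_tries=100000, seed=40 + i)
            a = nx.to_numpy_array(rewired).astype(np.int8)
            sigmas.append(gr.small_worldness(a, n_null=20, seed=i).sigma)
        assert abs(np.mean(sigmas) - 1.0) < 0.1


class TestMetricAUC:
    def test_constant_curve(self):
        s = gr.default_sparsity_sweep()
        assert len(s) == 31
        assert gr.metric_auc(s, np.ones(31)) == pytest.approx(0.30)

    def test_linear_ramp_triangle_area(self):
        s = gr.default_sparsity_sweep()
        assert gr.metric_auc(s, np.linspace(0, 1, 31)) == pytest.approx(0.15)

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(6)
        s = gr.default_sparsity_sweep()
        v = rng.normal(size=31)
        manual = sum(
            (s[i + 1] - s[i]) * (v[i] + v[i + 1]) / 2 for i in range(30)
        )
        assert gr.metric_auc(s, v) == pytest.approx(manual, abs=1e-12)

    def test_level_mismatch_rejected(self):
        with pytest.raises(gr.GraphInputError):
            gr.metric_auc(gr.default_sparsity_sweep(), np.ones(30))
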