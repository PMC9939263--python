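"""Metric implementations against closed forms and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from agesocnet import metrics

import oracles


def build_graph(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    return g


def dist_edges(edges):
    """Edges with weights converted to the package's distance convention."""
    wmax = max(w for _, _, w in edges)
    return [(i, j, wmax / w) for i, j, w in edges]


class TestWeightToDistance:
    @pytest.mark.parametrize("w,expected", [(2.0, 0.5), (1.0, 1.0), (0.25, 4.0)])
    def test_reciprocal(self, w, expected):
        assert metrics.weight_to_distance(w) == expected

    def test_monotonicity(self):
        assert metrics.weight_to_distance(3.0) < metrics.weight_to_distance(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            metrics.weight_to_distance(0.0)


class TestEigenvector:
    def test_star_hub_has_unique_maximum(self):
        g = nx.star_graph(4)
        scores = metrics.eigenvector_centrality(g)
        assert scores[0] == 1.0
        assert all(scores[v] < 1.0 for v in range(1, 5))

    def test_regular_graph_scores_equal(self):
        g = nx.cycle_graph(6)
        scores = metrics.eigenvector_centrality(g)
        assert np.allclose(list(scores.values()), 1.0)

    def test_weighted_toy_matches_power_iteration_oracle(self):
        edges = [(0, 1, 2.0), (1, 2, 1.0), (2, 3, 0.5), (3, 4, 3.0), (0, 4, 1.5)]
        g = build_graph(5, edges)
        scores = metrics.eigenvector_centrality(g)
        expected = oracles.eigenvector(5, edges)
        assert np.allclose([scores[v] for v in range(5)], expected, atol=1e-8)

    def test_isolate_scores_zero(self):
        g = build_graph(4, [(0, 1, 1.0), (1, 2, 1.0)])
        scores = metrics.eigenvector_centrality(g)
        assert scores[3] == 0.0

    def test_empty_graph(self):
        assert metrics.eigenvector_centrality(nx.Graph()) == {}


class TestShortestPathMetrics:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(3)
        btw, clo = metrics.shortest_path_metrics(g)
        assert [btw[v] for v in range(3)] == [0.0, 1.0, 0.0]
        assert clo[1] == pytest.approx(1.0)

    def test_star_hub_betweenness(self):
        g = nx.star_graph(4)
        btw, _ = metrics.shortest_path_metrics(g)
        assert btw[0] == 6.0  # C(4,2) leaf pairs

    def test_isolate_closeness_zero(self):
        g = build_graph(3, [(0, 1, 1.0)])
        _, clo = metrics.shortest_path_metrics(g)
        assert clo[2] == 0.0

    def test_random_weighted_graph_matches_brute_force(self):
        rng = np.random.default_rng(9)
        edges = oracles.random_graph(rng, 12, 0.35, weighted=True)
        g = build_graph(12, edges)
        btw, clo = metrics.shortest_path_metrics(g)
        de = dist_edges(edges)
        assert np.allclose(
            [btw[v] for v in range(12)], oracles.betweenness(12, de), atol=1e-9
        )
        assert np.allclose(
            [clo[v] for v in range(12)], oracles.closeness(12, de), atol=1e-9
        )


class TestClustering:
    def test_triangle_all_one(self):
        g = nx.complete_graph(3)
        assert all(v == 1.0 for v in metrics.local_clustering(g).values())

    def test_star_hub_zero(self):
        g = nx.star_graph(4)
        assert metrics.local_clustering(g)[0] == 0.0

    def test_low_degree_nodes_zero(self):
        g = build_graph(3, [(0, 1, 1.0)])
        clu = metrics.local_clustering(g)
        assert clu[0] == clu[2] == 0.0

    def test_toy_graph_matches_triangle_enumeration(self):
        rng = np.random.default_rng(3)
        edges = oracles.random_graph(rng, 10, 0.4, weighted=False)
        g = build_graph(10, edges)
        clu = metrics.local_clustering(g)
        expected = oracles.clustering(10, [(i, j) for i, j, _ in edges])
        assert np.allclose([clu[v] for v in range(10)], expected)


class TestGlobalMetrics:
    def test_complete_graph(self):
        rec = metrics.global_metrics(nx.complete_graph(4))
        assert (rec.mean_degree, rec.diameter, rec.transitivity, rec.density) == (
            3.0,
            1.0,
            1.0,
            1.0,
        )

    def test_path_graph(self):
        rec = metrics.global_metrics(nx.path_graph(3))
        assert rec.mean_degree == pytest.approx(4 / 3)
        assert rec.diameter == 2.0
        assert rec.transitivity == 0.0

    def test_two_disjoint_triangles(self):
        # diameter over connected pairs only
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        rec = metrics.global_metrics(g)
        assert rec.diameter == 1.0
        assert rec.transitivity == 1.0
        assert rec.density == pytest.approx(6 / 15)

    def test_edgeless_graph_flagged(self):
        g = nx.empty_graph(5)
        rec = metrics.global_metrics(g)
        assert rec.diameter == 0.0
        assert rec.edgeless

    def test_single_node_rejected(self):
        with pytest.raises(metrics.DegenerateGraphError):
            metrics.global_metrics(nx.empty_graph(1))

    def test_proportion_old_from_ages(self):
        g = nx.path_graph(4)
        for v, age in zip(g.nodes, (8, 12, 20, 25)):
            g.nodes[v]["age"] = age
        rec = metrics.global_metrics(g, old_threshold=18)
        assert rec.proportion_old == 0.5

    def test_binary_fast_path_agrees_with_graph_path(self):
        rng = np.random.default_rng(12)
        edges = oracles.random_graph(rng, 20, 0.15, weighted=False)
        arr = np.array([(i, j) for i, j, _ in edges])
        fast = metrics.binary_global_metrics(20, arr)
        g = nx.empty_graph(20)
        g.add_edges_from(arr.tolist())
        rec = metrics.global_metrics(g)
        for k in ("mean_degree", "diameter", "transitivity", "density"):
            assert fast[k] == pytest.approx(getattr(rec, k))


class TestInvariantsAndCrossChecks:
    def test_unit_weights_match_binary(self):
        rng = np.random.default_rng(5)
        edges = oracles.random_graph(rng, 15, 0.25, weighted=False)
        g_bin = nx.empty_graph(15)
        g_bin.add_edges_from([(i, j) for i, j, _ in edges])
        g_w = build_graph(15, edges)  # all weights 1.0
        nm_bin = metrics.node_metrics(g_bin).set_index("node")
        nm_w = metrics.node_metrics(g_w).set_index("node")
        for col in metrics.NODE_METRIC_NAMES:
            assert np.allclose(nm_bin[col], nm_w[col], atol=1e-9)

    def test_betweenness_tree_totals(self):
        # on a tree, total betweenness = sum over pairs of intermediate counts
        rng = np.random.default_rng(8)
        for _ in range(5):
            t = nx.random_labeled_tree(12, seed=int(rng.integers(1 << 30)))
            btw, _ = metrics.shortest_path_metrics(t)
            lengths = dict(nx.all_pairs_shortest_path_length(t))
            expected = sum(
                lengths[u][v] - 1 for u in t for v in t if u < v
            )
            assert sum(btw.values()) == pytest.approx(expected)

    def test_bounded_metrics_stay_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            edges = oracles.random_graph(rng, 15, rng.uniform(0.05, 0.5), True)
            g = build_graph(15, edges)
            nm = metrics.node_metrics(g)
            assert nm["closeness"].between(0, 1).all()
            assert nm["clustering"].between(0, 1).all()
            assert (nm["betweenness"] >= 0).all()
            rec = metrics.global_metrics(g)
            assert 0 <= rec.transitivity <= 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        edges = oracles.random_graph(rng, 12, 0.3, weighted=True)
        g = build_graph(12, edges)
        perm = dict(zip(range(12), rng.permutation(12).tolist()))
        h = nx.relabel_nodes(g, perm)
        nm_g = metrics.node_metrics(g).set_index("node")
        nm_h = metrics.node_metrics(h).set_index("node")
        for v in range(12):
            for col in metrics.NODE_METRIC_NAMES:
                assert nm_h.loc[perm[v], col] == pytest.approx(
                    nm_g.loc[v, col], abs=1e-9
                )

    def test_agreement_with_independent_graph_library(self):
        # cross-check unweighted metrics against igraph
        import igraph

        rng = np.random.default_rng(30)
        for _ in range(10):
            edges = oracles.random_graph(rng, 18, rng.uniform(0.1, 0.4), False)
            el = [(i, j) for i, j, _ in edges]
            g = nx.empty_graph(18)
            g.add_edges_from(el)
            ig = igraph.Graph(n=18, edges=el)
            btw, _ = metrics.shortest_path_metrics(g)
            assert np.allclose(
                [btw[v] for v in range(18)], ig.betweenness(), atol=1e-6
            )
            rec = metrics.global_metrics(g)
            assert rec.transitivity == pytest.approx(
                ig.transitivity_undirected(mode="zero"), abs=1e-6
            )
            clu = metrics.local_clustering(g)
            ig_clu = ig.transitivity_local_undirected(mode="zero")
            assert np.allclose([clu[v] for v in range(18)], ig_clu, atol=1e-6)
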