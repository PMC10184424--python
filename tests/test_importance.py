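"""Node-importance scoring against hand calculations and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

import kfcnet as k
from kfcnet.importance import baseline_centrality, extract_key_network, novel_importance

from oracles import CENTRALITY_ORACLES, novel_score


def _net_from_graph(g: nx.Graph, weights=None) -> k.CTPNetwork:
    net = k.CTPNetwork()
    for v in g.nodes:
        w = 1.0 if weights is None else weights[v]
        net.add_node(str(v), {"target"}, weight=w)
    for u, v in g.edges:
        net.add_edge(str(u), str(v), "pp")
    return net


def _random_net(rng, n_max=40, weighted=True):
    n = int(rng.integers(4, n_max))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.3)), seed=int(rng.integers(2**31)))
    weights = {v: float(rng.uniform(1.0, 6.0)) if weighted else 1.0 for v in g.nodes}
    return _net_from_graph(g, weights)


def _adj(net: k.CTPNetwork):
    return {v: set(net.graph.neighbors(v)) for v in net.graph.nodes}


class TestNovelImportance:
    def test_path_graph_hand_values(self):
        """A-B-C with unit weights, alpha=0.5: centre 1.0, ends 0.375."""
        net = k.CTPNetwork()
        for v in "ABC":
            net.add_node(v, {"target"})
        net.add_edge("A", "B", "pp")
        net.add_edge("B", "C", "pp")
        scores = novel_importance(net, alpha=0.5, max_depth=3)
        assert scores["B"] == pytest.approx(1.0)
        assert scores["A"] == pytest.approx(0.375)
        assert scores["C"] == pytest.approx(0.375)

    def test_isolated_node_scores_zero(self):
        net = k.CTPNetwork()
        net.add_node("X", {"target"})
        net.add_node("A", {"target"})
        net.add_node("B", {"target"})
        net.add_edge("A", "B", "pp")
        assert novel_importance(net)["X"] == 0.0

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5, 2.0])
    def test_alpha_outside_open_interval_raises(self, alpha):
        net = k.CTPNetwork()
        net.add_node("A", {"target"})
        with pytest.raises(ValueError, match="alpha"):
            novel_importance(net, alpha=alpha)

    def test_matches_bfs_oracle_on_weighted_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            net = _random_net(rng)
            alpha = float(rng.uniform(0.2, 0.8))
            depth = int(rng.integers(1, 5))
            got = novel_importance(net, alpha=alpha, max_depth=depth)
            weights = {v: net.node_weight(v) for v in net.graph.nodes}
            expected = novel_score(_adj(net), weights, alpha, depth)
            for v in got:
                assert got[v] == pytest.approx(expected[v], rel=1e-12)

    def test_adding_an_edge_never_decreases_the_endpoint_score(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            net = _random_net(rng)
            nodes = sorted(net.graph.nodes)
            u, v = rng.choice(nodes, size=2, replace=False)
            if net.graph.has_edge(u, v):
                continue
            before = novel_importance(net)
            net.add_edge(u, v, "pp")
            after = novel_importance(net)
            assert after[u] >= before[u] - 1e-12
            assert after[v] >= before[v] - 1e-12


class TestBaselines:
    def test_triangle_clustering_and_degree(self):
        net = _net_from_graph(nx.complete_graph(3))
        assert set(baseline_centrality(net, "clustering_coefficient").values()) == {1.0}
        assert set(baseline_centrality(net, "degree").values()) == {2.0}

    def test_star_neighborhood_connectivity(self):
        net = _net_from_graph(nx.star_graph(4))  # centre 0, leaves 1..4
        nc = baseline_centrality(net, "neighborhood_connectivity")
        assert nc["0"] == pytest.approx(1.0)
        assert nc["1"] == pytest.approx(4.0)

    def test_unknown_method_lists_choices(self):
        net = _net_from_graph(nx.path_graph(3))
        with pytest.raises(ValueError, match="radiality"):
            baseline_centrality(net, "pagerank")

    @pytest.mark.parametrize("method", sorted(CENTRALITY_ORACLES))
    def test_matches_naive_oracle_on_random_graphs(self, method):
        rng = np.random.default_rng(hash(method) % 2**31)
        for _ in range(12):
            net = _random_net(rng, weighted=False)
            got = baseline_centrality(net, method)
            expected = CENTRALITY_ORACLES[method](_adj(net))
            for v in got:
                assert got[v] == pytest.approx(expected[v], rel=1e-12), (method, v)


class TestKeyNetwork:
    def test_strictly_above_median_is_kept(self):
        net = _net_from_graph(nx.path_graph(5))
        scores = {str(i): float(i + 1) for i in range(5)}
        res = extract_key_network(net, scores)
        assert res.median == 3.0
        assert res.key_nodes == {"3", "4"}

    def test_all_equal_scores_give_empty_key_set_with_warning(self):
        net = _net_from_graph(nx.path_graph(4))
        with pytest.warns(UserWarning, match="median"):
            res = extract_key_network(net, {v: 1.0 for v in net.graph.nodes})
        assert res.key_nodes == set()
        assert res.key_network.n_nodes() == 0

    def test_missing_scores_rejected(self):
        net = _net_from_graph(nx.path_graph(3))
        with pytest.raises(ValueError, match="missing"):
            extract_key_network(net, {"0": 1.0})

    def test_random_score_maps_match_sort_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            net = _random_net(rng, n_max=25)
            scores = {v: float(rng.normal()) for v in net.graph.nodes}
            res = extract_key_network(net, scores)
            ordered = sorted(scores.values())
            med = float(np.median(ordered))
            assert res.key_nodes == {v for v, s in scores.items() if s > med}

    def test_distinct_scores_retain_at_most_half(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            net = _random_net(rng, n_max=30)
            scores = {v: float(i) for i, v in enumerate(rng.permutation(sorted(net.graph.nodes)))}
            res = extract_key_network(net, scores)
            assert len(res.key_nodes) <= math.ceil(net.n_nodes() / 2)

    def test_avg_shortest_path_is_inverted_before_thresholding(self):
        # path graph: the centre has the smallest mean distance -> most central
        net = _net_from_graph(nx.path_graph(5))
        scores = baseline_centrality(net, "avg_shortest_path")
        res = extract_key_network(net, scores, method="avg_shortest_path")
        assert "2" in res.key_nodes  # centre kept despite having the *lowest* raw value
        assert "0" not in res.key_nodes and "4" not in res.key_nodes

    def test_key_network_is_an_induced_subgraph(self, seed_runs):
        run = seed_runs[0]
        res = run.results["novel"]
        sub = res.key_network
        for u, v in sub.graph.edges:
            assert run.ctp.graph.has_edge(u, v)
        for v in res.key_nodes:
            assert v in sub.graph


class TestPlantedRanking:
    def test_planted_components_rank_better_under_novel_than_degree(self, seed_runs):
        """Tie-aware mean rank of planted components: the weight-propagating
        score places them higher than raw degree in >= 80% of replicates."""
        from scipy.stats import rankdata

        wins = 0
        for run in seed_runs:
            truth = run.dataset.truth_key_components
            nodes = list(run.ctp.graph.nodes)
            novel = run.results["novel"].scores
            deg = run.results["degree"].scores
            rn = dict(zip(nodes, rankdata([-novel[v] for v in nodes], method="average")))
            rd = dict(zip(nodes, rankdata([-deg[v] for v in nodes], method="average")))
            wins += np.mean([rn[c] for c in truth]) < np.mean([rd[c] for c in truth])
        assert wins >= 0.8 * len(seed_runs)
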