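import math

import networkx as nx
import numpy as np
import pytest

from srnanet.centrality import (
    UndefinedMetricError,
    betweenness,
    closeness,
    clustering_coefficient,
    degree,
    metric_vectors,
    node_metrics_table,
)
from srnanet.network import Network, UnknownNodeError

from _oracles import (
    adjacency,
    floyd_warshall,
    oracle_betweenness,
    oracle_closeness,
    oracle_clustering,
    oracle_degree,
)
from conftest import random_network


class TestDegree:
    def test_star_center(self, star5):
        assert degree(star5, "hub") == 4

    def test_directed_split(self):
        net = Network.from_edges([("a", "b"), ("c", "b")], directed=True)
        assert degree(net, "b") == (2, 0)

    def test_unknown_node(self, k3):
        with pytest.raises(UnknownNodeError):
            degree(k3, "zz")

    def test_matches_adjacency_sums(self):
        net = random_network(30, 0.15, seed=2, directed=True)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), True)
        for i, v in enumerate(order):
            assert degree(net, v) == oracle_degree(a, i, True)


class TestCloseness:
    def test_path_graph_values(self, path_abc):
        assert closeness(path_abc, "b") == pytest.approx(1.0)
        assert closeness(path_abc, "a") == pytest.approx(1 / 1.5)

    def test_isolated_node_is_zero(self):
        net = Network.from_edges([("a", "b")], nodes=["z"])
        assert closeness(net, "z") == 0.0

    def test_matches_brute_force_row(self):
        net = random_network(25, 0.2, seed=4)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), False)
        d = floyd_warshall(a)
        for i, v in enumerate(order):
            assert closeness(net, v) == pytest.approx(oracle_closeness(d, i), abs=1e-12)

    def test_directed_uses_outbound_paths(self):
        net = Network.from_edges([("a", "b"), ("b", "c")], directed=True)
        assert closeness(net, "a") == pytest.approx(2 / 3)  # dists 1, 2
        assert closeness(net, "c") == 0.0

    def test_harmonic_variant(self, path_abc):
        # a: neighbors at distance 1 and 2 -> (1 + 1/2) / 2
        assert closeness(path_abc, "a", harmonic=True) == pytest.approx(0.75)


class TestBetweenness:
    def test_path_center_is_one(self, path_abc):
        assert betweenness(path_abc, "b") == pytest.approx(1.0)

    def test_k3_all_zero(self, k3):
        for v in "abc":
            assert betweenness(k3, v) == 0.0

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_geodesic_enumeration(self, directed):
        net = random_network(20, 0.2, seed=6, directed=directed)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), directed)
        d = floyd_warshall(a)
        for i, v in enumerate(order):
            assert betweenness(net, v) == pytest.approx(
                oracle_betweenness(a, d, i, directed), abs=1e-9
            )


class TestClustering:
    def test_k3_is_one(self, k3):
        assert clustering_coefficient(k3, "a") == 1.0

    def test_star_center_is_zero(self, star5):
        assert clustering_coefficient(star5, "hub") == 0.0

    def test_degree_one_is_zero(self, path_abc):
        assert clustering_coefficient(path_abc, "a") == 0.0

    def test_directed_undefined(self):
        net = Network.from_edges([("a", "b")], directed=True)
        with pytest.raises(UndefinedMetricError):
            clustering_coefficient(net, "a")

    def test_matches_triangle_counter(self):
        net = random_network(30, 0.15, seed=8)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), False)
        for i, v in enumerate(order):
            assert clustering_coefficient(net, v) == pytest.approx(
                oracle_clustering(a, i), abs=1e-12
            )


class TestTable:
    def test_k3_means(self, k3):
        table, means = node_metrics_table(k3, ["a", "b", "c"])
        assert means["degree"] == pytest.approx(2.0)
        assert means["clustering_coefficient"] == pytest.approx(1.0)

    def test_empty_list(self, k3):
        table, means = node_metrics_table(k3, [])
        assert len(table) == 0
        assert all(math.isnan(v) for v in means)

    def test_unknown_nodes_listed(self, k3):
        with pytest.raises(UnknownNodeError, match="xx"):
            node_metrics_table(k3, ["a", "xx", "yy"])

    def test_means_equal_oracle_means(self):
        net = random_network(30, 0.15, seed=12)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), False)
        d = floyd_warshall(a)
        picks = order[::3][:10]
        _, means = node_metrics_table(net, picks)
        idx = [order.index(v) for v in picks]
        assert means["closeness"] == pytest.approx(
            np.mean([oracle_closeness(d, i) for i in idx]), abs=1e-12)
        assert means["clustering_coefficient"] == pytest.approx(
            np.mean([oracle_clustering(a, i) for i in idx]), abs=1e-12)


class TestProperties:
    def test_cycle_is_vertex_transitive(self):
        net = Network(nx.relabel_nodes(nx.cycle_graph(9),
                                       {i: f"c{i}" for i in range(9)}))
        table, _ = node_metrics_table(net, net.node_order())
        for col in ("degree", "closeness", "betweenness",
                    "clustering_coefficient"):
            assert table[col].nunique() == 1

    def test_tree_betweenness_sum_identity(self):
        """On trees every geodesic is unique, so the unnormalized
        betweenness total equals sum over pairs of (path length - 1)."""
        g = nx.relabel_nodes(nx.random_labeled_tree(15, seed=3),
                             {i: f"t{i}" for i in range(15)})
        net = Network(g)
        order = net.node_order()
        a, _ = adjacency(order, net.edge_set(), False)
        d = floyd_warshall(a)
        n = len(order)
        norm = (n - 1) * (n - 2) / 2
        total_bet = sum(betweenness(net, v) for v in order) * norm
        pair_sum = sum(d[i, j] - 1 for i in range(n) for j in range(i + 1, n))
        assert total_bet == pytest.approx(pair_sum, abs=1e-9)

    def test_closeness_never_decreases_under_edge_addition_connected(self):
        # reachable-only closeness is monotone under edge addition when the
        # graph stays connected (no new, distant nodes enter the average)
        net = random_network(20, 0.3, seed=14)
        assert nx.is_connected(net.g)
        before = {v: closeness(net, v) for v in net.node_order()}
        u, v = sorted(nx.non_edges(net.g))[0]
        net.g.add_edge(u, v)
        for w in net.node_order():
            assert closeness(net, w) >= before[w] - 1e-12

    def test_harmonic_closeness_monotone_on_fragmented_graph(self):
        # harmonic closeness is monotone even when an edge merges components
        net = random_network(20, 0.1, seed=13)
        before = {v: closeness(net, v, harmonic=True) for v in net.node_order()}
        u, v = sorted(nx.non_edges(net.g))[0]
        net.g.add_edge(u, v)
        for w in net.node_order():
            assert closeness(net, w, harmonic=True) >= before[w] - 1e-12
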