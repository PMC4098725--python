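"""Clustering engines: clique enumeration oracle, CMC merging, MCL
flow invariants, and iterative edge re-weighting."""

import networkx as nx
import numpy as np
import pytest

from cocin.clustering import (
    adjustcd_weights,
    cluster_graph,
    cmc_cluster,
    enumerate_maximal_cliques,
    mcl_cluster,
    mcl_iterates,
    weighted_density,
)
from cocin.errors import ValidationError
from cocin.networks import PPINetwork

from conftest import brute_force_maximal_cliques


def complete(nodes):
    g = nx.Graph()
    g.add_edges_from(
        (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]
    )
    return g


class TestAdjustCD:
    def test_identical_closed_neighborhoods_score_one(self):
        net = PPINetwork.from_edges("s", [("A", "B"), ("A", "C"), ("B", "C")])
        weighted = adjustcd_weights(net, iterations=1)
        assert weighted.weight("A", "B") == pytest.approx(1.0)

    def test_k3_symmetric_weights(self):
        net = PPINetwork.from_edges("s", [("A", "B"), ("B", "C"), ("A", "C")])
        weighted = adjustcd_weights(net, iterations=2)
        weights = {w for _, _, w in weighted.edges()}
        assert len(weights) == 1

    def test_isolated_edge_penalized_as_graph_grows(self):
        """A degree-1--degree-1 edge is pulled below 1 by the
        average-degree penalty, monotonically as the rest grows."""
        def isolated_edge_weight(extra_clique_size):
            net = PPINetwork.from_edges("s", [("A", "B")])
            clique = [f"x{i}" for i in range(extra_clique_size)]
            for i, u in enumerate(clique):
                for v in clique[i + 1 :]:
                    net.add_edge(u, v)
            return adjustcd_weights(net, iterations=1).weight("A", "B")

        w_small, w_mid, w_big = (isolated_edge_weight(k) for k in (3, 5, 8))
        assert 0 < w_big <= w_mid <= w_small <= 1.0

    def test_weights_bounded_random_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = PPINetwork("s")
            for i in range(12):
                for j in range(i + 1, 12):
                    if rng.random() < 0.3:
                        net.add_edge(f"n{i}", f"n{j}")
            for _, _, w in adjustcd_weights(net, iterations=2).edges():
                assert 0.0 < w <= 1.0

    def test_invalid_iterations(self):
        with pytest.raises(ValidationError):
            adjustcd_weights(PPINetwork("s"), iterations=0)


class TestMaximalCliques:
    def test_k4_single_clique(self):
        assert enumerate_maximal_cliques(complete("abcd")) == [("a", "b", "c", "d")]

    def test_two_k4s_sharing_a_vertex(self):
        g = complete("abcd")
        g.add_edges_from(complete("defg").edges)
        cliques = enumerate_maximal_cliques(g, min_size=4)
        assert cliques == [("a", "b", "c", "d"), ("d", "e", "f", "g")]

    def test_exhaustive_oracle_random_graphs(self):
        """Equality with brute-force subset enumeration on 50 random
        graphs of <= 12 nodes."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 13))
            g = nx.Graph()
            g.add_nodes_from(f"n{i}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        g.add_edge(f"n{i}", f"n{j}")
            assert enumerate_maximal_cliques(g) == brute_force_maximal_cliques(g), seed


class TestCMC:
    def test_lone_k5(self):
        cs = cmc_cluster(complete("abcde"), min_size=4)
        assert cs.node_sets() == [frozenset("abcde")]
        assert cs.clusters[0][1] == pytest.approx(1.0)

    def test_two_k4s_sharing_three_nodes_merge(self):
        g = complete("abcd")
        g.add_edges_from(complete("bcde").edges)
        cs = cmc_cluster(g, min_size=4, overlap_threshold=0.5, merge_threshold=0.25)
        assert cs.node_sets() == [frozenset("abcde")]

    def test_two_disjoint_k4s(self):
        g = complete("abcd")
        g.add_edges_from(complete("wxyz").edges)
        cs = cmc_cluster(g, min_size=4)
        assert sorted(cs.node_sets(), key=sorted) == [
            frozenset("abcd"), frozenset("wxyz")
        ]

    def test_every_cluster_contains_a_seed_clique(self):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        for i in range(18):
            for j in range(i + 1, 18):
                if rng.random() < 0.4:
                    g.add_edge(i, j)
        cs = cmc_cluster(g, min_size=3)
        seeds = [set(c) for c in enumerate_maximal_cliques(g, 3)]
        for members, _ in cs:
            assert any(seed <= members for seed in seeds)

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            cmc_cluster(complete("abcd"), overlap_threshold=1.5)
        with pytest.raises(ValidationError):
            cmc_cluster(complete("abcd"), merge_threshold=0.0)


class TestMCL:
    def test_two_disjoint_k5s(self):
        g = complete("abcde")
        g.add_edges_from(complete("vwxyz").edges)
        cs = mcl_cluster(g, inflation=2.0)
        assert sorted(cs.node_sets(), key=sorted) == [
            frozenset("abcde"), frozenset("vwxyz")
        ]

    def test_single_k4(self):
        cs = mcl_cluster(complete("abcd"))
        assert cs.node_sets() == [frozenset("abcd")]

    def test_bridge_between_k6s_splits(self):
        g = complete("abcdef")
        g.add_edges_from(complete("uvwxyz").edges)
        g.add_edge("f", "u")
        cs = mcl_cluster(g, inflation=2.0)
        assert sorted(cs.node_sets(), key=sorted) == [
            frozenset("abcdef"), frozenset("uvwxyz")
        ]

    def test_column_stochastic_every_iteration(self):
        rng = np.random.default_rng(2)
        n = 15
        a = (rng.random((n, n)) < 0.3).astype(float)
        a = np.triu(a, 1)
        a = a + a.T + np.eye(n)
        for m in mcl_iterates(a, inflation=2.0):
            np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_output_partitions_nodes(self):
        rng = np.random.default_rng(9)
        g = nx.Graph()
        g.add_nodes_from(range(20))
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.2:
                    g.add_edge(i, j)
        cs = mcl_cluster(g, min_size=1)
        all_nodes = [n for members in cs.node_sets() for n in members]
        assert sorted(all_nodes) == sorted(g.nodes)
        assert len(all_nodes) == len(set(all_nodes))

    def test_invariant_under_relabeling(self):
        g = complete("abcde")
        g.add_edges_from(complete("vwxyz").edges)
        g.add_edge("a", "v")
        mapping = {u: f"z{i}" for i, u in enumerate("abcdevwxyz")}
        relabeled = nx.relabel_nodes(g, mapping)
        original = {frozenset(mapping[u] for u in c) for c in mcl_cluster(g).node_sets()}
        assert original == set(mcl_cluster(relabeled).node_sets())

    def test_inflation_validation(self):
        with pytest.raises(ValidationError):
            mcl_cluster(complete("abc"), inflation=1.0)


class TestClusterGraph:
    def test_dispatch(self):
        k5 = complete("abcde")
        assert cluster_graph(k5, "cmc", min_size=4).node_sets() == [frozenset("abcde")]
        assert cluster_graph(k5, "mcl").node_sets() == [frozenset("abcde")]

    def test_unknown_engine(self):
        with pytest.raises(ValidationError):
            cluster_graph(complete("abc"), "haco")

    def test_both_engines_recover_planted_cliques_at_zero_noise(self):
        g = complete([f"c1_{i}" for i in range(5)])
        g.add_edges_from(complete([f"c2_{i}" for i in range(6)]).edges)
        expected = {frozenset(f"c1_{i}" for i in range(5)),
                    frozenset(f"c2_{i}" for i in range(6))}
        for engine in ("cmc", "mcl"):
            cs = cluster_graph(g, engine, min_size=4)
            assert set(cs.node_sets()) == expected, engine


def test_weighted_density_definition():
    g = complete("abc")
    g["a"]["b"]["weight"] = 0.5
    # (0.5 + 1 + 1) / 3 pairs
    assert weighted_density(g, "abc") == pytest.approx(2.5 / 3)
    assert weighted_density(g, ["a"]) == 0.0
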