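"""Shared fixtures and independent brute-force oracles.

The oracles deliberately unroll definitions (exhaustive double loops,
subset enumeration) so they stay independent of the implementation
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cocin.homology import OrthologMap
from cocin.interolog import CONSERVED, SHARED
from cocin.networks import ComplexCatalog, PPINetwork


# ---------------------------------------------------------------------------
# Random instance generators (plain numpy RNG; every test passes a seed)
# ---------------------------------------------------------------------------

def random_ppi(rng: np.random.Generator, species: str, n_nodes: int,
               density: float, prefix: str) -> PPINetwork:
    net = PPINetwork(species)
    names = [f"{prefix}{i}" for i in range(n_nodes)]
    for name in names:
        net.add_node(name)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                net.add_edge(names[i], names[j])
    return net


def random_ortholog_map(rng: np.random.Generator, net_a: PPINetwork,
                        net_b: PPINetwork, n_groups: int,
                        max_side: int = 3) -> OrthologMap:
    """Random many-to-many groups drawn from the two node pools."""
    omap = OrthologMap(net_a.species, net_b.species)
    pool_a, pool_b = sorted(net_a.nodes), sorted(net_b.nodes)
    for g in range(n_groups):
        ka = int(rng.integers(0, max_side + 1))
        kb = int(rng.integers(0, max_side + 1))
        if ka == 0 and kb == 0:
            ka = 1
        ma = list(rng.choice(pool_a, size=min(ka, len(pool_a)), replace=False)) if ka else []
        mb = list(rng.choice(pool_b, size=min(kb, len(pool_b)), replace=False)) if kb else []
        if not ma and not mb:
            continue
        omap.add_group(f"G{g}", ma, mb)
    return omap


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_interolog(g1: PPINetwork, g2: PPINetwork, omap: OrthologMap,
                          include_shared: bool = True,
                          restrict: bool = True,
                          prune_isolated: bool = True):
    """Literal unrolling of the interolog definitions.

    Nodes: all theta pairs (restricted to network membership); edges:
    exhaustive double loop over all node pairs testing (p,r) in E1 and
    (q,s) in E2, plus shared-protein edges for pairs sharing exactly
    one coordinate.  Returns (node_set, {edge -> provenance}).
    """
    theta = set()
    for ma, mb in omap.groups.values():
        for p in ma:
            for q in mb:
                theta.add((p, q))
    if restrict:
        theta = {(p, q) for p, q in theta
                 if g1.has_node(p) and g2.has_node(q)}

    edges = {}
    for u, v in itertools.combinations(sorted(theta), 2):
        (p, q), (r, s) = u, v
        if g1.has_edge(p, r) and g2.has_edge(q, s):
            edges[(u, v)] = CONSERVED
        elif include_shared and (p == r) != (q == s):
            edges[(u, v)] = SHARED

    nodes = set(theta)
    if prune_isolated:
        touched = {n for e in edges for n in e}
        nodes &= touched
    return nodes, edges


def brute_force_maximal_cliques(graph, min_size: int = 1):
    """Maximal cliques by exhaustive subset enumeration (n <= ~14)."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v)
                   for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    return sorted(tuple(sorted(c)) for c in maximal if len(c) >= min_size)


# ---------------------------------------------------------------------------
# Small fixed fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_pair():
    """The minimal interolog instance: one conserved interaction."""
    g1 = PPINetwork.from_edges("yeast", [("p1", "p2")])
    g2 = PPINetwork.from_edges("human", [("q1", "q2")])
    omap = OrthologMap("yeast", "human")
    omap.add_group("G1", ["p1"], ["q1"])
    omap.add_group("G2", ["p2"], ["q2"])
    return g1, g2, omap


@pytest.fixture
def shared_protein_pair():
    """Two species-1 proteins both orthologous to the same q1."""
    g1 = PPINetwork.from_edges("yeast", [("p1", "p2")])
    g2 = PPINetwork.from_edges("human", [("q1", "q2")])
    omap = OrthologMap("yeast", "human")
    omap.add_group("G1", ["p1", "p2"], ["q1"])
    return g1, g2, omap


@pytest.fixture
def two_complex_catalogs():
    cat_a = ComplexCatalog("yeast")
    cat_a.add("c1", ["A", "B"])
    cat_a.add("c2", ["A"])
    cat_b = ComplexCatalog("human")
    cat_b.add("h1", ["X", "Y", "Z"])
    return cat_a, cat_b
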