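"""Dense-cluster detection: clique-merging (CMC-style), Markov
clustering (MCL), and iterative edge-reliability weighting.

All engines accept a :class:`~cocin.networks.PPINetwork`, an
:class:`~cocin.interolog.InterologNetwork`, or a bare
``networkx.Graph`` whose edges carry a ``weight`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Hashable, Iterable

import networkx as nx
import numpy as np

from .errors import ValidationError
from .interolog import InterologNetwork
from .networks import PPINetwork

logger = logging.getLogger(__name__)


def as_graph(g) -> nx.Graph:
    if isinstance(g, (PPINetwork, InterologNetwork)):
        return g.graph
    if isinstance(g, nx.Graph):
        return g
    raise ValidationError(f"cannot cluster object of type {type(g).__name__}")


def _source_label(g) -> str:
    if isinstance(g, PPINetwork):
        return g.species
    if isinstance(g, InterologNetwork):
        return f"{g.species_a}x{g.species_b}"
    return "graph"


def _weight(g: nx.Graph, u, v) -> float:
    return g[u][v].get("weight", 1.0)


def weighted_density(g: nx.Graph, nodes: Iterable[Hashable]) -> float:
    """Sum of internal edge weights over the number of node pairs."""
    members = list(nodes)
    n = len(members)
    if n < 2:
        return 0.0
    total = sum(
        _weight(g, u, v)
        for i, u in enumerate(members)
        for v in members[i + 1 :]
        if g.has_edge(u, v)
    )
    return total / (n * (n - 1) / 2)


@dataclass
class ClusterSet:
    """Clusters with their weighted-density scores plus run metadata."""

    clusters: list[tuple[frozenset, float]]
    engine: str
    source: str = "graph"
    params: dict = field(default_factory=dict)

    def node_sets(self) -> list[frozenset]:
        return [c for c, _ in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


# ---------------------------------------------------------------------------
# Iterative Czekanowski-Dice edge reliability (AdjustCD / "ICD" scoring)
# ---------------------------------------------------------------------------

def adjustcd_weights(net: PPINetwork, iterations: int = 2) -> PPINetwork:
    """Re-weight edges by iterated Czekanowski-Dice neighborhood overlap.

    Round k scores edge (u, v) as

        w_k(u, v) = sum_{x in N[u] & N[v]} (w_{k-1}(x,u) + w_{k-1}(x,v))
                    / (lam_u + S_u + lam_v + S_v)

    with closed neighborhoods N[.], S_u = sum_{x in N[u]} w_{k-1}(x, u),
    w(u, u) = 1 fixed, and lam_u = max(0, mean_S - S_u) penalizing nodes
    with fewer (or less reliable) interactions than average.  Weights
    stay in (0, 1]; two nodes with identical closed neighborhoods and
    at-least-average degree score 1.0.
    """
    if iterations < 1:
        raise ValidationError(f"iterations must be >= 1, got {iterations}")
    g = net.graph
    nodes = sorted(g.nodes)
    closed = {u: frozenset(g[u]) | {u} for u in nodes}
    edges = [tuple(sorted((u, v))) for u, v in g.edges]

    def key(x, y):
        return (x, y) if x <= y else (y, x)

    prev = {e: 1.0 for e in edges}

    def w_prev(x, u):
        return 1.0 if x == u else prev.get(key(x, u), 0.0)

    current = prev
    for _ in range(iterations):
        strength = {u: sum(w_prev(x, u) for x in closed[u]) for u in nodes}
        mean_s = sum(strength.values()) / len(nodes) if nodes else 0.0
        lam = {u: max(0.0, mean_s - strength[u]) for u in nodes}
        current = {}
        for u, v in edges:
            common = closed[u] & closed[v]
            num = sum(w_prev(x, u) + w_prev(x, v) for x in common)
            den = lam[u] + strength[u] + lam[v] + strength[v]
            current[(u, v)] = num / den if den > 0 else 0.0
        prev = current

    out = PPINetwork(net.species)
    out.graph.add_nodes_from(nodes)
    for (u, v), w in current.items():
        out.add_edge(u, v, min(max(w, 1e-12), 1.0))
    return out


# ---------------------------------------------------------------------------
# Maximal cliques and CMC-style merging
# ---------------------------------------------------------------------------

def enumerate_maximal_cliques(g, min_size: int = 1) -> list[tuple]:
    """All maximal cliques of size >= min_size, each sorted, the list
    sorted lexicographically."""
    graph = as_graph(g)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= min_size]
    return sorted(cliques)


def _interconnectivity(g: nx.Graph, core: set, extension: set) -> float:
    """Mean edge weight between ``extension`` and ``core`` over all
    cross pairs (the merge acceptance score)."""
    if not core or not extension:
        return 0.0
    total = sum(
        _weight(g, u, v) for u in extension for v in core if g.has_edge(u, v)
    )
    return total / (len(core) * len(extension))


def cmc_cluster(
    g,
    min_size: int = 4,
    overlap_threshold: float = 0.5,
    merge_threshold: float = 0.25,
) -> ClusterSet:
    """Cluster by ranking maximal cliques by weighted density and
    merging highly overlapping ones.

    Cliques of size >= min_size are ranked by descending weighted
    density (ties broken lexicographically).  Scanning in rank order,
    each lower-ranked clique B overlapping the current cluster A by
    |A & B| / |B| >= overlap_threshold is merged into A when the
    inter-connectivity between B \\ A and A reaches merge_threshold,
    and discarded otherwise.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValidationError(f"overlap_threshold must be in (0, 1], got {overlap_threshold}")
    if not 0.0 < merge_threshold <= 1.0:
        raise ValidationError(f"merge_threshold must be in (0, 1], got {merge_threshold}")
    graph = as_graph(g)
    seeds = enumerate_maximal_cliques(graph, min_size)
    ranked = sorted(seeds, key=lambda c: (-weighted_density(graph, c), c))
    clusters: list[set] = [set(c) for c in ranked]
    removed = [False] * len(clusters)

    for i in range(len(clusters)):
        if removed[i]:
            continue
        for j in range(i + 1, len(clusters)):
            if removed[j]:
                continue
            overlap = clusters[i] & clusters[j]
            if not overlap:
                continue
            if len(overlap) / len(clusters[j]) >= overlap_threshold:
                extension = clusters[j] - clusters[i]
                if not extension:
                    removed[j] = True  # wholly contained
                elif _interconnectivity(graph, clusters[i], extension) >= merge_threshold:
                    clusters[i] |= extension
                    removed[j] = True
                else:
                    removed[j] = True  # highly overlapping but weakly connected

    seen: set[frozenset] = set()
    out: list[tuple[frozenset, float]] = []
    for keep, members in zip(removed, clusters):
        if keep or len(members) < min_size:
            continue
        fs = frozenset(members)
        if fs in seen:
            continue
        seen.add(fs)
        out.append((fs, weighted_density(graph, fs)))
    out.sort(key=lambda t: (-t[1], sorted(map(str, t[0]))))
    return ClusterSet(
        out,
        engine="cmc",
        source=_source_label(g),
        params={
            "min_size": min_size,
            "overlap_threshold": overlap_threshold,
            "merge_threshold": merge_threshold,
        },
    )


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_iterates(
    matrix: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
):
    """Yield successive column-stochastic MCL matrices (after each
    expansion + inflation + prune + renormalize round) until the max
    entrywise change drops below ``tolerance``."""
    m = matrix / matrix.sum(axis=0, keepdims=True)
    for _ in range(max_iterations):
        nxt = np.linalg.matrix_power(m, expansion)
        nxt = np.power(nxt, inflation)
        nxt[nxt < prune_threshold] = 0.0
        col = nxt.sum(axis=0)
        dead = col == 0.0
        if dead.any():  # a fully pruned column restarts at its own node
            nxt[dead, dead] = 1.0
            col = nxt.sum(axis=0)
        nxt /= col
        delta = float(np.abs(nxt - m).max())
        m = nxt
        yield m
        if delta < tolerance:
            return
    logger.warning("MCL did not converge within %d iterations", max_iterations)


def mcl_cluster(
    g,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loop_weight: float = 1.0,
    prune_threshold: float = 1e-5,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
    min_size: int = 1,
) -> ClusterSet:
    """Markov clustering: random-walk flow is expanded (matrix power)
    and inflated (entrywise power, column renormalization) until it
    decomposes into attractor basins; every node lands in exactly one
    cluster, and clusters below ``min_size`` are dropped from the
    reported set."""
    if inflation <= 1.0:
        raise ValidationError(f"inflation must be > 1, got {inflation}")
    if expansion < 2:
        raise ValidationError(f"expansion must be >= 2, got {expansion}")
    graph = as_graph(g)
    nodes = sorted(graph.nodes)
    if not nodes:
        return ClusterSet([], engine="mcl", source=_source_label(g))
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    a[np.diag_indices(n)] += self_loop_weight

    m = a
    for m in mcl_iterates(
        a,
        inflation=inflation,
        expansion=expansion,
        prune_threshold=prune_threshold,
        max_iterations=max_iterations,
        tolerance=tolerance,
    ):
        pass

    # Attractor basins: connected components of the limit flow's support.
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    components = [frozenset(nodes[i] for i in comp) for comp in nx.connected_components(support)]

    out = [
        (comp, weighted_density(graph, comp))
        for comp in components
        if len(comp) >= min_size
    ]
    out.sort(key=lambda t: (-t[1], sorted(map(str, t[0]))))
    return ClusterSet(
        out,
        engine="mcl",
        source=_source_label(g),
        params={
            "inflation": inflation,
            "expansion": expansion,
            "self_loop_weight": self_loop_weight,
            "prune_threshold": prune_threshold,
            "max_iterations": max_iterations,
            "tolerance": tolerance,
            "min_size": min_size,
        },
    )


def cluster_graph(g, engine: str, **params) -> ClusterSet:
    """Dispatch to a clustering engine ("cmc" or "mcl")."""
    if engine == "cmc":
        return cmc_cluster(g, **params)
    if engine == "mcl":
        return mcl_cluster(g, **params)
    raise ValidationError(f"unknown clustering engine {engine!r}")
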