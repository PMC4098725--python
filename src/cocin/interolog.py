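"""Interolog network construction and back-projection.

Given PPI networks G1(V1, E1) and G2(V2, E2) of two species and a
many-to-many homology correspondence theta induced by ortholog groups,
the interolog network GI has

* nodes: homologous pairs (p, q) with p in V1, q in V2, (p, q) in theta;
* conserved-interaction edges: {(p, q), (r, s)} whenever (p, r) in E1
  and (q, s) in E2 — i.e. the interaction is conserved in both species
  (an *interolog*);
* shared-protein edges (optional): {(p, q), (p, s)} or {(p, q), (r, q)}
  linking two nodes that reuse the same protein of either species.
  These wire the paralog expansions of many-to-many groups into one
  cluster-friendly neighborhood.

Dense clusters of GI back-project to a complex in each species by
taking the first (side "a") or second (side "b") coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Iterator

import networkx as nx

from .errors import ValidationError
from .homology import OrthologMap
from .networks import PPINetwork

CONSERVED = "conserved_interaction"
SHARED = "shared_protein"

Node = tuple[str, str]


@dataclass
class InterologNetwork:
    """Graph over homologous protein pairs; edges tagged with provenance."""

    species_a: str
    species_b: str
    graph: nx.Graph = field(default_factory=nx.Graph, compare=False)

    @property
    def nodes(self) -> set[Node]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[Node, Node, float, str]]:
        """Canonicalized, sorted (u, v, weight, provenance) tuples."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = (u, v) if u <= v else (v, u)
            out.append((a, b, d["weight"], d["provenance"]))
        return iter(sorted(out))

    def conserved_edges(self) -> list[tuple[Node, Node]]:
        return [(u, v) for u, v, _, tag in self.edges() if tag == CONSERVED]

    def without_shared_protein_edges(self) -> "InterologNetwork":
        """Copy keeping only conserved-interaction edges (same node set)."""
        out = InterologNetwork(self.species_a, self.species_b)
        out.graph.add_nodes_from(self.graph.nodes)
        for u, v, w, tag in self.edges():
            if tag == CONSERVED:
                out.graph.add_edge(u, v, weight=w, provenance=tag)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InterologNetwork):
            return NotImplemented
        return (
            (self.species_a, self.species_b) == (other.species_a, other.species_b)
            and self.nodes == other.nodes
            and list(self.edges()) == list(other.edges())
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"InterologNetwork({self.species_a!r}x{self.species_b!r}, "
            f"{self.n_nodes} nodes, {self.n_edges} edges)"
        )


def _check_species(g1: PPINetwork, g2: PPINetwork, omap: OrthologMap) -> None:
    if g1.species != omap.species_a or g2.species != omap.species_b:
        raise ValidationError(
            f"species mismatch: networks are ({g1.species!r}, {g2.species!r}) "
            f"but ortholog map spans ({omap.species_a!r}, {omap.species_b!r})"
        )


def build_interolog_network(
    g1: PPINetwork,
    g2: PPINetwork,
    omap: OrthologMap,
    *,
    include_shared_protein_edges: bool = True,
    restrict_to_networks: bool = True,
    prune_isolated: bool = True,
) -> InterologNetwork:
    """Construct GI from (G1, G2, theta).

    ``restrict_to_networks`` limits nodes to theta pairs whose proteins
    occur in the respective networks; ``prune_isolated`` drops degree-0
    nodes afterwards.  Conserved edges get weight w1(p,r) * w2(q,s);
    shared-protein edges get weight 1.0.  Output is independent of the
    iteration order of the inputs.
    """
    _check_species(g1, g2, omap)
    restrict_a = g1.nodes if restrict_to_networks else None
    restrict_b = g2.nodes if restrict_to_networks else None
    theta = omap.theta_pairs(restrict_a, restrict_b)

    net = InterologNetwork(g1.species, g2.species)
    for node in sorted(theta):
        net.graph.add_node(node)

    # Conserved interactions: walk E1 once, pair each endpoint's
    # counterparts, and test the orthologous edge in E2.
    counterparts: dict[str, frozenset] = {}
    for p, q in theta:
        counterparts.setdefault(p, frozenset())
    by_p: dict[str, set[str]] = {}
    for p, q in theta:
        by_p.setdefault(p, set()).add(q)
    for p, r, w1 in g1.edges():
        qs = by_p.get(p)
        ss = by_p.get(r)
        if not qs or not ss:
            continue
        for q in sorted(qs):
            for s in sorted(ss):
                if q == s:
                    continue  # (q, q) can never be an E2 edge
                if g2.has_edge(q, s):
                    w = w1 * g2.weight(q, s)
                    w = min(max(w, 1e-12), 1.0)
                    net.graph.add_edge((p, q), (r, s), weight=w, provenance=CONSERVED)

    if include_shared_protein_edges:
        by_a: dict[str, list[Node]] = {}
        by_b: dict[str, list[Node]] = {}
        for node in sorted(theta):
            by_a.setdefault(node[0], []).append(node)
            by_b.setdefault(node[1], []).append(node)
        for bucket in list(by_a.values()) + list(by_b.values()):
            for i, u in enumerate(bucket):
                for v in bucket[i + 1 :]:
                    if not net.graph.has_edge(u, v):
                        net.graph.add_edge(u, v, weight=1.0, provenance=SHARED)

    if prune_isolated:
        isolated = [n for n in net.graph.nodes if net.graph.degree(n) == 0]
        net.graph.remove_nodes_from(isolated)
    return net


def conserved_subnetwork(
    g_target: PPINetwork, g_other: PPINetwork, omap: OrthologMap
) -> PPINetwork:
    """Edges of ``g_target`` whose orthologous counterparts interact in
    ``g_other``; nodes are the endpoints of the retained edges.

    ``g_target`` may be either species of the map; orientation is
    resolved from its species label.
    """
    side = omap.side_for_species(g_target.species)
    other_side = "b" if side == "a" else "a"
    if g_other.species != (omap.species_b if side == "a" else omap.species_a):
        raise ValidationError(
            f"other network species {g_other.species!r} does not match "
            f"the map's {other_side!r} side"
        )
    out = PPINetwork(g_target.species)
    for p, r, w in g_target.edges():
        qs = omap.counterparts(p, side) & g_other.nodes
        ss = omap.counterparts(r, side) & g_other.nodes
        if any(g_other.has_edge(q, s) for q in qs for s in ss if q != s):
            out.add_edge(p, r, w)
    return out


def project_cluster(cluster: Iterable[Node], side: str) -> frozenset:
    """Per-species protein set of an interolog cluster (its side-a or
    side-b coordinates); paralogous nodes may collapse, so the
    projection can be smaller than the cluster."""
    nodes = list(cluster)
    if not nodes:
        raise ValidationError("cannot project an empty cluster")
    if side not in ("a", "b"):
        raise ValidationError(f"side must be 'a' or 'b', got {side!r}")
    idx = 0 if side == "a" else 1
    return frozenset(node[idx] for node in nodes)
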