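"""Species-level PPI networks and curated complex catalogs.

A :class:`PPINetwork` is an undirected simple graph over protein
identifiers (opaque, case-sensitive strings) whose edges carry a
reliability weight in ``(0, 1]``.  A :class:`ComplexCatalog` is a named
collection of protein complexes of one species, each complex a multiset
of member proteins (curated catalogs are plain sets; multiplicities
arise from repeat-count columns or programmatic construction).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import networkx as nx

from .errors import ValidationError


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an undirected edge so (a, b) and (b, a) compare equal."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PPINetwork:
    """Undirected simple interaction network of one species.

    Invariants: no self-loops, no duplicate edges, every edge endpoint
    is a node, every weight lies in ``(0, 1]`` (unweighted edges get
    weight 1.0).
    """

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph, compare=False)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        species: str,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network from (a, b) or (a, b, weight) tuples."""
        net = cls(species)
        net.graph.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                a, b = edge
                net.add_edge(a, b)
            else:
                a, b, w = edge
                net.add_edge(a, b, w)
        return net

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> bool:
        """Add an edge, dropping self-loops and keeping the max weight
        among duplicates.  Returns True when the graph gained the edge."""
        if a == b:
            return False
        if not 0.0 < weight <= 1.0:
            raise ValidationError(
                f"edge weight must lie in (0, 1], got {weight!r} for ({a}, {b})"
            )
        data = self.graph.get_edge_data(a, b)
        if data is None:
            self.graph.add_edge(a, b, weight=float(weight))
            return True
        if weight > data["weight"]:
            data["weight"] = float(weight)
        return False

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate canonicalized (a, b, weight) triples in sorted order."""
        triples = (
            (*canonical_edge(a, b), d["weight"])
            for a, b, d in self.graph.edges(data=True)
        )
        return iter(sorted(triples))

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        data = self.graph.get_edge_data(a, b)
        if data is None:
            raise KeyError(f"no edge ({a}, {b}) in {self.species} network")
        return data["weight"]

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph[node])

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.species, self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.nodes == other.nodes
            and list(self.edges()) == list(other.edges())
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PPINetwork({self.species!r}, {self.n_nodes} nodes, "
            f"{self.n_edges} edges)"
        )


@dataclass
class ComplexCatalog:
    """Named protein complexes of one species (benchmark or predicted)."""

    species: str
    complexes: dict[str, Counter] = field(default_factory=dict)

    def add(self, complex_id: str, members: Iterable[str] | Counter) -> None:
        if complex_id in self.complexes:
            raise ValidationError(f"duplicate complex id {complex_id!r}")
        counts = Counter(members) if not isinstance(members, Counter) else Counter(members)
        if not counts:
            raise ValidationError(f"complex {complex_id!r} has no members")
        self.complexes[complex_id] = counts

    def members(self, complex_id: str) -> Counter:
        return self.complexes[complex_id]

    def size(self, complex_id: str) -> int:
        """Total member count, counting multiplicity."""
        return sum(self.complexes[complex_id].values())

    def filter_min_size(self, min_size: int) -> "ComplexCatalog":
        """Catalog restricted to complexes of size >= min_size."""
        kept = ComplexCatalog(self.species)
        for cid in sorted(self.complexes):
            if self.size(cid) >= min_size:
                kept.complexes[cid] = Counter(self.complexes[cid])
        return kept

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.complexes))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ComplexCatalog({self.species!r}, {len(self)} complexes)"
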