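"""Paired-species synthetic scenarios with planted conserved complexes.

The generator emulates the regime the interolog approach targets: a set
of protein complexes conserved between two species, linked through a
many-to-many ortholog map (paralog expansions), embedded in networks
that also carry species-specific proteins and independently sampled
false-positive edges.  Because noise edges are drawn per species, they
are non-conserved by construction — exactly the interactions that
interolog construction filters out.

Construction, per planted complex of size s:

* s ortholog groups, each with one base member per species; with
  probability ``paralog_expansion_rate`` a group gains one extra member
  on a uniformly chosen side (creating 1-to-many / many-to-many
  groups).  The complex of each species is the species-side union of
  its groups' members.
* for each unordered group pair, with probability ``p_intra`` an
  interaction pattern is planted; it is realized in both species with
  probability ``p_conserve`` and in one uniformly chosen species
  otherwise.  A realized pattern connects all cross-members of the two
  groups.  Each realized edge is then lost independently with
  probability ``edge_loss_rate`` (false negatives).

Background proteins (``n_background_a/b``) join 1-to-1 ortholog groups
at ``background_ortholog_rate`` so the ortholog map extends beyond the
planted complexes.  Per species, ``noise_edge_multiplier`` times the
number of planted edges are added uniformly over protein pairs lying
outside every planted complex.

The returned benchmark lists exactly the planted complex pairs with
their *true* multiset-Jaccard scores computed from the group structure.
Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .evaluation import ConservedBenchmark
from .homology import OrthologMap
from .networks import ComplexCatalog, PPINetwork


@dataclass
class ScenarioParams:
    """Knobs of the planted-complex scenario; defaults define the
    standard noisy test conditions used throughout the package."""

    n_conserved_complexes: int = 20
    complex_size_range: tuple[int, int] = (4, 8)
    p_intra: float = 0.9
    p_conserve: float = 0.9
    paralog_expansion_rate: float = 0.2
    n_background_a: int = 100
    n_background_b: int = 100
    noise_edge_multiplier: float = 2.0
    edge_loss_rate: float = 0.1
    background_ortholog_rate: float = 0.3
    species_a: str = "yeast"
    species_b: str = "human"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.complex_size_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid complex_size_range {self.complex_size_range}")
        if self.n_conserved_complexes < 0:
            raise ValidationError("n_conserved_complexes must be >= 0")
        for name in (
            "p_intra", "p_conserve", "paralog_expansion_rate",
            "edge_loss_rate", "background_ortholog_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.noise_edge_multiplier < 0:
            raise ValidationError("noise_edge_multiplier must be >= 0")
        if self.n_background_a < 0 or self.n_background_b < 0:
            raise ValidationError("background sizes must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["complex_size_range"] = list(self.complex_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        d = dict(d)
        if "complex_size_range" in d:
            d["complex_size_range"] = tuple(d["complex_size_range"])
        return cls(**d)


class Scenario(NamedTuple):
    network_a: PPINetwork
    network_b: PPINetwork
    orthologs: OrthologMap
    catalog_a: ComplexCatalog
    catalog_b: ComplexCatalog
    benchmark: ConservedBenchmark


def zero_noise_params(**overrides) -> ScenarioParams:
    """The clean limit: full intra-complex wiring, full conservation,
    no paralogs, no noise, no edge loss."""
    base = dict(
        p_intra=1.0,
        p_conserve=1.0,
        paralog_expansion_rate=0.0,
        noise_edge_multiplier=0.0,
        edge_loss_rate=0.0,
    )
    base.update(overrides)
    return ScenarioParams(**base)


def generate_scenario(params: ScenarioParams) -> Scenario:
    """Generate (network_a, network_b, orthologs, catalog_a, catalog_b,
    benchmark) for the given parameters; deterministic given the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.complex_size_range

    net_a = PPINetwork(params.species_a)
    net_b = PPINetwork(params.species_b)
    omap = OrthologMap(params.species_a, params.species_b)
    catalog_a = ComplexCatalog(params.species_a)
    catalog_b = ComplexCatalog(params.species_b)

    complex_of_a: dict[str, int] = {}
    complex_of_b: dict[str, int] = {}
    planted_pairs: list[tuple[str, str, float]] = []
    planted_a: list[tuple[str, str]] = []
    planted_b: list[tuple[str, str]] = []

    for k in range(1, params.n_conserved_complexes + 1):
        size = int(rng.integers(lo, hi + 1))
        groups_a: list[list[str]] = []
        groups_b: list[list[str]] = []
        for i in range(1, size + 1):
            ma = [f"a{k}.{i}"]
            mb = [f"b{k}.{i}"]
            if rng.random() < params.paralog_expansion_rate:
                if rng.random() < 0.5:
                    ma.append(f"a{k}.{i}x")
                else:
                    mb.append(f"b{k}.{i}x")
            omap.add_group(f"C{k}G{i}", ma, mb)
            groups_a.append(ma)
            groups_b.append(mb)

        members_a = [p for grp in groups_a for p in grp]
        members_b = [q for grp in groups_b for q in grp]
        cid_a, cid_b = f"A{k}", f"B{k}"
        catalog_a.add(cid_a, members_a)
        catalog_b.add(cid_b, members_b)
        for p in members_a:
            complex_of_a[p] = k
            net_a.add_node(p)
        for q in members_b:
            complex_of_b[q] = k
            net_b.add_node(q)

        min_sum = sum(min(len(ga), len(gb)) for ga, gb in zip(groups_a, groups_b))
        max_sum = sum(max(len(ga), len(gb)) for ga, gb in zip(groups_a, groups_b))
        planted_pairs.append((cid_a, cid_b, min_sum / max_sum))

        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() >= params.p_intra:
                    continue
                if rng.random() < params.p_conserve:
                    in_a = in_b = True
                else:
                    in_a = rng.random() < 0.5
                    in_b = not in_a
                if in_a:
                    for p in groups_a[i]:
                        for r in groups_a[j]:
                            planted_a.append((p, r))
                if in_b:
                    for q in groups_b[i]:
                        for s in groups_b[j]:
                            planted_b.append((q, s))

    # false negatives: each planted edge lost independently
    kept_a = [e for e in planted_a if rng.random() >= params.edge_loss_rate]
    kept_b = [e for e in planted_b if rng.random() >= params.edge_loss_rate]
    for p, r in kept_a:
        net_a.add_edge(p, r)
    for q, s in kept_b:
        net_b.add_edge(q, s)

    for i in range(params.n_background_a):
        net_a.add_node(f"bgA{i}")
    for i in range(params.n_background_b):
        net_b.add_node(f"bgB{i}")
    for i in range(min(params.n_background_a, params.n_background_b)):
        if rng.random() < params.background_ortholog_rate:
            omap.add_group(f"BG{i}", [f"bgA{i}"], [f"bgB{i}"])

    _add_noise_edges(net_a, complex_of_a, params.noise_edge_multiplier, rng)
    _add_noise_edges(net_b, complex_of_b, params.noise_edge_multiplier, rng)

    benchmark = ConservedBenchmark(
        sorted(planted_pairs), msj_threshold=0.0, min_size=1
    )
    return Scenario(net_a, net_b, omap, catalog_a, catalog_b, benchmark)


def _add_noise_edges(
    net: PPINetwork,
    complex_of: dict[str, int],
    multiplier: float,
    rng: np.random.Generator,
) -> None:
    """Add ``multiplier * n_edges`` false-positive edges uniformly over
    pairs lying outside every planted complex."""
    target = int(round(multiplier * net.n_edges))
    proteins = sorted(net.nodes)
    if target == 0 or len(proteins) < 2:
        return
    added = 0
    attempts = 0
    max_attempts = 100 * target + 1000
    while added < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(proteins), size=2)
        if i == j:
            continue
        p, r = proteins[i], proteins[j]
        same_complex = (
            p in complex_of and r in complex_of and complex_of[p] == complex_of[r]
        )
        if same_complex or net.has_edge(p, r):
            continue
        net.add_edge(p, r)
        added += 1


def degrade_conservation(
    g_a: PPINetwork,
    g_b: PPINetwork,
    orthologs: OrthologMap,
    rewire_fraction: float,
    seed: int,
) -> tuple[PPINetwork, PPINetwork]:
    """Break a fraction of conserved edge pairs in exactly one species.

    A species-a edge is *conserved* when some orthologous counterpart
    edge exists in species b.  ``floor(rewire_fraction * n)`` of the n
    conserved a-edges are broken: for each, a fair coin removes either
    the a-edge itself or all of its b-counterpart edges.  Single-species
    edge density is (approximately) preserved while interolog density
    degrades.
    """
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValidationError(f"rewire_fraction must be in [0, 1], got {rewire_fraction}")
    rng = np.random.default_rng(seed)
    out_a, out_b = g_a.copy(), g_b.copy()

    def counterpart_edges(p: str, r: str) -> list[tuple[str, str]]:
        qs = orthologs.counterparts(p, "a") & out_b.nodes
        ss = orthologs.counterparts(r, "a") & out_b.nodes
        return sorted(
            {tuple(sorted((q, s))) for q in qs for s in ss
             if q != s and out_b.has_edge(q, s)}
        )

    conserved = [
        (p, r) for p, r, _ in out_a.edges() if counterpart_edges(p, r)
    ]
    n_break = int(rewire_fraction * len(conserved))
    if n_break == 0:
        return out_a, out_b
    chosen = rng.choice(len(conserved), size=n_break, replace=False)
    for idx in sorted(chosen):
        p, r = conserved[idx]
        if rng.random() < 0.5:
            if out_a.has_edge(p, r):
                out_a.graph.remove_edge(p, r)
        else:
            for q, s in counterpart_edges(p, r):
                out_b.graph.remove_edge(q, s)
    return out_a, out_b
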