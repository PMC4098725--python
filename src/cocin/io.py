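"""Readers and writers for all on-disk formats.

Formats (all plain TSV / text, ``#`` starts a comment line):

* PPI edge list — ``protein_a<TAB>protein_b[<TAB>weight]``.
* Ortholog groups — OrthoMCL group-file dialect,
  ``group_id: species|protein species|protein ...``.
* Complex catalogs — either ``membership_rows`` (one
  ``complex_id<TAB>protein[<TAB>count]`` row per membership) or
  ``one_per_line`` (``complex_id<TAB>member member ...``).
* Interolog networks — one edge per line,
  ``pA|pB<TAB>rA|rB<TAB>weight<TAB>provenance``, preceded by ``#node``
  lines so isolated nodes survive a round trip.
* Interolog clusters — one_per_line with ``p|q`` members.

Every reader/writer pair round-trips: ``read(write(x)) == x``.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from .errors import ParseError, ValidationError
from .evaluation import ConservedBenchmark
from .homology import OrthologMap
from .interolog import InterologNetwork
from .networks import ComplexCatalog, PPINetwork

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


def _data_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_ppi_edgelist(
    path, species_label: str, weighted: bool = False
) -> PPINetwork:
    """Parse a tab-separated edge list into a simple network.

    Self-loops are dropped; duplicate and reversed-duplicate edges
    collapse keeping the maximum weight.  With ``weighted`` a third
    column is parsed as a reliability in (0, 1]; otherwise edges get
    weight 1.0.
    """
    path = Path(path)
    net = PPINetwork(species_label)
    n_self = n_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected >= 2 tab-separated fields, "
                f"got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein identifier")
        weight = 1.0
        if weighted and len(fields) >= 3 and fields[2].strip():
            try:
                weight = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparsable weight {fields[2]!r}"
                ) from exc
            if not 0.0 < weight <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: weight {weight} outside (0, 1]"
                )
        if a == b:
            n_self += 1
            continue
        if not net.add_edge(a, b, weight):
            n_dup += 1
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop and %d duplicate edge line(s)",
            path, n_self, n_dup,
        )
    return net


def write_ppi_edgelist(net: PPINetwork, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# PPI edge list, species={net.species}\n")
        for node in sorted(net.nodes - {e for a, b, _ in net.edges() for e in (a, b)}):
            fh.write(f"#node\t{node}\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_ppi_edgelist_full(path, species_label: str) -> PPINetwork:
    """Weighted reader that also restores ``#node`` isolated-node lines
    written by :func:`write_ppi_edgelist` (round-trip counterpart)."""
    net = read_ppi_edgelist(path, species_label, weighted=True)
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#node\t"):
                net.add_node(raw.rstrip("\n").split("\t", 1)[1])
    return net


# ---------------------------------------------------------------------------
# Ortholog groups (OrthoMCL group-file dialect)
# ---------------------------------------------------------------------------

def read_ortholog_groups(path, species_a: str, species_b: str) -> OrthologMap:
    """Parse ``group_id: species|protein ...`` lines.  Groups listing
    proteins of only one species are retained as paralog groups."""
    path = Path(path)
    omap = OrthologMap(species_a, species_b)
    for lineno, line in _data_lines(path):
        head, sep, rest = line.partition(":")
        if not sep:
            raise ParseError(f"{path}:{lineno}: missing 'group_id:' prefix")
        gid = head.strip()
        if gid in omap.groups:
            raise ValidationError(f"{path}:{lineno}: duplicate group id {gid!r}")
        members_a, members_b = [], []
        for token in rest.split():
            tag, sep2, protein = token.partition(PAIR_SEP)
            if not sep2 or not protein:
                raise ParseError(
                    f"{path}:{lineno}: malformed member token {token!r}"
                )
            if tag == species_a:
                members_a.append(protein)
            elif tag == species_b:
                members_b.append(protein)
            else:
                raise ValidationError(
                    f"{path}:{lineno}: unknown species tag {tag!r} "
                    f"(expected {species_a!r} or {species_b!r})"
                )
        if not members_a and not members_b:
            raise ParseError(f"{path}:{lineno}: group {gid!r} has no members")
        omap.add_group(gid, members_a, members_b)
    return omap


def write_ortholog_groups(omap: OrthologMap, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ortholog groups, a={omap.species_a} b={omap.species_b}\n")
        for gid in sorted(omap.groups):
            ma, mb = omap.groups[gid]
            tokens = [f"{omap.species_a}{PAIR_SEP}{p}" for p in sorted(ma)]
            tokens += [f"{omap.species_b}{PAIR_SEP}{q}" for q in sorted(mb)]
            fh.write(f"{gid}: {' '.join(tokens)}\n")


# ---------------------------------------------------------------------------
# Complex catalogs
# ---------------------------------------------------------------------------

def read_complex_catalog(
    path, species_label: str, dialect: str = "membership_rows"
) -> ComplexCatalog:
    """Parse a complex catalog in either TSV dialect.

    ``membership_rows``: one (complex_id, protein[, count]) row per
    membership; duplicate rows collapse to multiplicity 1 unless a
    count column is present.  ``one_per_line``: complex_id TAB
    space-separated members.
    """
    path = Path(path)
    catalog = ComplexCatalog(species_label)
    if dialect == "membership_rows":
        staged: dict[str, Counter] = {}
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected complex_id<TAB>protein"
                )
            cid, protein = fields[0].strip(), fields[1].strip()
            if not cid or not protein:
                raise ParseError(f"{path}:{lineno}: empty field")
            counts = staged.setdefault(cid, Counter())
            if len(fields) >= 3 and fields[2].strip():
                try:
                    k = int(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable count {fields[2]!r}"
                    ) from exc
                if k < 1:
                    raise ValidationError(f"{path}:{lineno}: count {k} < 1")
                counts[protein] = max(counts[protein], k)
            else:
                counts[protein] = max(counts[protein], 1)
        for cid in staged:
            catalog.add(cid, staged[cid])
    elif dialect == "one_per_line":
        for lineno, line in _data_lines(path):
            cid, sep, members = line.partition("\t")
            proteins = members.split()
            if not sep or not proteins:
                raise ValidationError(
                    f"{path}:{lineno}: complex {cid!r} has no members"
                )
            catalog.add(cid.strip(), Counter(proteins))
    else:
        raise ValidationError(f"unknown catalog dialect {dialect!r}")
    if any(not c for c in catalog.complexes.values()):
        raise ValidationError(f"{path}: empty complex after parsing")
    return catalog


def write_complex_catalog(
    catalog: ComplexCatalog, path, dialect: str = "membership_rows"
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# complex catalog, species={catalog.species}\n")
        if dialect == "membership_rows":
            for cid in catalog:
                for protein in sorted(catalog.members(cid)):
                    k = catalog.members(cid)[protein]
                    fh.write(f"{cid}\t{protein}\t{k}\n")
        elif dialect == "one_per_line":
            for cid in catalog:
                members = []
                for protein in sorted(catalog.members(cid)):
                    members += [protein] * catalog.members(cid)[protein]
                fh.write(f"{cid}\t{' '.join(members)}\n")
        else:
            raise ValidationError(f"unknown catalog dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Interolog networks and clusters
# ---------------------------------------------------------------------------

def _format_node(node: tuple[str, str]) -> str:
    p, q = node
    if PAIR_SEP in p or PAIR_SEP in q:
        raise ValidationError(
            f"protein id containing {PAIR_SEP!r} cannot be serialized: {node}"
        )
    return f"{p}{PAIR_SEP}{q}"


def _parse_node(token: str, where: str) -> tuple[str, str]:
    p, sep, q = token.partition(PAIR_SEP)
    if not sep or not p or not q:
        raise ParseError(f"{where}: malformed interolog node {token!r}")
    return (p, q)


def write_interolog_network(net: InterologNetwork, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# interolog network, a={net.species_a} b={net.species_b}\n")
        degree = net.graph.degree
        for node in sorted(net.nodes):
            if degree(node) == 0:
                fh.write(f"#node\t{_format_node(node)}\n")
        for u, v, w, tag in net.edges():
            fh.write(f"{_format_node(u)}\t{_format_node(v)}\t{w!r}\t{tag}\n")


def read_interolog_network(path, species_a: str, species_b: str) -> InterologNetwork:
    path = Path(path)
    net = InterologNetwork(species_a, species_b)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#node\t"):
                net.graph.add_node(_parse_node(line.split("\t", 1)[1], f"{path}:{lineno}"))
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            u = _parse_node(fields[0], f"{path}:{lineno}")
            v = _parse_node(fields[1], f"{path}:{lineno}")
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparsable weight {fields[2]!r}"
                ) from exc
            net.graph.add_edge(u, v, weight=w, provenance=fields[3])
    return net


def write_clusters(clusters, path, interolog: bool = False) -> None:
    """Write cluster node sets in the one_per_line dialect; interolog
    nodes are serialized as ``p|q``.  Accepts a ClusterSet or any
    iterable of node sets."""
    node_sets = clusters.node_sets() if hasattr(clusters, "node_sets") else list(clusters)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# clusters, one per line\n")
        for k, members in enumerate(node_sets, start=1):
            if interolog:
                tokens = sorted(_format_node(n) for n in members)
            else:
                tokens = sorted(members)
            fh.write(f"cluster{k}\t{' '.join(tokens)}\n")


def read_clusters(path, interolog: bool = False) -> list[frozenset]:
    path = Path(path)
    out = []
    for lineno, line in _data_lines(path):
        _, sep, members = line.partition("\t")
        tokens = members.split()
        if not sep or not tokens:
            raise ParseError(f"{path}:{lineno}: cluster with no members")
        if interolog:
            out.append(frozenset(_parse_node(t, f"{path}:{lineno}") for t in tokens))
        else:
            out.append(frozenset(tokens))
    return out


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

def write_benchmark(benchmark: ConservedBenchmark, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# conserved complex pairs, msj_threshold={benchmark.msj_threshold!r} "
            f"min_size={benchmark.min_size}\n"
        )
        for cid_a, cid_b, score in benchmark.pairs:
            fh.write(f"{cid_a}\t{cid_b}\t{score!r}\n")


def read_benchmark(path) -> ConservedBenchmark:
    path = Path(path)
    msj_threshold, min_size = 0.5, 4
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#") and "msj_threshold=" in line:
                for token in line.lstrip("# ").split():
                    key, sep, value = token.partition("=")
                    if key == "msj_threshold" and sep:
                        msj_threshold = float(value)
                    elif key == "min_size" and sep:
                        min_size = int(value)
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            pairs.append((fields[0], fields[1], float(fields[2])))
    return ConservedBenchmark(pairs, msj_threshold, min_size)
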