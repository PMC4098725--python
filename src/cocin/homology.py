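"""Ortholog groups spanning two species.

An :class:`OrthologMap` holds groups of homologous proteins (by sequence
similarity and/or shared functional domains, e.g. Ensembl or OrthoMCL
exports).  A group may contain several proteins per species (paralogs),
so the induced protein-level correspondence theta between the two
species is many-to-many; groups with members on one side only are
paralog groups and induce no cross-species pairs.

A :class:`GroupProfile` summarizes one complex against the map: for each
group, the number of complex members it contains (its multiplicity),
plus the complex members belonging to no group at all.  Profiles are the
inputs to the multiset-Jaccard conservation score.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, field

from .errors import ValidationError

Side = str  # "a" | "b"


def _check_side(side: str) -> None:
    if side not in ("a", "b"):
        raise ValidationError(f"side must be 'a' or 'b', got {side!r}")


@dataclass
class OrthologMap:
    """Ortholog groups between species A and species B.

    ``groups`` maps group_id -> (members_a, members_b); either side may
    be empty (paralog group) but not both.
    """

    species_a: str
    species_b: str
    groups: dict[str, tuple[frozenset, frozenset]] = field(default_factory=dict)
    _index_a: dict = field(default=None, compare=False, repr=False)
    _index_b: dict = field(default=None, compare=False, repr=False)

    def add_group(
        self, group_id: str, members_a: Iterable[str], members_b: Iterable[str]
    ) -> None:
        if group_id in self.groups:
            raise ValidationError(f"duplicate group id {group_id!r}")
        ma, mb = frozenset(members_a), frozenset(members_b)
        if not ma and not mb:
            raise ValidationError(f"group {group_id!r} has no members")
        self.groups[group_id] = (ma, mb)
        self._index_a = self._index_b = None

    def _indexes(self) -> tuple[dict, dict]:
        if self._index_a is None:
            index_a: dict[str, set[str]] = {}
            index_b: dict[str, set[str]] = {}
            for gid, (ma, mb) in self.groups.items():
                for p in ma:
                    index_a.setdefault(p, set()).add(gid)
                for q in mb:
                    index_b.setdefault(q, set()).add(gid)
            self._index_a, self._index_b = index_a, index_b
        return self._index_a, self._index_b

    def groups_of(self, protein: str, side: Side) -> frozenset:
        """Group ids containing ``protein`` on the given side."""
        _check_side(side)
        index = self._indexes()[0 if side == "a" else 1]
        return frozenset(index.get(protein, ()))

    def members(self, group_id: str, side: Side) -> frozenset:
        _check_side(side)
        ma, mb = self.groups[group_id]
        return ma if side == "a" else mb

    def counterparts(self, protein: str, side: Side) -> frozenset:
        """All proteins of the *other* species sharing a group with ``protein``."""
        _check_side(side)
        other = "b" if side == "a" else "a"
        out: set[str] = set()
        for gid in self.groups_of(protein, side):
            out |= self.members(gid, other)
        return frozenset(out)

    def theta_pairs(
        self,
        restrict_a: set[str] | None = None,
        restrict_b: set[str] | None = None,
    ) -> set[tuple[str, str]]:
        """The many-to-many correspondence theta as explicit (p, q) pairs.

        Every cross-species member product of every group, optionally
        intersected with per-side restriction sets.
        """
        pairs: set[tuple[str, str]] = set()
        for ma, mb in self.groups.values():
            left = ma if restrict_a is None else ma & restrict_a
            if not left:
                continue
            right = mb if restrict_b is None else mb & restrict_b
            for p in left:
                for q in right:
                    pairs.add((p, q))
        return pairs

    def side_for_species(self, species: str) -> Side:
        if species == self.species_a:
            return "a"
        if species == self.species_b:
            return "b"
        raise ValidationError(
            f"species {species!r} is neither {self.species_a!r} (side a) "
            f"nor {self.species_b!r} (side b) of this ortholog map"
        )

    def category_counts(self) -> dict[str, int]:
        """Group counts by shape: 1-to-1, 1-A-to-many, many-to-1,
        many-to-many, and single-species paralog groups per side."""
        counts = Counter()
        for ma, mb in self.groups.values():
            if ma and mb:
                if len(ma) == 1 and len(mb) == 1:
                    key = "one_to_one"
                elif len(ma) == 1:
                    key = "one_a_to_many"
                elif len(mb) == 1:
                    key = "many_to_one_b"
                else:
                    key = "many_to_many"
            elif ma:
                key = "paralog_only_a"
            else:
                key = "paralog_only_b"
            counts[key] += 1
        return dict(counts)

    def merged_with(self, other: "OrthologMap") -> "OrthologMap":
        """Simple union merge of two maps over the same species pair.

        Groups are concatenated; colliding group ids from ``other`` are
        suffixed.  This is a deliberately naive integration of two
        orthology resources (e.g. Ensembl + OrthoMCL): no attempt is
        made to reconcile disagreeing group boundaries.
        """
        if (other.species_a, other.species_b) != (self.species_a, self.species_b):
            raise ValidationError("cannot merge maps over different species pairs")
        merged = OrthologMap(self.species_a, self.species_b)
        for gid, (ma, mb) in self.groups.items():
            merged.add_group(gid, ma, mb)
        for gid, (ma, mb) in other.groups.items():
            new_id = gid if gid not in merged.groups else f"{gid}~merged"
            merged.add_group(new_id, ma, mb)
        return merged

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class GroupProfile:
    """Ortholog-group composition of one complex on one species side.

    ``multiplicities[g]`` counts the complex members assigned to group
    ``g`` (a member in k groups contributes 1 to each of the k);
    ``ungrouped`` collects members outside every group.
    """

    complex_id: str
    multiplicities: dict[str, int] = field(default_factory=dict)
    ungrouped: Counter = field(default_factory=Counter)

    @property
    def group_ids(self) -> frozenset:
        return frozenset(self.multiplicities)

    @property
    def n_ungrouped(self) -> int:
        return sum(self.ungrouped.values())

    def is_empty(self) -> bool:
        return not self.multiplicities and not self.ungrouped


def group_profile(
    members: Iterable[str] | Counter,
    side: Side,
    omap: OrthologMap,
    complex_id: str = "",
) -> GroupProfile:
    """Profile a complex's members against the ortholog map.

    Each member contributes its multiset count to every group containing
    it on ``side``; members in no group accumulate in ``ungrouped``.
    """
    _check_side(side)
    counts = members if isinstance(members, Counter) else Counter(members)
    profile = GroupProfile(complex_id)
    for protein, k in counts.items():
        gids = omap.groups_of(protein, side)
        if gids:
            for gid in gids:
                profile.multiplicities[gid] = profile.multiplicities.get(gid, 0) + k
        else:
            profile.ungrouped[protein] += k
    return profile
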