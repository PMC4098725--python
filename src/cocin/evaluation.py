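"""Conservation scoring and benchmark-based evaluation.

Two conservation scores between a complex pair (C1, C2) from the two
species, both computed over ortholog-group profiles:

* plain group Jaccard: |G_C1 & G_C2| / |G_C1 | G_C2| on group-id sets;
* multiset Jaccard (MSJ):

      MSJ(C1, C2) = sum_g min(I_C1(g), I_C2(g))
                    / sum_g max(I_C1(g), I_C2(g)),

  the sums running over g in G_C1 | G_C2, where I_Ci(g) is the
  multiplicity of group g in complex Ci (its paralog count).  MSJ
  penalizes unbalanced paralog expansion that the plain score ignores.

By default, complex members belonging to no ortholog group enter both
scores as species-private groups (multiplicity = their count) that can
only inflate the denominator — a complex of unmapped proteins cannot
look conserved.

Predicted complexes are matched to curated benchmark complexes by the
protein-set Jaccard J(C, B) = |C & B| / |C | B| at a match threshold
t (default 0.50); precision is the fraction of predictions matching
some benchmark complex, and conserved-complex recall the fraction of
gold-standard conserved pairs detected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

from .errors import ValidationError
from .homology import GroupProfile, OrthologMap, group_profile
from .networks import ComplexCatalog

logger = logging.getLogger(__name__)


def jaccard_match(c: Iterable[str], b: Iterable[str]) -> float:
    """Protein-set Jaccard overlap J(C, B) = |C & B| / |C | B|."""
    cs, bs = set(c), set(b)
    if not cs and not bs:
        raise ValidationError("Jaccard of two empty sets is undefined")
    return len(cs & bs) / len(cs | bs)


def _check_profiles(p1: GroupProfile, p2: GroupProfile) -> None:
    if p1.is_empty() and p2.is_empty():
        raise ValidationError("both group profiles are empty")


def group_jaccard(
    profile1: GroupProfile, profile2: GroupProfile, ignore_ungrouped: bool = False
) -> float:
    """Plain Jaccard on ortholog-group id sets (multiplicity ignored);
    each distinct ungrouped protein counts as a unique private group in
    the union unless ``ignore_ungrouped``."""
    _check_profiles(profile1, profile2)
    inter = len(profile1.group_ids & profile2.group_ids)
    union = len(profile1.group_ids | profile2.group_ids)
    if not ignore_ungrouped:
        union += len(profile1.ungrouped) + len(profile2.ungrouped)
    if union == 0:
        raise ValidationError("both group profiles are empty")
    return inter / union


def msj(
    profile1: GroupProfile, profile2: GroupProfile, ignore_ungrouped: bool = False
) -> float:
    """Multiset Jaccard over group multiplicities (absent group => 0);
    ungrouped proteins are private groups whose multiplicity enters the
    max sum only, unless ``ignore_ungrouped``."""
    _check_profiles(profile1, profile2)
    min_sum = 0
    max_sum = 0
    for gid in profile1.group_ids | profile2.group_ids:
        m1 = profile1.multiplicities.get(gid, 0)
        m2 = profile2.multiplicities.get(gid, 0)
        min_sum += min(m1, m2)
        max_sum += max(m1, m2)
    if not ignore_ungrouped:
        max_sum += profile1.n_ungrouped + profile2.n_ungrouped
    if max_sum == 0:
        raise ValidationError("both group profiles are empty")
    return min_sum / max_sum


@dataclass
class ConservedBenchmark:
    """Gold standard of conserved complex pairs between the two species:
    cross-catalog pairs with MSJ >= msj_threshold and both sizes >=
    min_size."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    msj_threshold: float = 0.5
    min_size: int = 4

    def pair_ids(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def build_conserved_benchmark(
    catalog_a: ComplexCatalog,
    catalog_b: ComplexCatalog,
    omap: OrthologMap,
    msj_threshold: float = 0.5,
    min_size: int = 4,
    ignore_ungrouped: bool = False,
) -> ConservedBenchmark:
    """Score all cross-catalog complex pairs by MSJ and keep those at or
    above ``msj_threshold`` with both complexes of size >= min_size."""
    omap.side_for_species(catalog_a.species)
    omap.side_for_species(catalog_b.species)
    profiles_a = {
        cid: group_profile(catalog_a.members(cid), "a", omap, cid)
        for cid in catalog_a
        if catalog_a.size(cid) >= min_size
    }
    profiles_b = {
        cid: group_profile(catalog_b.members(cid), "b", omap, cid)
        for cid in catalog_b
        if catalog_b.size(cid) >= min_size
    }
    pairs = []
    for cid_a in sorted(profiles_a):
        pa = profiles_a[cid_a]
        for cid_b in sorted(profiles_b):
            pb = profiles_b[cid_b]
            if pa.is_empty() and pb.is_empty():
                continue
            score = msj(pa, pb, ignore_ungrouped=ignore_ungrouped)
            if score >= msj_threshold:
                pairs.append((cid_a, cid_b, score))
    return ConservedBenchmark(pairs, msj_threshold, min_size)


@dataclass
class EvaluationReport:
    """Outcome of matching predicted complex pairs to the benchmarks."""

    matched_predictions: list[tuple[str, str, str, float]]
    # (prediction_id, side, benchmark_id, jaccard)
    derived_benchmarks_a: frozenset
    derived_benchmarks_b: frozenset
    detected_conserved_pairs: frozenset
    n_predictions: int
    n_matched: int
    precision: float
    n_gold: int
    n_detected: int
    recall_conserved: float
    match_threshold: float
    paired: bool

    def summary(self) -> dict:
        return {
            "n_predictions": self.n_predictions,
            "n_matched": self.n_matched,
            "precision": self.precision,
            "n_gold": self.n_gold,
            "n_detected": self.n_detected,
            "recall_conserved": self.recall_conserved,
            "match_threshold": self.match_threshold,
            "paired": self.paired,
        }


def evaluate(
    predicted_pairs: Sequence[tuple[Iterable[str], Iterable[str]]],
    catalog_a: ComplexCatalog,
    catalog_b: ComplexCatalog,
    gold: ConservedBenchmark,
    t: float = 0.50,
    paired: bool = True,
) -> EvaluationReport:
    """Match predictions to per-species benchmark complexes at J >= t
    and count detected gold conserved pairs.

    Each prediction is a (set_a, set_b) pair; either side may be empty
    (single-species baselines supply one side only).  A prediction is a
    *matched prediction* when every non-empty side matches some
    benchmark complex of its species.  A gold pair (B_a, B_b) is
    *detected* when one prediction matches both sides (``paired``,
    the interolog-pipeline convention) or when each side is matched by
    some — possibly different — prediction (``paired=False``, the
    convention for independently clustered baselines).
    """
    if not 0.0 < t <= 1.0:
        raise ValidationError(f"match threshold t must be in (0, 1], got {t}")

    matches_a: list[dict[str, float]] = []
    matches_b: list[dict[str, float]] = []
    matched_records: list[tuple[str, str, str, float]] = []
    n_matched = 0
    for k, (side_a, side_b) in enumerate(predicted_pairs):
        pid = f"P{k + 1}"
        sa, sb = set(side_a), set(side_b)
        ma = {
            cid: jaccard_match(sa, catalog_a.members(cid))
            for cid in catalog_a
        } if sa else {}
        mb = {
            cid: jaccard_match(sb, catalog_b.members(cid))
            for cid in catalog_b
        } if sb else {}
        ma = {cid: j for cid, j in ma.items() if j >= t}
        mb = {cid: j for cid, j in mb.items() if j >= t}
        matches_a.append(ma)
        matches_b.append(mb)
        ok_a = bool(ma) or not sa
        ok_b = bool(mb) or not sb
        if (sa or sb) and ok_a and ok_b:
            n_matched += 1
            for cid, j in sorted(ma.items()):
                matched_records.append((pid, "a", cid, j))
            for cid, j in sorted(mb.items()):
                matched_records.append((pid, "b", cid, j))

    n_predictions = len(predicted_pairs)
    if n_predictions == 0:
        logger.warning("no predictions supplied; precision reported as 0.0")
        precision = 0.0
    else:
        precision = n_matched / n_predictions

    detected = set()
    for ba, bb, _ in gold:
        if paired:
            hit = any(ba in ma and bb in mb for ma, mb in zip(matches_a, matches_b))
        else:
            hit = any(ba in ma for ma in matches_a) and any(
                bb in mb for mb in matches_b
            )
        if hit:
            detected.add((ba, bb))

    n_gold = len(gold)
    if n_gold == 0:
        logger.warning("empty gold standard; recall reported as NaN")
        recall = math.nan
    else:
        recall = len(detected) / n_gold

    return EvaluationReport(
        matched_predictions=matched_records,
        derived_benchmarks_a=frozenset(
            cid for _, side, cid, _ in matched_records if side == "a"
        ),
        derived_benchmarks_b=frozenset(
            cid for _, side, cid, _ in matched_records if side == "b"
        ),
        detected_conserved_pairs=frozenset(detected),
        n_predictions=n_predictions,
        n_matched=n_matched,
        precision=precision,
        n_gold=n_gold,
        n_detected=len(detected),
        recall_conserved=recall,
        match_threshold=t,
        paired=paired,
    )
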