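"""Conservation scores, benchmark construction, precision/recall."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocin.errors import ValidationError
from cocin.evaluation import (
    ConservedBenchmark,
    build_conserved_benchmark,
    evaluate,
    group_jaccard,
    jaccard_match,
    msj,
)
from cocin.homology import GroupProfile, OrthologMap
from cocin.networks import ComplexCatalog


def profile(mult, ungrouped=(), cid="c"):
    return GroupProfile(cid, dict(mult), Counter(ungrouped))


class TestJaccardMatch:
    def test_identity(self):
        assert jaccard_match({"A", "B", "C"}, {"A", "B", "C"}) == 1.0

    def test_disjoint(self):
        assert jaccard_match({"A", "B", "C"}, {"D", "E"}) == 0.0

    def test_half_overlap_matches_at_default_threshold(self):
        j = jaccard_match({"A", "B", "C"}, {"B", "C", "D"})
        assert j == pytest.approx(0.5)
        assert j >= 0.50  # a match at the standard threshold

    def test_symmetric(self):
        a, b = {"A", "B"}, {"B", "C", "D"}
        assert jaccard_match(a, b) == jaccard_match(b, a)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_match(set(), set())


class TestGroupJaccard:
    def test_identical_group_sets(self):
        assert group_jaccard(profile({"G1": 2}), profile({"G1": 5})) == 1.0

    def test_one_of_three(self):
        p1 = profile({"G1": 1, "G2": 1})
        p2 = profile({"G1": 1, "G3": 1})
        assert group_jaccard(p1, p2) == pytest.approx(1 / 3)

    def test_ungrouped_private_group_in_union(self):
        p1 = profile({"G1": 1}, ungrouped=["u1"])
        p2 = profile({"G1": 1})
        assert group_jaccard(p1, p2) == pytest.approx(1 / 2)
        assert group_jaccard(p1, p2, ignore_ungrouped=True) == 1.0


class TestMSJ:
    def test_multiplicity_example(self):
        p1 = profile({"G1": 2, "G2": 1})
        p2 = profile({"G1": 1, "G3": 1})
        assert msj(p1, p2) == pytest.approx(0.25)

    def test_identical_profiles(self):
        p = {"G1": 2, "G2": 3}
        assert msj(profile(p), profile(p)) == 1.0

    def test_disjoint_groups(self):
        assert msj(profile({"G1": 1}), profile({"G2": 1})) == 0.0

    def test_ungrouped_inflates_denominator_only(self):
        p1 = profile({"G1": 4}, ungrouped=["u1", "u2"])
        p2 = profile({"G1": 4})
        assert msj(p1, p2) == pytest.approx(4 / 6)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            msj(profile({}), profile({}))

    @staticmethod
    def random_profiles(seed):
        rng = np.random.default_rng(seed)
        def one(tag):
            mult = {
                f"G{g}": int(rng.integers(1, 5))
                for g in rng.choice(20, size=rng.integers(0, 8), replace=False)
            }
            ungrouped = [f"u{tag}{i}" for i in range(int(rng.integers(0, 3)))]
            return profile(mult, ungrouped)
        return one("a"), one("b")

    def test_symmetry_bounds_and_identity_500_pairs(self):
        """MSJ is symmetric, in [0, 1], and 1 iff the multiset profiles
        coincide (with no ungrouped members)."""
        checked = 0
        for seed in range(600):
            p1, p2 = self.random_profiles(seed)
            if p1.is_empty() and p2.is_empty():
                continue
            checked += 1
            s = msj(p1, p2)
            assert 0.0 <= s <= 1.0
            assert s == msj(p2, p1)
            identical = (
                p1.multiplicities == p2.multiplicities
                and not p1.ungrouped and not p2.ungrouped
            )
            assert (s == 1.0) == identical
            if checked >= 500:
                break
        assert checked >= 500

    def test_monotone_in_min_side_multiplicity(self):
        """Raising a min-side multiplicity toward the other side's
        never decreases the score."""
        for seed in range(100):
            p1, p2 = self.random_profiles(seed + 10_000)
            shared = [
                g for g in p1.multiplicities
                if p2.multiplicities.get(g, 0) > p1.multiplicities[g]
            ]
            if not shared or (p1.is_empty() and p2.is_empty()):
                continue
            before = msj(p1, p2)
            bumped = dict(p1.multiplicities)
            bumped[shared[0]] += 1
            after = msj(profile(bumped, p1.ungrouped), p2)
            assert after >= before


def simple_map():
    omap = OrthologMap("yeast", "human")
    for i in range(1, 8):
        omap.add_group(f"G{i}", [f"p{i}"], [f"q{i}"])
    return omap


class TestBuildBenchmark:
    def test_one_to_one_through_four_groups(self):
        omap = simple_map()
        cat_a = ComplexCatalog("yeast")
        cat_a.add("A1", ["p1", "p2", "p3", "p4"])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "q2", "q3", "q4"])
        gold = build_conserved_benchmark(cat_a, cat_b, omap)
        assert gold.pairs == [("A1", "B1", 1.0)]

    def test_extra_unmapped_proteins_dilute(self):
        omap = simple_map()
        cat_a = ComplexCatalog("yeast")
        cat_a.add("A1", ["p1", "p2", "p3", "p4", "zz1", "zz2"])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "q2", "q3", "q4"])
        gold = build_conserved_benchmark(cat_a, cat_b, omap)
        assert len(gold) == 1
        assert gold.pairs[0][2] == pytest.approx(4 / 6)

    def test_low_sharing_excluded(self):
        omap = simple_map()
        cat_a = ComplexCatalog("yeast")
        cat_a.add("A1", [f"p{i}" for i in range(1, 8)])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "zb1", "zb2", "zb3", "zb4", "zb5", "zb6"])
        gold = build_conserved_benchmark(cat_a, cat_b, omap)
        assert len(gold) == 0  # MSJ = 1/13 < 0.5

    def test_size_filter(self):
        omap = simple_map()
        cat_a = ComplexCatalog("yeast")
        cat_a.add("small", ["p1", "p2", "p3"])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "q2", "q3"])
        assert len(build_conserved_benchmark(cat_a, cat_b, omap, min_size=4)) == 0
        assert len(build_conserved_benchmark(cat_a, cat_b, omap, min_size=3)) == 1

    def test_threshold_extremes(self):
        omap = simple_map()
        cat_a = ComplexCatalog("yeast")
        cat_a.add("A1", ["p1", "p2", "p3", "p4"])
        cat_a.add("A2", ["p5", "p6", "p7", "zz"])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "q2", "q3", "q4"])
        all_pairs = build_conserved_benchmark(cat_a, cat_b, omap, msj_threshold=0.0)
        assert len(all_pairs) == 2  # every size-filtered pair
        assert len(build_conserved_benchmark(cat_a, cat_b, omap, msj_threshold=1.01)) == 0


class TestEvaluate:
    @staticmethod
    def gold_and_catalogs():
        cat_a = ComplexCatalog("yeast")
        cat_a.add("A1", ["p1", "p2", "p3", "p4"])
        cat_a.add("A2", ["p5", "p6", "p7", "p8"])
        cat_b = ComplexCatalog("human")
        cat_b.add("B1", ["q1", "q2", "q3", "q4"])
        cat_b.add("B2", ["q5", "q6", "q7", "q8"])
        gold = ConservedBenchmark([("A1", "B1", 1.0), ("A2", "B2", 1.0)])
        return cat_a, cat_b, gold

    def test_exact_predictions(self):
        cat_a, cat_b, gold = self.gold_and_catalogs()
        preds = [
            ({"p1", "p2", "p3", "p4"}, {"q1", "q2", "q3", "q4"}),
            ({"p5", "p6", "p7", "p8"}, {"q5", "q6", "q7", "q8"}),
        ]
        report = evaluate(preds, cat_a, cat_b, gold)
        assert report.precision == 1.0
        assert report.recall_conserved == 1.0

    def test_no_predictions(self):
        cat_a, cat_b, gold = self.gold_and_catalogs()
        report = evaluate([], cat_a, cat_b, gold)
        assert report.precision == 0.0
        assert report.recall_conserved == 0.0

    def test_half_matching(self):
        """One of two predictions matches a gold pair at J = 0.5 on
        both sides; precision and recall are both one half."""
        cat_a, cat_b, gold = self.gold_and_catalogs()
        preds = [
            # J({p1,p2,p3,px}, A1) = 3/5 >= 0.5 on both sides -> match
            ({"p1", "p2", "p3", "px"}, {"q1", "q2", "q3", "qx"}),
            ({"zz1"}, {"zz2"}),
        ]
        report = evaluate(preds, cat_a, cat_b, gold)
        assert report.precision == 0.5
        assert report.recall_conserved == 0.5
        assert report.detected_conserved_pairs == {("A1", "B1")}

    def test_paired_vs_independent_detection(self):
        """Two single-sided predictions detect a gold pair only under
        per-side (independent) matching."""
        cat_a, cat_b, gold = self.gold_and_catalogs()
        preds = [
            ({"p1", "p2", "p3", "p4"}, frozenset()),
            (frozenset(), {"q1", "q2", "q3", "q4"}),
        ]
        paired = evaluate(preds, cat_a, cat_b, gold, paired=True)
        assert paired.n_detected == 0
        independent = evaluate(preds, cat_a, cat_b, gold, paired=False)
        assert independent.n_detected == 1
        assert independent.precision == 1.0  # each non-empty side matches

    def test_empty_gold_reports_nan_recall(self):
        cat_a, cat_b, _ = self.gold_and_catalogs()
        report = evaluate(
            [({"p1", "p2", "p3", "p4"}, {"q1", "q2", "q3", "q4"})],
            cat_a, cat_b, ConservedBenchmark([]),
        )
        assert math.isnan(report.recall_conserved)

    def test_invalid_threshold(self):
        cat_a, cat_b, gold = self.gold_and_catalogs()
        with pytest.raises(ValidationError):
            evaluate([], cat_a, cat_b, gold, t=0.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_raising_threshold_never_increases_scores(self, seed):
        rng = np.random.default_rng(seed)
        cat_a, cat_b, gold = self.gold_and_catalogs()
        pool_a = [f"p{i}" for i in range(1, 10)] + ["x1", "x2"]
        pool_b = [f"q{i}" for i in range(1, 10)] + ["y1", "y2"]
        preds = []
        for _ in range(int(rng.integers(1, 6))):
            sa = set(rng.choice(pool_a, size=rng.integers(1, 6), replace=False))
            sb = set(rng.choice(pool_b, size=rng.integers(1, 6), replace=False))
            preds.append((sa, sb))
        previous = None
        for t in (0.25, 0.5, 0.75, 1.0):
            report = evaluate(preds, cat_a, cat_b, gold, t=t)
            if previous is not None:
                assert report.precision <= previous.precision
                assert report.recall_conserved <= previous.recall_conserved
            previous = report
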