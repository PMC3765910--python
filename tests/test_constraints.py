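import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import translated
from kgml2sbgn.constraints import (
    SeparationConstraint,
    build_constraint_set,
    containment_constraints,
    enzyme_constraints,
    infer_alignments,
    order_constraints,
    reaction_group_constraints,
)
from kgml2sbgn.geometry import Rect
from kgml2sbgn.sbgn_model import Glyph, GlyphClass, SbgnMap, Side
from kgml2sbgn.translator import EnzymeProcessPair, ReactionGroup
from oracles import single_linkage_1d_brute


def chem(gid, x, y, w=20, h=20):
    return Glyph(gid, GlyphClass.SIMPLE_CHEMICAL, gid, Rect(x, y, w, h))


class TestInferAlignments:
    def test_identical_coordinates_one_group(self):
        glyphs = [chem(f"c{i}", 10 * i, 200) for i in range(3)]
        out = [a for a in infer_alignments(glyphs, 4) if a.axis == "y"]
        assert len(out) == 1 and len(out[0].member_ids) == 3
        assert out[0].guide_pos == 200

    def test_tolerance_splits_groups(self):
        glyphs = [
            chem("a", 0, 200), chem("b", 50, 203), chem("c", 100, 210),
        ]
        out = [a for a in infer_alignments(glyphs, 4) if a.axis == "y"]
        assert len(out) == 1
        assert sorted(out[0].member_ids) == ["a", "b"]

    def test_empty(self):
        assert infer_alignments([], 4) == []

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            infer_alignments([], -1)

    def test_disconnected_nodes_still_align(self, simple_irreversible_kgml):
        # compounds and the process share y=200 without regard to edges
        res = translated(simple_irreversible_kgml)
        ys = [a for a in infer_alignments(res.map.glyphs, 4) if a.axis == "y"]
        assert any(
            {"sc1", "sc2", "pn3_r1"} <= set(a.member_ids) for a in ys
        )

    @given(
        st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=12),
        st.integers(min_value=0, max_value=6),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_single_linkage(self, coords, tol):
        glyphs = [chem(f"c{i:02d}", float(c), 0.0) for i, c in enumerate(coords)]
        got = [a for a in infer_alignments(glyphs, float(tol)) if a.axis == "x"]
        expected = [
            c for c in single_linkage_1d_brute([float(v) for v in coords], tol)
            if len(c) >= 2
        ]
        got_clusters = sorted(
            sorted(glyphs[int(m[1:])].bbox.cx for m in a.member_ids) for a in got
        )
        assert got_clusters == sorted(expected)

    def test_idempotent_on_aligned_layout(self):
        glyphs = [chem(f"c{i}", 30 * i, 100.0) for i in range(4)]
        first = infer_alignments(glyphs, 4)
        again = infer_alignments(glyphs, 4)
        assert [(a.axis, a.member_ids) for a in first] == [
            (a.axis, a.member_ids) for a in again
        ]


class TestOrderConstraints:
    def two_guide_fixture(self):
        glyphs = [
            chem("a", 0, 100, h=40), chem("b", 50, 100, h=30),
            chem("c", 0, 200, h=40), chem("d", 50, 200, h=20),
        ]
        aligns = [a for a in infer_alignments(glyphs, 4) if a.axis == "y"]
        return glyphs, aligns

    def test_gap_is_sum_of_widest_half_extents(self):
        glyphs, aligns = self.two_guide_fixture()
        seps = order_constraints(aligns, glyphs, "y")
        assert len(seps) == 1
        (s,) = seps
        assert s.gap == 40.0  # 40/2 + 40/2, larger than min_group_gap
        assert not s.is_equality

    def test_single_guide_no_separations(self):
        glyphs = [chem("a", 0, 100), chem("b", 50, 100)]
        aligns = [a for a in infer_alignments(glyphs, 4) if a.axis == "y"]
        assert order_constraints(aligns, glyphs, "y") == []

    def test_three_guides_two_chained(self):
        glyphs = [
            chem(f"{r}{c}", 50 * c, 100 * r) for r in range(3) for c in range(2)
        ]
        aligns = [a for a in infer_alignments(glyphs, 4) if a.axis == "y"]
        seps = order_constraints(aligns, glyphs, "y")
        assert len(seps) == 2
        # chained consecutively: acyclic by construction, left precedes right
        order = {a.guide: a.guide_pos for a in aligns}
        assert all(order[s.left] < order[s.right] for s in seps)

    def test_min_group_gap_floor(self):
        glyphs = [chem("a", 0, 100, h=8), chem("b", 0, 200, h=8)]
        seps = order_constraints([], glyphs, "y", min_group_gap=20)
        assert seps[0].gap == 20.0


class TestReactionGroupConstraints:
    def fixture(self):
        rects = {
            "sc1": Rect(100, 50, 20, 20), "sc2": Rect(100, 250, 20, 20),
            "p1": Rect(100, 135, 14, 14), "p2": Rect(100, 160, 14, 14),
            "p3": Rect(100, 185, 14, 14),
        }
        glyphs = [chem("sc1", 100, 50), chem("sc2", 100, 250)]
        aligns = infer_alignments(glyphs, 4)
        return rects, aligns

    def test_vertical_group_of_two(self):
        rects, aligns = self.fixture()
        g = ReactionGroup("sc1", "sc2", ["p1", "p2"], "vertical")
        new_aligns, seps = reaction_group_constraints([g], aligns, rects)
        assert len(new_aligns) == 1 and new_aligns[0].axis == "x"
        eqs = [s for s in seps if s.is_equality]
        assert len(eqs) == 1 and eqs[0].gap == 25.0 and eqs[0].axis == "y"

    def test_empty(self):
        assert reaction_group_constraints([], [], {}) == ([], [])

    def test_group_of_three_two_equalities(self):
        rects, aligns = self.fixture()
        g = ReactionGroup("sc1", "sc2", ["p1", "p2", "p3"], "vertical")
        _, seps = reaction_group_constraints([g], aligns, rects)
        assert sum(1 for s in seps if s.is_equality) == 2
        # plus the two inequalities pinning the group between the compounds
        assert sum(1 for s in seps if not s.is_equality) == 2

    def test_unaligned_compounds_demote_group(self, caplog):
        rects, _ = self.fixture()
        g = ReactionGroup("sc1", "sc2", ["p1", "p2"], "vertical")
        with caplog.at_level(logging.WARNING):
            aligns, seps = reaction_group_constraints([g], [], rects)
        assert aligns == [] and seps == []
        assert "demoted" in caplog.text


class TestContainmentConstraints:
    def submap_with_terminals(self):
        sm = Glyph("sm", GlyphClass.SUBMAP, "m", Rect(300, 100, 46, 17))
        t1 = Glyph("t1", GlyphClass.TERMINAL, "", Rect(311, 98, 24, 12),
                   parent_id="sm", terminal_side=Side.RIGHT)
        t2 = Glyph("t2", GlyphClass.TERMINAL, "", Rect(289, 102, 24, 12),
                   parent_id="sm", terminal_side=Side.LEFT)
        return SbgnMap(glyphs=[sm, t1, t2])

    def test_submap_with_two_terminals(self):
        cons, pins = containment_constraints(self.submap_with_terminals())
        assert len(cons) == 1 and sorted(cons[0].child_ids) == ["t1", "t2"]
        assert len(pins) == 2 and all(p.is_equality for p in pins)

    def test_map_without_submaps(self):
        assert containment_constraints(SbgnMap(glyphs=[chem("a", 0, 0)])) == ([], [])

    def test_right_side_pin_ties_to_right_border(self):
        cons, pins = containment_constraints(self.submap_with_terminals())
        pin = next(p for p in pins if "t1" in (p.left, p.right))
        # submap center + (46-24)/2 = terminal center keeps the right edges flush
        assert pin.axis == "x" and pin.left == "sm" and pin.right == "t1"
        assert pin.gap == pytest.approx(11.0)

    def test_compile_skips_pinned_axis(self):
        m = self.submap_with_terminals()
        cons, pins = containment_constraints(m)
        from kgml2sbgn.constraints import ConstraintSet

        cset = ConstraintSet(separations=pins, containments=cons)
        rects = {g.glyph_id: g.bbox for g in m.glyphs}
        eqs_x, ineqs_x = cset.compile_axis("x", rects)
        eqs_y, ineqs_y = cset.compile_axis("y", rects)
        assert len(eqs_x) == 2 and len(ineqs_x) == 0  # both terminals x-pinned
        assert len(eqs_y) == 0 and len(ineqs_y) == 4  # y containment, 2 each


class TestEnzymeConstraints:
    def test_side_above(self):
        pair = EnzymeProcessPair("mm", "pn", Side.TOP, 35.0)
        aligns, seps = enzyme_constraints([pair])
        assert aligns[0].axis == "x" and set(aligns[0].member_ids) == {"mm", "pn"}
        (s,) = seps
        assert (s.axis, s.left, s.right, s.gap, s.is_equality) == (
            "y", "mm", "pn", 35.0, True,
        )

    def test_side_left_is_symmetric(self):
        pair = EnzymeProcessPair("mm", "pn", Side.LEFT, 35.0)
        aligns, seps = enzyme_constraints([pair])
        assert aligns[0].axis == "y"
        assert seps[0].axis == "x" and seps[0].is_equality

    def test_no_pairs(self):
        assert enzyme_constraints([]) == ([], [])


class TestBuildConstraintSet:
    def test_all_references_resolve(self, multi_reaction_kgml):
        res = translated(multi_reaction_kgml)
        cset = build_constraint_set(res)
        known = {g.glyph_id for g in res.map.glyphs}
        known |= {a.guide for a in cset.alignments}
        for s in cset.separations:
            assert s.left in known and s.right in known
        for a in cset.alignments:
            assert set(a.member_ids) <= known

    def test_group_axis_order_excludes_group_processes(self, multi_reaction_kgml):
        res = translated(multi_reaction_kgml)
        cset = build_constraint_set(res)
        group_pns = set(res.groups[0].process_ids)
        for s in cset.separations:
            if s.axis == "y" and not s.is_equality:
                # consecutive group processes are spaced by the equality
                # chain; an additional order gap would contradict it
                assert not ({s.left, s.right} <= group_pns)
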