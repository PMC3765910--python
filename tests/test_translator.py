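import itertools

import pytest

from conftest import entry, kgml_doc, reaction, translated
from kgml2sbgn import kgml_io
from kgml2sbgn.sbgn_model import ArcClass, GlyphClass, Side
from kgml2sbgn.synth import SynthSpec, generate_kgml
from kgml2sbgn.translator import (
    detect_reaction_groups,
    place_initial,
    translate_pathway,
)


def class_counts(sbgn_map):
    glyphs = {}
    for g in sbgn_map.glyphs:
        glyphs[g.glyph_class] = glyphs.get(g.glyph_class, 0) + 1
    arcs = {}
    for a in sbgn_map.arcs:
        arcs[a.arc_class] = arcs.get(a.arc_class, 0) + 1
    return glyphs, arcs


class TestTableRules:
    def test_irreversible_reaction(self, simple_irreversible_kgml):
        res = translated(simple_irreversible_kgml)
        glyphs, arcs = class_counts(res.map)
        assert glyphs == {
            GlyphClass.SIMPLE_CHEMICAL: 2,
            GlyphClass.MACROMOLECULE: 1,
            GlyphClass.PROCESS: 1,
        }
        assert arcs == {
            ArcClass.CONSUMPTION: 1,
            ArcClass.PRODUCTION: 1,
            ArcClass.CATALYSIS: 1,
        }

    def test_reversible_reaction_uses_two_production_arcs(
        self, simple_reversible_kgml
    ):
        res = translated(simple_reversible_kgml)
        _, arcs = class_counts(res.map)
        assert arcs == {ArcClass.PRODUCTION: 2, ArcClass.CATALYSIS: 1}

    def test_map_link_gets_submap_terminal_equivalence(self, maplink_kgml):
        res = translated(maplink_kgml)
        glyphs, arcs = class_counts(res.map)
        assert glyphs[GlyphClass.SUBMAP] == 1
        assert glyphs[GlyphClass.TERMINAL] == 1
        assert arcs == {ArcClass.EQUIVALENCE: 1}
        te = next(g for g in res.map.glyphs if g.glyph_class is GlyphClass.TERMINAL)
        assert te.parent_id == "sm2"

    def test_empty_pathway(self):
        res = translate_pathway(kgml_io.parse_kgml(kgml_doc("")))
        assert res.map.glyphs == [] and res.map.arcs == []
        assert res.groups == [] and res.enzyme_pairs == []

    def test_parallel_reactions_make_a_group(self, multi_reaction_kgml):
        res = translated(multi_reaction_kgml)
        glyphs, _ = class_counts(res.map)
        assert glyphs[GlyphClass.PROCESS] == 2
        assert len(res.groups) == 1
        assert len(res.groups[0].process_ids) == 2

    def test_unknown_reversibility_translated_irreversible_but_flagged(self):
        text = kgml_doc(
            entry("1", "compound", 0, 0) + entry("2", "compound", 100, 0)
            + entry("3", "gene", 50, 0, w=46, h=17, reaction="rn:r1")
            + reaction("r1", ["1"], ["2"], rtype=None)
        )
        p = kgml_io.parse_kgml(text)
        flags = kgml_io.detect_ambiguities(p)
        res = translate_pathway(p, flags)
        _, arcs = class_counts(res.map)
        assert ArcClass.CONSUMPTION in arcs  # treated as irreversible
        pn = next(g for g in res.map.glyphs if g.glyph_class is GlyphClass.PROCESS)
        assert pn.flagged
        assert all(a.flagged for a in res.map.arcs)

    def test_group_entry_becomes_complex(self):
        text = kgml_doc(
            entry("1", "compound", 0, 0) + entry("2", "compound", 30, 0)
            + '<entry id="9" name="grp" type="group">'
            '<component id="1"/><component id="2"/></entry>'
        )
        res = translated(text)
        cx = next(g for g in res.map.glyphs if g.glyph_class is GlyphClass.COMPLEX)
        members = res.map.children(cx.glyph_id)
        assert {m.glyph_id for m in members} == {"sc1", "sc2"}
        assert all(cx.bbox.contains_rect(m.bbox) for m in members)

    def test_other_relations_skipped(self, caplog):
        text = kgml_doc(
            entry("1", "compound", 0, 0) + entry("2", "compound", 30, 0)
            + '<relation entry1="1" entry2="2" type="PPrel"/>'
        )
        res = translated(text)
        assert res.map.arcs == []


class TestCountLaw:
    @pytest.mark.parametrize("seed", range(12))
    def test_counts_match_closed_form(self, seed):
        text, man = generate_kgml(SynthSpec(seed=seed))
        res = translated(text)
        assert len(res.map.glyphs) == man.expected_glyphs
        assert len(res.map.arcs) == man.expected_arcs
        assert len(res.groups) == man.expected_reaction_groups

    def test_translation_deterministic(self):
        text, _ = generate_kgml(SynthSpec(seed=4))
        a = translated(text)
        b = translated(text)
        assert [g.glyph_id for g in a.map.glyphs] == [g.glyph_id for g in b.map.glyphs]
        assert [(x.arc_id, x.source_id, x.target_id) for x in a.map.arcs] == [
            (x.arc_id, x.source_id, x.target_id) for x in b.map.arcs
        ]


class TestDetectReactionGroups:
    def brute_force_pairs(self, res):
        pairs = {}
        for info in res.processes:
            if len(info.substrate_ids) == 1 and len(info.product_ids) == 1:
                key = frozenset((info.substrate_ids[0], info.product_ids[0]))
                if len(key) == 2:
                    pairs.setdefault(key, []).append(info.process_id)
        return {k: v for k, v in pairs.items() if len(v) >= 2}

    def test_three_stacked_processes_one_vertical_group(self):
        body = (
            entry("1", "compound", 100, 50)
            + entry("2", "compound", 100, 250)
            + "".join(
                entry(str(10 + i), "gene", 140, 110 + 40 * i, w=46, h=17,
                      reaction=f"rn:r{i}")
                + reaction(f"r{i}", ["1"], ["2"])
                for i in range(3)
            )
        )
        res = translated(kgml_doc(body))
        oracle = self.brute_force_pairs(res)
        assert len(res.groups) == len(oracle) == 1
        g = res.groups[0]
        assert g.orientation == "vertical"
        assert len(g.process_ids) == 3
        assert g.compound_a_id == "sc1" and g.compound_b_id == "sc2"

    def test_single_reactions_no_groups(self, simple_irreversible_kgml):
        res = translated(simple_irreversible_kgml)
        assert detect_reaction_groups(res) == []

    def test_two_distinct_multi_pairs(self):
        text, man = generate_kgml(SynthSpec(multi_reaction_pairs=2, seed=9))
        res = translated(text)
        oracle = self.brute_force_pairs(res)
        assert len(res.groups) == len(oracle) == 2


class TestPlaceInitial:
    def test_enzyme_above_for_horizontal_flow(self, simple_irreversible_kgml):
        res = translated(simple_irreversible_kgml)
        pn = res.map.glyph("pn3_r1")
        mm = res.map.glyph("mm3_r1")
        assert (pn.bbox.cx, pn.bbox.cy) == (100.0, 200.0)
        assert (mm.bbox.cx, mm.bbox.cy) == (100.0, 165.0)
        assert res.enzyme_pairs[0].side is Side.TOP

    def test_enzyme_left_for_vertical_flow(self, multi_reaction_kgml):
        res = translated(multi_reaction_kgml)
        for pair in res.enzyme_pairs:
            assert pair.side is Side.LEFT
            pn = res.map.glyph(pair.process_id).bbox
            mm = res.map.glyph(pair.macromolecule_id).bbox
            assert mm.cx == pytest.approx(pn.cx - 35.0)
            assert mm.cy == pytest.approx(pn.cy)

    def test_terminal_on_border_facing_partner(self, maplink_kgml):
        res = translated(maplink_kgml)
        te = next(g for g in res.map.glyphs if g.glyph_class is GlyphClass.TERMINAL)
        sm = res.map.glyph("sm2")
        # partner compound is to the submap's left
        assert te.terminal_side is Side.LEFT
        assert te.bbox.left == pytest.approx(sm.bbox.left)
        assert sm.bbox.contains_rect(te.bbox)

    def test_no_map_entries_no_terminals(self, simple_irreversible_kgml):
        res = translated(simple_irreversible_kgml)
        assert not any(
            g.glyph_class is GlyphClass.TERMINAL for g in res.map.glyphs
        )

    def test_group_processes_spread_about_midpoint(self, multi_reaction_kgml):
        res = translated(multi_reaction_kgml)
        g = res.groups[0]
        ys = [res.map.glyph(p).bbox.cy for p in g.process_ids]
        xs = [res.map.glyph(p).bbox.cx for p in g.process_ids]
        assert xs == [100.0, 100.0]
        assert ys == [pytest.approx(160.0 - 12.5), pytest.approx(160.0 + 12.5)]


class TestFlagPropagation:
    @pytest.mark.parametrize(
        "modes",
        list(itertools.combinations(
            ("drop_reaction_type", "drop_products", "orphan_role"), 2
        )),
    )
    def test_no_injected_defect_loses_its_marker(self, modes):
        from kgml2sbgn.synth import corrupt_kgml

        text, _ = generate_kgml(SynthSpec(seed=11))
        corrupted, injected = corrupt_kgml(text, modes, seed=5)
        p = kgml_io.parse_kgml(corrupted)
        flags = kgml_io.detect_ambiguities(p)
        res = translate_pathway(p, flags)
        flagged_sources = {
            g.source_ref for g in res.map.glyphs if g.flagged
        }
        for f in injected:
            assert f.target in flagged_sources
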