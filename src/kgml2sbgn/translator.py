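"""KEGG -> SBGN PD translation.

Every compound entry becomes a simple chemical; every "another map" entry a
submap with one terminal per incident map link; every catalyst of every
reaction becomes a macromolecule *plus* a process node joined by a catalysis
arc (this is what makes the node count grow during translation and what later
creates reaction groups when KEGG draws the same compound pair with several
reactions).  Irreversible reactions get consumption arcs in and production
arcs out; reversible reactions get production arcs on both sides.  KGML group
entries become complex glyphs containing their members.

Ambiguity flags detected on the KGML side are propagated onto every glyph and
arc derived from the flagged element so they can be rendered red.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .geometry import Rect, union_rect
from .kgml_io import (
    AmbiguityFlag,
    EntryType,
    KgmlPathway,
    RelationType,
    Reversibility,
)
from .sbgn_model import Arc, ArcClass, Glyph, GlyphClass, SbgnMap, Side

logger = logging.getLogger(__name__)

PROCESS_SIZE = (14.0, 14.0)
TERMINAL_SIZE = (24.0, 12.0)
MIN_CHEMICAL_SIZE = 20.0
COMPLEX_MARGIN = 8.0
DEFAULT_ENZYME_OFFSET = 35.0
DEFAULT_GROUP_SPACING = 25.0


@dataclass
class EnzymeProcessPair:
    macromolecule_id: str
    process_id: str
    side: Side = Side.TOP  # side of the process on which the enzyme sits
    offset: float = DEFAULT_ENZYME_OFFSET


@dataclass
class ReactionGroup:
    compound_a_id: str  # smaller coordinate on the group axis
    compound_b_id: str
    process_ids: list[str]
    orientation: str  # "horizontal" | "vertical"


@dataclass
class ProcessInfo:
    """Bookkeeping per translated process node."""

    process_id: str
    macromolecule_id: Optional[str]
    reaction_id: str
    reversible: bool
    substrate_ids: list[str]
    product_ids: list[str]
    consumption_arcs: list[str] = field(default_factory=list)
    production_arcs: list[str] = field(default_factory=list)
    catalysis_arc: Optional[str] = None


@dataclass
class TranslationResult:
    map: SbgnMap
    groups: list[ReactionGroup] = field(default_factory=list)
    enzyme_pairs: list[EnzymeProcessPair] = field(default_factory=list)
    flags: list[AmbiguityFlag] = field(default_factory=list)
    id_map: dict[str, list[str]] = field(default_factory=dict)  # KEGG id -> glyph ids
    reverse_id_map: dict[str, str] = field(default_factory=dict)  # glyph id -> KEGG id
    processes: list[ProcessInfo] = field(default_factory=list)
    terminal_partner: dict[str, str] = field(default_factory=dict)  # terminal -> partner glyph

    def process_by_id(self, pid: str) -> ProcessInfo:
        return next(p for p in self.processes if p.process_id == pid)


class TranslationError(ValueError):
    pass


def _primary_glyph(result: TranslationResult, entry_id: str) -> Optional[str]:
    ids = result.id_map.get(entry_id, [])
    return ids[0] if ids else None


def translate_pathway(
    pathway: KgmlPathway, flags: Optional[list[AmbiguityFlag]] = None
) -> TranslationResult:
    """Apply the one-to-one translation rules and build the side structures
    (enzyme/process pairs, reaction groups) the layout stage needs.

    ``flags`` are the ambiguities detected on the KGML side; the derived SBGN
    elements of each flagged reaction are marked ``flagged``.
    """
    flags = list(flags or [])
    flagged_reactions = {f.target for f in flags}
    result = TranslationResult(map=SbgnMap(), flags=flags)
    index = {e.entry_id: e for e in pathway.entries}
    arc_counter = 0

    def new_arc(cls: ArcClass, src: str, tgt: str, flagged: bool) -> Arc:
        nonlocal arc_counter
        arc_counter += 1
        arc = Arc(f"arc{arc_counter}", cls, src, tgt, flagged=flagged)
        result.map.arcs.append(arc)
        return arc

    def register(entry_id: str, glyph: Glyph) -> None:
        result.map.glyphs.append(glyph)
        result.id_map.setdefault(entry_id, []).append(glyph.glyph_id)
        result.reverse_id_map[glyph.glyph_id] = entry_id

    # --- nodes with a one-to-one translation -------------------------------
    for e in pathway.entries:
        cx, cy = e.center
        if e.entry_type is EntryType.COMPOUND:
            w = max(e.size[0], MIN_CHEMICAL_SIZE)
            h = max(e.size[1], MIN_CHEMICAL_SIZE)
            register(
                e.entry_id,
                Glyph(f"sc{e.entry_id}", GlyphClass.SIMPLE_CHEMICAL, e.label,
                      Rect(cx, cy, w, h), source_ref=e.entry_id),
            )
        elif e.entry_type is EntryType.MAP:
            register(
                e.entry_id,
                Glyph(f"sm{e.entry_id}", GlyphClass.SUBMAP, e.label,
                      Rect(cx, cy, *e.size), source_ref=e.entry_id),
            )

    # --- reactions: one macromolecule + process per catalyst ---------------
    for r in pathway.reactions:
        for ref in r.substrate_refs + r.product_refs:
            if ref not in index:
                raise TranslationError(
                    f"reaction {r.reaction_id} references missing entry {ref}"
                )
        is_flagged = r.reaction_id in flagged_reactions
        reversible = r.reversibility is Reversibility.REVERSIBLE
        substrate_glyphs = [
            g for ref in r.substrate_refs if (g := _primary_glyph(result, ref))
        ]
        product_glyphs = [
            g for ref in r.product_refs if (g := _primary_glyph(result, ref))
        ]

        catalysts = [index[c] for c in r.catalyst_refs]
        units: list[tuple[Optional[str], str]] = []
        if catalysts:
            for cat in catalysts:
                mm_id = f"mm{cat.entry_id}_{r.reaction_id}"
                pn_id = f"pn{cat.entry_id}_{r.reaction_id}"
                register(
                    cat.entry_id,
                    Glyph(mm_id, GlyphClass.MACROMOLECULE, cat.label,
                          Rect(*cat.center, *cat.size), flagged=is_flagged,
                          source_ref=cat.entry_id),
                )
                register(
                    cat.entry_id,
                    Glyph(pn_id, GlyphClass.PROCESS, "",
                          Rect(*cat.center, *PROCESS_SIZE), flagged=is_flagged,
                          source_ref=r.reaction_id),
                )
                units.append((mm_id, pn_id))
        else:
            # no catalyst entry: bare process at the participants' centroid
            pts = [index[ref].center for ref in r.substrate_refs + r.product_refs]
            cx = sum(p[0] for p in pts) / len(pts) if pts else 0.0
            cy = sum(p[1] for p in pts) / len(pts) if pts else 0.0
            pn_id = f"pn_{r.reaction_id}"
            result.map.glyphs.append(
                Glyph(pn_id, GlyphClass.PROCESS, "", Rect(cx, cy, *PROCESS_SIZE),
                      flagged=is_flagged, source_ref=r.reaction_id)
            )
            result.reverse_id_map[pn_id] = r.reaction_id
            units.append((None, pn_id))

        for mm_id, pn_id in units:
            info = ProcessInfo(
                process_id=pn_id, macromolecule_id=mm_id, reaction_id=r.reaction_id,
                reversible=reversible, substrate_ids=substrate_glyphs,
                product_ids=product_glyphs,
            )
            if mm_id is not None:
                arc = new_arc(ArcClass.CATALYSIS, mm_id, pn_id, is_flagged)
                info.catalysis_arc = arc.arc_id
                result.enzyme_pairs.append(EnzymeProcessPair(mm_id, pn_id))
            if reversible:
                for sc in substrate_glyphs:
                    a = new_arc(ArcClass.PRODUCTION, pn_id, sc, is_flagged)
                    info.production_arcs.append(a.arc_id)
                for sc in product_glyphs:
                    a = new_arc(ArcClass.PRODUCTION, pn_id, sc, is_flagged)
                    info.production_arcs.append(a.arc_id)
            else:
                # reversibility=unknown is translated as irreversible but flagged
                for sc in substrate_glyphs:
                    a = new_arc(ArcClass.CONSUMPTION, sc, pn_id, is_flagged)
                    info.consumption_arcs.append(a.arc_id)
                for sc in product_glyphs:
                    a = new_arc(ArcClass.PRODUCTION, pn_id, sc, is_flagged)
                    info.production_arcs.append(a.arc_id)
            result.processes.append(info)

    # --- map links: terminals + equivalence arcs ---------------------------
    terminal_count: dict[str, int] = {}
    for rel in pathway.relations:
        if rel.relation_type is not RelationType.MAPLINK:
            logger.warning(
                "relation %s-%s of type %s skipped (not translated)",
                rel.entry1, rel.entry2, rel.relation_type.value,
            )
            continue
        e1, e2 = index[rel.entry1], index[rel.entry2]
        if e1.entry_type is EntryType.MAP:
            map_entry, partner_entry = e1, e2
        elif e2.entry_type is EntryType.MAP:
            map_entry, partner_entry = e2, e1
        else:
            logger.warning(
                "maplink %s-%s has no map endpoint; skipped", rel.entry1, rel.entry2
            )
            continue
        if rel.via_compound and rel.via_compound in index:
            partner_entry = index[rel.via_compound]
        partner_glyph = _primary_glyph(result, partner_entry.entry_id)
        if partner_glyph is None:
            logger.warning(
                "maplink partner %s has no glyph; skipped", partner_entry.entry_id
            )
            continue
        sm_id = f"sm{map_entry.entry_id}"
        n = terminal_count.get(sm_id, 0) + 1
        terminal_count[sm_id] = n
        te_id = f"{sm_id}_t{n}"
        register(
            map_entry.entry_id,
            Glyph(te_id, GlyphClass.TERMINAL, partner_entry.label,
                  Rect(*map_entry.center, *TERMINAL_SIZE), parent_id=sm_id,
                  source_ref=map_entry.entry_id),
        )
        result.terminal_partner[te_id] = partner_glyph
        new_arc(ArcClass.EQUIVALENCE, te_id, partner_glyph, False)

    # --- group entries become complex glyphs -------------------------------
    for e in pathway.entries:
        if e.entry_type is not EntryType.GROUP or not e.component_ids:
            continue
        member_glyphs = [
            gid for cid in e.component_ids for gid in result.id_map.get(cid, [])
        ]
        if not member_glyphs:
            logger.warning("group entry %s has no translated members", e.entry_id)
            continue
        cx_id = f"cx{e.entry_id}"
        boxes = [result.map.glyph(g).bbox for g in member_glyphs]
        bbox = union_rect(boxes).inflate(COMPLEX_MARGIN)
        register(
            e.entry_id,
            Glyph(cx_id, GlyphClass.COMPLEX, e.label, bbox, source_ref=e.entry_id),
        )
        for gid in member_glyphs:
            result.map.glyph(gid).parent_id = cx_id

    result.groups = detect_reaction_groups(result)
    return result


def detect_reaction_groups(result: TranslationResult) -> list[ReactionGroup]:
    """Find compound pairs connected by two or more processes.

    Orientation is vertical when the pair's centers differ more in y than in
    x; process order follows the original KGML position along the pair axis
    (ties by id).
    """
    by_pair: dict[frozenset, list[ProcessInfo]] = {}
    for info in result.processes:
        if len(info.substrate_ids) == 1 and len(info.product_ids) == 1:
            key = frozenset((info.substrate_ids[0], info.product_ids[0]))
            if len(key) == 2:
                by_pair.setdefault(key, []).append(info)

    groups: list[ReactionGroup] = []
    for key in sorted(by_pair, key=lambda k: sorted(k)):
        infos = by_pair[key]
        if len(infos) < 2:
            continue
        a_id, b_id = sorted(key)
        ga, gb = result.map.glyph(a_id).bbox, result.map.glyph(b_id).bbox
        vertical = abs(gb.cy - ga.cy) > abs(gb.cx - ga.cx)
        # order the two compounds along the group axis
        if (ga.cy if vertical else ga.cx) > (gb.cy if vertical else gb.cx):
            a_id, b_id = b_id, a_id
        ordered = sorted(
            infos,
            key=lambda i: (
                result.map.glyph(i.process_id).bbox.cy
                if vertical
                else result.map.glyph(i.process_id).bbox.cx,
                i.process_id,
            ),
        )
        groups.append(
            ReactionGroup(
                compound_a_id=a_id,
                compound_b_id=b_id,
                process_ids=[i.process_id for i in ordered],
                orientation="vertical" if vertical else "horizontal",
            )
        )
    return groups


def _flow_direction(result: TranslationResult, info: ProcessInfo) -> tuple[float, float]:
    """Substrate -> product direction from the original KGML centers."""

    def mean(ids: list[str]) -> Optional[tuple[float, float]]:
        boxes = [result.map.glyph(g).bbox for g in ids if g in result.map.index()]
        if not boxes:
            return None
        return (
            sum(b.cx for b in boxes) / len(boxes),
            sum(b.cy for b in boxes) / len(boxes),
        )

    s, p = mean(info.substrate_ids), mean(info.product_ids)
    if s is None or p is None:
        return (1.0, 0.0)
    return (p[0] - s[0], p[1] - s[1])


def place_initial(
    result: TranslationResult,
    enzyme_offset: float = DEFAULT_ENZYME_OFFSET,
    group_spacing: float = DEFAULT_GROUP_SPACING,
) -> TranslationResult:
    """Assign desired positions to the glyphs that have no KGML coordinate of
    their own.

    Processes sit at their catalyst's KGML center; the macromolecule is
    displaced perpendicular to the substrate->product flow (above for a
    horizontal reaction, to the left for a vertical one); reaction-group
    processes are re-spread along the group axis about the compound-pair
    midpoint; terminals are pinned to the submap border facing their
    equivalence partner.
    """
    index = result.map.index()
    group_members = {pid for g in result.groups for pid in g.process_ids}

    # re-spread reaction-group processes about the pair midpoint
    for g in result.groups:
        a, b = index[g.compound_a_id].bbox, index[g.compound_b_id].bbox
        mid = ((a.cx + b.cx) / 2.0, (a.cy + b.cy) / 2.0)
        k = len(g.process_ids)
        for i, pid in enumerate(g.process_ids):
            off = (i - (k - 1) / 2.0) * group_spacing
            pn = index[pid]
            if g.orientation == "vertical":
                pn.bbox = pn.bbox.moved_to(mid[0], mid[1] + off)
            else:
                pn.bbox = pn.bbox.moved_to(mid[0] + off, mid[1])

    # enzymes: perpendicular offset; record the side on the pair
    for pair in result.enzyme_pairs:
        info = result.process_by_id(pair.process_id)
        pn = index[pair.process_id]
        mm = index[pair.macromolecule_id]
        dx, dy = _flow_direction(result, info)
        pair.offset = enzyme_offset
        if abs(dx) >= abs(dy):  # horizontal flow -> enzyme above
            pair.side = Side.TOP
            mm.bbox = mm.bbox.moved_to(pn.bbox.cx, pn.bbox.cy - enzyme_offset)
        else:  # vertical flow -> enzyme to the left
            pair.side = Side.LEFT
            mm.bbox = mm.bbox.moved_to(pn.bbox.cx - enzyme_offset, pn.bbox.cy)

    # terminals on the submap border facing their partner
    terminals_per_side: dict[tuple[str, Side], list[Glyph]] = {}
    for te_id, partner_id in result.terminal_partner.items():
        te = index[te_id]
        sm = index[te.parent_id]
        partner = index[partner_id]
        dx = partner.bbox.cx - sm.bbox.cx
        dy = partner.bbox.cy - sm.bbox.cy
        if abs(dx) >= abs(dy):
            side = Side.RIGHT if dx >= 0 else Side.LEFT
        else:
            side = Side.BOTTOM if dy >= 0 else Side.TOP
        te.terminal_side = side
        terminals_per_side.setdefault((sm.glyph_id, side), []).append(te)

    for (sm_id, side), tes in terminals_per_side.items():
        sm = index[sm_id].bbox
        tes.sort(key=lambda t: t.glyph_id)
        k = len(tes)
        for i, te in enumerate(tes):
            w = min(te.bbox.w, sm.w)
            h = min(te.bbox.h, sm.h)
            if side in (Side.LEFT, Side.RIGHT):
                cx = sm.left + w / 2.0 if side is Side.LEFT else sm.right - w / 2.0
                cy = sm.top + (i + 1) * sm.h / (k + 1)
                cy = min(max(cy, sm.top + h / 2.0), sm.bottom - h / 2.0)
            else:
                cy = sm.top + h / 2.0 if side is Side.TOP else sm.bottom - h / 2.0
                cx = sm.left + (i + 1) * sm.w / (k + 1)
                cx = min(max(cx, sm.left + w / 2.0), sm.right - w / 2.0)
            te.bbox = Rect(cx, cy, w, h)

    # complexes: recompute bbox from (possibly moved) members
    for g in result.map.glyphs:
        if g.glyph_class is GlyphClass.COMPLEX:
            members = result.map.children(g.glyph_id)
            if members:
                g.bbox = union_rect([m.bbox for m in members]).inflate(COMPLEX_MARGIN)
    return result
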