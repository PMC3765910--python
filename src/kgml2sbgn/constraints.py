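"""Geometric constraint inference and construction for the layout stage.

Three families of constraints are produced, mirroring the layout model:

* **Recognizability** — alignment groups inferred from the original KEGG
  coordinates (single-linkage within a small tolerance, per axis, over
  compounds and processes regardless of connectivity), plus order-preserving
  separation constraints between consecutive alignment guides/singletons so
  the original left-to-right / top-to-bottom reading can never invert.
* **Beautification** — non-overlap is *not* expressed here; the layout stage
  resolves it greedily at a lower priority using enlarged node sizes.
* **Style** — containment of terminals in submaps (and members in
  complexes), border pinning of terminals, fixed relative position of each
  enzyme macromolecule w.r.t. its process node, and reaction-group
  alignment/spacing.

Everything compiles down to separation constraints ``u + g <= v`` (or ``=``)
over per-axis position variables: glyph centers and free alignment-guide
variables that are co-optimized with the nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .geometry import Rect
from .sbgn_model import GlyphClass, SbgnMap, Side
from .translator import EnzymeProcessPair, ReactionGroup, TranslationResult

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 4.0
DEFAULT_MIN_GROUP_GAP = 20.0
DEFAULT_GROUP_SPACING = 25.0
GROUP_END_PAD = 6.0

ALIGNABLE_CLASSES = (GlyphClass.SIMPLE_CHEMICAL, GlyphClass.PROCESS)


@dataclass
class AlignmentConstraint:
    axis: str  # "x" | "y"
    member_ids: list[str]
    guide: str  # name of the shared position variable
    guide_pos: float  # initial value (group mean); the guide itself is free


@dataclass
class SeparationConstraint:
    axis: str
    left: str  # variable key: glyph id or guide name
    right: str
    gap: float
    is_equality: bool = False
    tier: str = "hard"  # "hard" | "nonoverlap"


@dataclass
class ContainmentConstraint:
    parent_id: str
    child_ids: list[str]
    margin: float = 0.0
    # axes (per child) already pinned by an equality; containment skips them
    pinned_axis: dict[str, str] = field(default_factory=dict)


@dataclass
class ConstraintSet:
    alignments: list[AlignmentConstraint] = field(default_factory=list)
    separations: list[SeparationConstraint] = field(default_factory=list)
    containments: list[ContainmentConstraint] = field(default_factory=list)
    enzyme_pairs: list[EnzymeProcessPair] = field(default_factory=list)

    def guides(self) -> dict[str, float]:
        return {a.guide: a.guide_pos for a in self.alignments}

    def compile_axis(
        self, axis: str, rects: dict[str, Rect]
    ) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
        """Lower everything on one axis to (left, right, gap) triples.

        Returns ``(equalities, inequalities)``.  Containment produces
        inequalities with negative gaps (a child center may lie on either
        side of the parent center).
        """
        eqs: list[tuple[str, str, float]] = []
        ineqs: list[tuple[str, str, float]] = []
        for a in self.alignments:
            if a.axis == axis:
                for m in a.member_ids:
                    eqs.append((a.guide, m, 0.0))
        for s in self.separations:
            if s.axis != axis:
                continue
            (eqs if s.is_equality else ineqs).append((s.left, s.right, s.gap))
        for c in self.containments:
            parent = rects[c.parent_id]
            p_half = (parent.w if axis == "x" else parent.h) / 2.0
            for child_id in c.child_ids:
                if c.pinned_axis.get(child_id) == axis:
                    continue
                child = rects[child_id]
                c_half = (child.w if axis == "x" else child.h) / 2.0
                slack = p_half - c.margin - c_half
                ineqs.append((c.parent_id, child_id, -slack))
                ineqs.append((child_id, c.parent_id, -slack))
        return eqs, ineqs


def _single_linkage_1d(
    items: list[tuple[float, str]], tolerance: float
) -> list[list[tuple[float, str]]]:
    """1-D single-linkage clustering: sorted neighbors within tolerance chain up."""
    if not items:
        return []
    ordered = sorted(items)  # (coord, id): deterministic tie-break by id
    clusters = [[ordered[0]]]
    for item in ordered[1:]:
        if item[0] - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    return clusters


def infer_alignments(
    glyphs: Iterable, tolerance: float = DEFAULT_TOLERANCE,
    axes: tuple[str, ...] = ("x", "y"),
) -> list[AlignmentConstraint]:
    """Infer visually-intended alignment groups from desired positions.

    Compounds (simple chemicals) and processes participate, connected or not;
    groups need at least two members; the guide starts at the group mean.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    eligible = [
        g for g in glyphs
        if g.glyph_class in ALIGNABLE_CLASSES and g.bbox is not None
    ]
    out: list[AlignmentConstraint] = []
    for axis in axes:
        items = [
            ((g.bbox.cx if axis == "x" else g.bbox.cy), g.glyph_id) for g in eligible
        ]
        n = 0
        for cluster in _single_linkage_1d(items, tolerance):
            if len(cluster) < 2:
                continue
            mean = sum(c for c, _ in cluster) / len(cluster)
            out.append(
                AlignmentConstraint(
                    axis=axis,
                    member_ids=[gid for _, gid in cluster],
                    guide=f"g{axis}{n}",
                    guide_pos=mean,
                )
            )
            n += 1
    return out


def order_constraints(
    alignments: list[AlignmentConstraint],
    glyphs: Iterable,
    axis: str,
    extents: Optional[dict[str, float]] = None,
    min_group_gap: float = DEFAULT_MIN_GROUP_GAP,
    exclude: Optional[set[str]] = None,
) -> list[SeparationConstraint]:
    """Chain consecutive alignment guides and unaligned singletons along one
    axis so the relative orthogonal order is preserved.

    ``extents`` maps glyph id to its full extent on this axis (layout passes
    enlarged sizes); the gap between consecutive items is the larger of
    ``min_group_gap`` and the sum of the two half-extents of the widest
    members involved.
    """
    exclude = exclude or set()
    glyph_list = [
        g for g in glyphs
        if g.glyph_class in ALIGNABLE_CLASSES and g.bbox is not None
        and g.glyph_id not in exclude
    ]
    extents = extents or {
        g.glyph_id: (g.bbox.w if axis == "x" else g.bbox.h) for g in glyph_list
    }
    aligned_ids = {
        m for a in alignments if a.axis == axis for m in a.member_ids
    }
    items: list[tuple[float, str, float]] = []  # (coord, key, half_extent)
    for a in alignments:
        if a.axis != axis:
            continue
        members = [m for m in a.member_ids if m not in exclude]
        if not members:
            continue
        half = max(extents.get(m, 0.0) for m in members) / 2.0
        items.append((a.guide_pos, a.guide, half))
    for g in glyph_list:
        if g.glyph_id in aligned_ids:
            continue
        coord = g.bbox.cx if axis == "x" else g.bbox.cy
        items.append((coord, g.glyph_id, extents.get(g.glyph_id, 0.0) / 2.0))

    items.sort(key=lambda t: (t[0], t[1]))
    out: list[SeparationConstraint] = []
    for (c1, k1, h1), (c2, k2, h2) in zip(items[:-1], items[1:]):
        out.append(
            SeparationConstraint(
                axis=axis, left=k1, right=k2,
                gap=max(min_group_gap, h1 + h2),
            )
        )
    return out


def reaction_group_constraints(
    groups: list[ReactionGroup],
    alignments: list[AlignmentConstraint],
    rects: dict[str, Rect],
    group_spacing: float = DEFAULT_GROUP_SPACING,
) -> tuple[list[AlignmentConstraint], list[SeparationConstraint]]:
    """Alignment + spacing constraints lining up each reaction group between
    its two compounds.

    Precondition: the group's compounds share an alignment on the axis
    perpendicular to the group orientation; otherwise the group is demoted to
    independent processes with a warning.
    """
    new_alignments: list[AlignmentConstraint] = []
    seps: list[SeparationConstraint] = []
    for i, g in enumerate(groups):
        perp = "x" if g.orientation == "vertical" else "y"
        along = "y" if g.orientation == "vertical" else "x"
        shared = any(
            a.axis == perp
            and g.compound_a_id in a.member_ids
            and g.compound_b_id in a.member_ids
            for a in alignments
        )
        if not shared:
            logger.warning(
                "reaction group %s-%s: compounds not aligned on %s axis; "
                "demoted to independent processes",
                g.compound_a_id, g.compound_b_id, perp,
            )
            continue
        coords = [
            (rects[p].cx if perp == "x" else rects[p].cy) for p in g.process_ids
        ]
        new_alignments.append(
            AlignmentConstraint(
                axis=perp, member_ids=list(g.process_ids),
                guide=f"grp{i}{perp}", guide_pos=sum(coords) / len(coords),
            )
        )
        for p1, p2 in zip(g.process_ids[:-1], g.process_ids[1:]):
            seps.append(
                SeparationConstraint(
                    axis=along, left=p1, right=p2, gap=group_spacing,
                    is_equality=True,
                )
            )

        def half(key: str) -> float:
            r = rects[key]
            return (r.h if along == "y" else r.w) / 2.0

        first, last = g.process_ids[0], g.process_ids[-1]
        seps.append(
            SeparationConstraint(
                axis=along, left=g.compound_a_id, right=first,
                gap=half(g.compound_a_id) + half(first) + GROUP_END_PAD,
            )
        )
        seps.append(
            SeparationConstraint(
                axis=along, left=last, right=g.compound_b_id,
                gap=half(last) + half(g.compound_b_id) + GROUP_END_PAD,
            )
        )
    return new_alignments, seps


def containment_constraints(
    sbgn_map: SbgnMap,
) -> tuple[list[ContainmentConstraint], list[SeparationConstraint]]:
    """Containment for submap terminals and complex members, plus the border
    pin of each terminal: an equality separation tying the terminal to the
    parent border on its side (margin 0 there)."""
    containments: list[ContainmentConstraint] = []
    pins: list[SeparationConstraint] = []
    index = sbgn_map.index()
    for parent in sbgn_map.glyphs:
        children = sbgn_map.children(parent.glyph_id)
        if not children:
            continue
        if parent.glyph_class is GlyphClass.SUBMAP:
            pinned: dict[str, str] = {}
            for te in children:
                if te.terminal_side is None:
                    raise ValueError(f"terminal {te.glyph_id} has no side assigned")
                p, t = parent.bbox, te.bbox
                side = te.terminal_side
                if side in (Side.LEFT, Side.RIGHT):
                    gap = (p.w - t.w) / 2.0
                    left, right = (
                        (te.glyph_id, parent.glyph_id) if side is Side.LEFT
                        else (parent.glyph_id, te.glyph_id)
                    )
                    pins.append(
                        SeparationConstraint("x", left, right, gap, is_equality=True)
                    )
                    pinned[te.glyph_id] = "x"
                else:
                    gap = (p.h - t.h) / 2.0
                    left, right = (
                        (te.glyph_id, parent.glyph_id) if side is Side.TOP
                        else (parent.glyph_id, te.glyph_id)
                    )
                    pins.append(
                        SeparationConstraint("y", left, right, gap, is_equality=True)
                    )
                    pinned[te.glyph_id] = "y"
            containments.append(
                ContainmentConstraint(
                    parent_id=parent.glyph_id,
                    child_ids=[c.glyph_id for c in children],
                    margin=0.0,
                    pinned_axis=pinned,
                )
            )
        elif parent.glyph_class is GlyphClass.COMPLEX:
            containments.append(
                ContainmentConstraint(
                    parent_id=parent.glyph_id,
                    child_ids=[c.glyph_id for c in children],
                    margin=2.0,
                )
            )
    # silence unused-variable linters for index; kept for symmetry of checks
    del index
    return containments, pins


def enzyme_constraints(
    pairs: list[EnzymeProcessPair],
) -> tuple[list[AlignmentConstraint], list[SeparationConstraint]]:
    """Fix each macromolecule relative to its process: one alignment on the
    axis perpendicular to the side, one equality separation of the configured
    offset on the other axis.  Both are hard-tier."""
    alignments: list[AlignmentConstraint] = []
    seps: list[SeparationConstraint] = []
    for i, pair in enumerate(pairs):
        mm, pn = pair.macromolecule_id, pair.process_id
        if pair.side in (Side.TOP, Side.BOTTOM):
            alignments.append(
                AlignmentConstraint("x", [mm, pn], f"enz{i}x", 0.0)
            )
            left, right = (mm, pn) if pair.side is Side.TOP else (pn, mm)
            seps.append(
                SeparationConstraint("y", left, right, pair.offset, is_equality=True)
            )
        else:
            alignments.append(
                AlignmentConstraint("y", [mm, pn], f"enz{i}y", 0.0)
            )
            left, right = (mm, pn) if pair.side is Side.LEFT else (pn, mm)
            seps.append(
                SeparationConstraint("x", left, right, pair.offset, is_equality=True)
            )
    return alignments, seps


def build_constraint_set(
    result: TranslationResult,
    tolerance: float = DEFAULT_TOLERANCE,
    min_group_gap: float = DEFAULT_MIN_GROUP_GAP,
    group_spacing: float = DEFAULT_GROUP_SPACING,
    node_margin: float = 10.0,
) -> ConstraintSet:
    """Assemble the full constraint set for a translated, initially placed map."""
    glyphs = result.map.glyphs
    rects = {g.glyph_id: g.bbox for g in glyphs}
    cset = ConstraintSet(enzyme_pairs=result.enzyme_pairs)

    cset.alignments.extend(infer_alignments(glyphs, tolerance))

    grp_aligns, grp_seps = reaction_group_constraints(
        result.groups, cset.alignments, rects, group_spacing
    )
    cset.alignments.extend(grp_aligns)
    cset.separations.extend(grp_seps)

    # guide positions need fixing before ordering; enzyme guides resolve from
    # their members, so add enzyme constraints after ordering is derived
    group_member_axis: dict[str, set[str]] = {"x": set(), "y": set()}
    for g in result.groups:
        along = "y" if g.orientation == "vertical" else "x"
        group_member_axis[along].update(g.process_ids)

    enlarged = {
        gid: {"x": r.w + 2 * node_margin, "y": r.h + 2 * node_margin}
        for gid, r in rects.items()
    }
    for axis in ("x", "y"):
        cset.separations.extend(
            order_constraints(
                [a for a in cset.alignments if not a.guide.startswith(("enz", "grp"))],
                glyphs,
                axis,
                extents={gid: e[axis] for gid, e in enlarged.items()},
                min_group_gap=min_group_gap,
                exclude=group_member_axis[axis],
            )
        )

    containments, pins = containment_constraints(result.map)
    cset.containments.extend(containments)
    cset.separations.extend(pins)

    enz_aligns, enz_seps = enzyme_constraints(result.enzyme_pairs)
    cset.alignments.extend(enz_aligns)
    cset.separations.extend(enz_seps)
    return cset
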