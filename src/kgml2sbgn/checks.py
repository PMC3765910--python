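"""Quantitative quality checks on converted maps.

These measure, rather than assume, the layout-requirement properties: node
overlap, hard-constraint satisfaction, route orthogonality, obstacle
avoidance, residual collinear edge overlap, and checkpoint visiting.  They
back both the test suite and the reproducibility script.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .geometry import OrthoRoute, Rect, segment_crosses_rect
from .sbgn_model import SbgnMap
from .translator import TranslationResult


def overlapping_pairs(sbgn_map: SbgnMap, tol: float = 1e-6) -> list[tuple[str, str]]:
    """Pairs of glyphs with actual-size bbox overlap, ancestor chains excluded."""
    index = sbgn_map.index()

    def ancestors(gid: str) -> set[str]:
        out = set()
        g = index[gid]
        while g.parent_id is not None:
            out.add(g.parent_id)
            g = index[g.parent_id]
        return out

    glyphs = [g for g in sbgn_map.glyphs if g.bbox is not None]
    out = []
    for i, a in enumerate(glyphs):
        for b in glyphs[i + 1 :]:
            if a.glyph_id in ancestors(b.glyph_id) or b.glyph_id in ancestors(a.glyph_id):
                continue
            if a.bbox.overlaps(b.bbox) and a.bbox.overlap_area(b.bbox) > tol:
                out.append((a.glyph_id, b.glyph_id))
    return out


def segment_obstacle_crossings(
    route: OrthoRoute, obstacles: list[Rect], eps: float = 1e-9
) -> int:
    n = 0
    for a, b in route.segments():
        for r in obstacles:
            if segment_crosses_rect(a, b, r, eps):
                n += 1
    return n


def collinear_overlap_length(
    routes: dict[str, OrthoRoute],
    shared_prefix_ok: Optional[dict[str, object]] = None,
    tol: float = 1e-6,
) -> float:
    """Total length of collinear overlap between segments of distinct routes.

    ``shared_prefix_ok`` maps arc id to a bundle key; overlap between two
    routes of the same bundle is permitted (their shared corridor is by
    design) and not counted.
    """
    shared_prefix_ok = shared_prefix_ok or {}
    items = []
    for arc_id, route in routes.items():
        for (a, b) in route.segments():
            horizontal = abs(a[1] - b[1]) <= 1e-9
            cross = a[1] if horizontal else a[0]
            lo, hi = sorted((a[0], b[0]) if horizontal else (a[1], b[1]))
            items.append((arc_id, horizontal, cross, lo, hi))
    total = 0.0
    for i, (id1, h1, c1, lo1, hi1) in enumerate(items):
        for (id2, h2, c2, lo2, hi2) in items[i + 1 :]:
            if id1 == id2 or h1 != h2 or abs(c1 - c2) > tol:
                continue
            b1, b2 = shared_prefix_ok.get(id1), shared_prefix_ok.get(id2)
            if b1 is not None and b1 == b2:
                continue
            ov = min(hi1, hi2) - max(lo1, lo2)
            if ov > tol:
                total += ov
    return total


def visits_checkpoints(
    route: OrthoRoute, checkpoints: Iterable[tuple[float, float]], tol: float = 1e-6
) -> bool:
    """True when the polyline passes through every checkpoint in order."""
    segs = route.segments()
    pos = 0
    for cp in checkpoints:
        found = False
        for si in range(pos, len(segs)):
            (x1, y1), (x2, y2) = segs[si]
            on = (
                min(x1, x2) - tol <= cp[0] <= max(x1, x2) + tol
                and min(y1, y2) - tol <= cp[1] <= max(y1, y2) + tol
                and (abs(x1 - x2) <= tol or abs(y1 - y2) <= tol)
                and (
                    (abs(y1 - y2) <= tol and abs(cp[1] - y1) <= tol)
                    or (abs(x1 - x2) <= tol and abs(cp[0] - x1) <= tol)
                )
            )
            if on:
                pos = si
                found = True
                break
        if not found:
            return False
    return True


def guide_order_preserved(
    layout_result, cset, axis: str
) -> bool:
    """Relative order of alignment guides on one axis matches the input order."""
    inferred = [
        a for a in cset.alignments
        if a.axis == axis and not a.guide.startswith(("enz", "grp"))
    ]
    before = [a.guide for a in sorted(inferred, key=lambda a: a.guide_pos)]
    solved = {
        a.guide: layout_result.guide_values[a.guide][0 if axis == "x" else 1]
        for a in inferred
    }
    after = sorted(before, key=lambda g: solved[g])
    return before == after


def flagged_elements(sbgn_map: SbgnMap) -> tuple[set[str], set[str]]:
    """Ids of flagged glyphs and flagged arcs."""
    return (
        {g.glyph_id for g in sbgn_map.glyphs if g.flagged},
        {a.arc_id for a in sbgn_map.arcs if a.flagged},
    )


def route_quality(result: TranslationResult, buffer: float) -> dict:
    """Orthogonality, obstacle-crossing and port-side compliance counts for a
    routed map."""
    from .routing import build_obstacles

    obstacles = build_obstacles(result, buffer)
    index = result.map.index()
    non_orthogonal = 0
    crossings = 0
    for a in result.map.arcs:
        if a.route is None:
            continue
        if not a.route.is_orthogonal():
            non_orthogonal += 1
            continue
        endpoint_roots = set()
        for gid in (a.source_id, a.target_id):
            g = index[gid]
            while g.parent_id is not None:
                g = index[g.parent_id]
            endpoint_roots.add(g.glyph_id)
        rects = [
            o.rect for o in obstacles
            if not any(gid in endpoint_roots for gid in o.owners)
        ]
        crossings += segment_obstacle_crossings(a.route, rects)
    return {"non_orthogonal": non_orthogonal, "obstacle_crossings": crossings}
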