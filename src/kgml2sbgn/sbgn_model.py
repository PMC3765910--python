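"""SBGN Process Description map model: structural validation, SBGN-ML
serialization and an SVG renderer.

The model is deliberately small: glyphs (nodes with a center-based bounding
box) and arcs (edges with an optional orthogonal route).  Coordinates stay in
the y-down pixel frame of the input KGML.  The emitted SBGN-ML follows the
0.2-era schema (map/glyph/arc with bbox and start/next/end arc points); bbox
x/y are written as the top-left corner, as that dialect requires.

Ambiguity flags (defective KGML source information) travel on glyphs and arcs
as a boolean and are serialized in a small extension attribute so that a
write -> parse round trip preserves them; the renderer strokes flagged
elements red.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from lxml import etree

from .geometry import OrthoRoute, Rect

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
EXT_NS = "https://example.org/kgml2sbgn"
_NSMAP = {None: SBGN_NS, "k2s": EXT_NS}


class GlyphClass(str, Enum):
    SIMPLE_CHEMICAL = "simple chemical"
    MACROMOLECULE = "macromolecule"
    PROCESS = "process"
    SUBMAP = "submap"
    TERMINAL = "terminal"
    COMPLEX = "complex"


class ArcClass(str, Enum):
    CONSUMPTION = "consumption"
    PRODUCTION = "production"
    CATALYSIS = "catalysis"
    EQUIVALENCE = "equivalence arc"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    TOP = "top"
    BOTTOM = "bottom"


@dataclass
class Glyph:
    glyph_id: str
    glyph_class: GlyphClass
    label: str = ""
    bbox: Optional[Rect] = None
    parent_id: Optional[str] = None
    terminal_side: Optional[Side] = None
    flagged: bool = False
    source_ref: str = ""  # original KGML id (reaction id on processes)


@dataclass
class Arc:
    arc_id: str
    arc_class: ArcClass
    source_id: str
    target_id: str
    route: Optional[OrthoRoute] = None
    flagged: bool = False


@dataclass
class SbgnMap:
    language: str = "process description"
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)

    def glyph(self, glyph_id: str) -> Glyph:
        return self.index()[glyph_id]

    def index(self) -> dict[str, Glyph]:
        return {g.glyph_id: g for g in self.glyphs}

    def children(self, parent_id: Optional[str]) -> list[Glyph]:
        return [g for g in self.glyphs if g.parent_id == parent_id]


# arc endpoint class rules of the PD dialect used here
_SOURCE_CLASSES = {
    ArcClass.CONSUMPTION: {GlyphClass.SIMPLE_CHEMICAL, GlyphClass.TERMINAL},
    ArcClass.PRODUCTION: {GlyphClass.PROCESS},
    ArcClass.CATALYSIS: {GlyphClass.MACROMOLECULE},
}
_TARGET_CLASSES = {
    ArcClass.CONSUMPTION: {GlyphClass.PROCESS},
    ArcClass.PRODUCTION: {GlyphClass.SIMPLE_CHEMICAL, GlyphClass.TERMINAL},
    ArcClass.CATALYSIS: {GlyphClass.PROCESS},
}


def _is_ancestor(index: dict[str, Glyph], a: Glyph, b: Glyph) -> bool:
    cur = b
    while cur.parent_id is not None:
        if cur.parent_id == a.glyph_id:
            return True
        cur = index[cur.parent_id]
    return False


def validate_map(sbgn_map: SbgnMap, tol: float = 1e-6) -> list[str]:
    """Structural validation: id resolution, arc endpoint classes, node
    overlap outside ancestor chains, and terminal-on-border placement.

    Returns a list of human-readable violations; empty means valid.
    """
    violations: list[str] = []
    index = sbgn_map.index()
    if len(index) != len(sbgn_map.glyphs):
        violations.append("duplicate glyph ids")

    for g in sbgn_map.glyphs:
        if g.bbox is None:
            violations.append(f"glyph {g.glyph_id} has no bbox")
        elif g.bbox.w <= 0 or g.bbox.h <= 0:
            violations.append(f"glyph {g.glyph_id} has non-positive bbox")
        if g.parent_id is not None and g.parent_id not in index:
            violations.append(f"glyph {g.glyph_id} parent {g.parent_id} unresolved")
        if g.glyph_class is GlyphClass.TERMINAL:
            if g.parent_id is None or index.get(g.parent_id) is None or (
                index[g.parent_id].glyph_class is not GlyphClass.SUBMAP
            ):
                violations.append(f"terminal {g.glyph_id} not inside a submap")

    for a in sbgn_map.arcs:
        src = index.get(a.source_id)
        tgt = index.get(a.target_id)
        if src is None or tgt is None:
            violations.append(f"arc {a.arc_id} endpoint unresolved")
            continue
        if a.arc_class is ArcClass.EQUIVALENCE:
            if GlyphClass.TERMINAL not in (src.glyph_class, tgt.glyph_class):
                violations.append(f"equivalence arc {a.arc_id} touches no terminal")
        else:
            if src.glyph_class not in _SOURCE_CLASSES[a.arc_class]:
                violations.append(
                    f"arc {a.arc_id} ({a.arc_class.value}) has illegal source class "
                    f"{src.glyph_class.value}"
                )
            if tgt.glyph_class not in _TARGET_CLASSES[a.arc_class]:
                violations.append(
                    f"arc {a.arc_id} ({a.arc_class.value}) has illegal target class "
                    f"{tgt.glyph_class.value}"
                )

    placed = [g for g in sbgn_map.glyphs if g.bbox is not None]
    for i, g in enumerate(placed):
        for h in placed[i + 1 :]:
            if _is_ancestor(index, g, h) or _is_ancestor(index, h, g):
                continue
            if g.bbox.overlaps(h.bbox) and g.bbox.overlap_area(h.bbox) > tol:
                violations.append(f"glyphs {g.glyph_id} and {h.glyph_id} overlap")

    for g in sbgn_map.glyphs:
        if g.glyph_class is not GlyphClass.TERMINAL or g.bbox is None:
            continue
        parent = index.get(g.parent_id or "")
        if parent is None or parent.bbox is None or g.terminal_side is None:
            continue
        p, t = parent.bbox, g.bbox
        ok = {
            Side.LEFT: abs(t.left - p.left) <= tol,
            Side.RIGHT: abs(t.right - p.right) <= tol,
            Side.TOP: abs(t.top - p.top) <= tol,
            Side.BOTTOM: abs(t.bottom - p.bottom) <= tol,
        }[g.terminal_side]
        if not ok or not p.contains_rect(t, tol=tol):
            violations.append(
                f"terminal {g.glyph_id} not on {g.terminal_side.value} border of "
                f"{parent.glyph_id}"
            )
    return violations


def _fmt(v: float) -> str:
    return f"{v:.6g}"


_SIDE_ORIENTATION = {
    Side.LEFT: "left",
    Side.RIGHT: "right",
    Side.TOP: "up",
    Side.BOTTOM: "down",
}
_ORIENTATION_SIDE = {v: k for k, v in _SIDE_ORIENTATION.items()}


def _glyph_element(parent_el, glyph: Glyph, sbgn_map: SbgnMap) -> None:
    attrs = {"id": glyph.glyph_id, "class": glyph.glyph_class.value}
    if glyph.glyph_class is GlyphClass.TERMINAL and glyph.terminal_side is not None:
        attrs["orientation"] = _SIDE_ORIENTATION[glyph.terminal_side]
    el = etree.SubElement(parent_el, f"{{{SBGN_NS}}}glyph", **attrs)
    if glyph.flagged:
        el.set(f"{{{EXT_NS}}}flagged", "true")
    if glyph.source_ref:
        el.set(f"{{{EXT_NS}}}source", glyph.source_ref)
    if glyph.label:
        etree.SubElement(el, f"{{{SBGN_NS}}}label", text=glyph.label)
    if glyph.bbox is None:
        raise ValueError(f"glyph {glyph.glyph_id} has no bbox to serialize")
    b = glyph.bbox
    etree.SubElement(
        el, f"{{{SBGN_NS}}}bbox",
        x=_fmt(b.left), y=_fmt(b.top), w=_fmt(b.w), h=_fmt(b.h),
    )
    for child in sbgn_map.children(glyph.glyph_id):
        _glyph_element(el, child, sbgn_map)


def write_sbgnml(sbgn_map: SbgnMap) -> str:
    """Serialize to SBGN-ML text; re-parsing yields a structurally equal map."""
    index = sbgn_map.index()
    for a in sbgn_map.arcs:
        if a.source_id not in index or a.target_id not in index:
            raise ValueError(f"arc {a.arc_id} has unresolved endpoints")

    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap=_NSMAP)
    map_el = etree.SubElement(root, f"{{{SBGN_NS}}}map", language=sbgn_map.language)
    for g in sbgn_map.glyphs:
        if g.parent_id is None:
            _glyph_element(map_el, g, sbgn_map)
    for a in sbgn_map.arcs:
        el = etree.SubElement(
            map_el, f"{{{SBGN_NS}}}arc",
            **{"id": a.arc_id, "class": a.arc_class.value,
               "source": a.source_id, "target": a.target_id},
        )
        if a.flagged:
            el.set(f"{{{EXT_NS}}}flagged", "true")
        if a.route is not None:
            pts = a.route.points
        else:
            sb = index[a.source_id].bbox
            tb = index[a.target_id].bbox
            pts = [(sb.cx, sb.cy), (tb.cx, tb.cy)]
        etree.SubElement(el, f"{{{SBGN_NS}}}start", x=_fmt(pts[0][0]), y=_fmt(pts[0][1]))
        for (x, y) in pts[1:-1]:
            etree.SubElement(el, f"{{{SBGN_NS}}}next", x=_fmt(x), y=_fmt(y))
        etree.SubElement(el, f"{{{SBGN_NS}}}end", x=_fmt(pts[-1][0]), y=_fmt(pts[-1][1]))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def parse_sbgnml(text: str | bytes) -> SbgnMap:
    if isinstance(text, str):
        text = text.encode("utf-8")
    root = etree.fromstring(text)
    map_el = root.find(f"{{{SBGN_NS}}}map")
    if map_el is None:
        raise ValueError("no <map> element found")
    sbgn_map = SbgnMap(language=map_el.get("language", "process description"))

    def read_glyph(el, parent_id: Optional[str]) -> None:
        bbox_el = el.find(f"{{{SBGN_NS}}}bbox")
        bbox = None
        if bbox_el is not None:
            x, y = float(bbox_el.get("x")), float(bbox_el.get("y"))
            w, h = float(bbox_el.get("w")), float(bbox_el.get("h"))
            bbox = Rect(x + w / 2.0, y + h / 2.0, w, h)
        label_el = el.find(f"{{{SBGN_NS}}}label")
        orientation = el.get("orientation")
        glyph = Glyph(
            glyph_id=el.get("id"),
            glyph_class=GlyphClass(el.get("class")),
            label=label_el.get("text") if label_el is not None else "",
            bbox=bbox,
            parent_id=parent_id,
            terminal_side=_ORIENTATION_SIDE.get(orientation) if orientation else None,
            flagged=el.get(f"{{{EXT_NS}}}flagged") == "true",
            source_ref=el.get(f"{{{EXT_NS}}}source", ""),
        )
        sbgn_map.glyphs.append(glyph)
        for child in el.findall(f"{{{SBGN_NS}}}glyph"):
            read_glyph(child, glyph.glyph_id)

    for el in map_el.findall(f"{{{SBGN_NS}}}glyph"):
        read_glyph(el, None)
    for el in map_el.findall(f"{{{SBGN_NS}}}arc"):
        pts = []
        for tag in ("start", "next", "end"):
            for p in el.findall(f"{{{SBGN_NS}}}{tag}"):
                pts.append((float(p.get("x")), float(p.get("y"))))
        route = OrthoRoute(pts) if len(pts) >= 2 else None
        sbgn_map.arcs.append(
            Arc(
                arc_id=el.get("id"),
                arc_class=ArcClass(el.get("class")),
                source_id=el.get("source"),
                target_id=el.get("target"),
                route=route,
                flagged=el.get(f"{{{EXT_NS}}}flagged") == "true",
            )
        )
    return sbgn_map


# ---------------------------------------------------------------------------
# SVG rendering

_FLAG_COLOR = "#cc0000"
_STROKE = "#222222"
_FILLS = {
    GlyphClass.SIMPLE_CHEMICAL: "#f3f7e9",
    GlyphClass.MACROMOLECULE: "#e6eef8",
    GlyphClass.PROCESS: "#ffffff",
    GlyphClass.SUBMAP: "#f5f0fa",
    GlyphClass.TERMINAL: "#ece4f4",
    GlyphClass.COMPLEX: "#f8f4ec",
}


def _svg_path_d(points: list[tuple[float, float]], radius: float = 4.0) -> str:
    """Orthogonal polyline as an SVG path with slightly rounded corners."""
    if len(points) == 2:
        (x1, y1), (x2, y2) = points
        return f"M {_fmt(x1)} {_fmt(y1)} L {_fmt(x2)} {_fmt(y2)}"
    d = [f"M {_fmt(points[0][0])} {_fmt(points[0][1])}"]
    for i in range(1, len(points) - 1):
        px, py = points[i - 1]
        cx, cy = points[i]
        nx, ny = points[i + 1]
        r = min(radius, abs(cx - px) / 2 + abs(cy - py) / 2,
                abs(nx - cx) / 2 + abs(ny - cy) / 2)
        inx = cx + (px - cx) * (r / max(abs(px - cx) + abs(py - cy), 1e-9))
        iny = cy + (py - cy) * (r / max(abs(px - cx) + abs(py - cy), 1e-9))
        outx = cx + (nx - cx) * (r / max(abs(nx - cx) + abs(ny - cy), 1e-9))
        outy = cy + (ny - cy) * (r / max(abs(nx - cx) + abs(ny - cy), 1e-9))
        d.append(f"L {_fmt(inx)} {_fmt(iny)}")
        d.append(f"Q {_fmt(cx)} {_fmt(cy)} {_fmt(outx)} {_fmt(outy)}")
    d.append(f"L {_fmt(points[-1][0])} {_fmt(points[-1][1])}")
    return " ".join(d)


def _glyph_svg(g: Glyph, sbgn_map: SbgnMap) -> list[str]:
    b = g.bbox
    stroke = _FLAG_COLOR if g.flagged else _STROKE
    fill = _FILLS[g.glyph_class]
    out: list[str] = []
    common = f'fill="{fill}" stroke="{stroke}" stroke-width="1"'
    if g.glyph_class is GlyphClass.SIMPLE_CHEMICAL:
        out.append(
            f'<ellipse cx="{_fmt(b.cx)}" cy="{_fmt(b.cy)}" rx="{_fmt(b.w / 2)}" '
            f'ry="{_fmt(b.h / 2)}" {common}/>'
        )
    elif g.glyph_class is GlyphClass.MACROMOLECULE:
        out.append(
            f'<rect x="{_fmt(b.left)}" y="{_fmt(b.top)}" width="{_fmt(b.w)}" '
            f'height="{_fmt(b.h)}" rx="5" ry="5" {common}/>'
        )
    elif g.glyph_class is GlyphClass.COMPLEX:
        c = min(8.0, b.w / 3, b.h / 3)
        pts = [
            (b.left + c, b.top), (b.right - c, b.top), (b.right, b.top + c),
            (b.right, b.bottom - c), (b.right - c, b.bottom), (b.left + c, b.bottom),
            (b.left, b.bottom - c), (b.left, b.top + c),
        ]
        pstr = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        out.append(f'<polygon points="{pstr}" {common}/>')
    elif g.glyph_class is GlyphClass.TERMINAL:
        tag = min(6.0, b.w / 3, b.h / 2)
        side = g.terminal_side or Side.LEFT
        if side is Side.RIGHT:  # point aims into the submap (leftwards)
            pts = [(b.right, b.top), (b.left + tag, b.top), (b.left, b.cy),
                   (b.left + tag, b.bottom), (b.right, b.bottom)]
        elif side is Side.LEFT:
            pts = [(b.left, b.top), (b.right - tag, b.top), (b.right, b.cy),
                   (b.right - tag, b.bottom), (b.left, b.bottom)]
        elif side is Side.TOP:
            pts = [(b.left, b.top), (b.right, b.top), (b.right, b.bottom - tag),
                   (b.cx, b.bottom), (b.left, b.bottom - tag)]
        else:
            pts = [(b.left, b.bottom), (b.right, b.bottom), (b.right, b.top + tag),
                   (b.cx, b.top), (b.left, b.top + tag)]
        pstr = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        out.append(f'<polygon points="{pstr}" {common}/>')
    else:  # process, submap: plain rectangle
        out.append(
            f'<rect x="{_fmt(b.left)}" y="{_fmt(b.top)}" width="{_fmt(b.w)}" '
            f'height="{_fmt(b.h)}" {common}/>'
        )
    if g.label and g.glyph_class is not GlyphClass.PROCESS:
        # Requirement: labels are horizontal and at least partly inside the node
        out.append(
            f'<text x="{_fmt(b.cx)}" y="{_fmt(b.cy)}" text-anchor="middle" '
            f'dominant-baseline="middle" font-size="9" font-family="sans-serif">'
            f"{_escape(g.label)}</text>"
        )
    for child in sbgn_map.children(g.glyph_id):
        out.extend(_glyph_svg(child, sbgn_map))
    return out


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def render_svg(sbgn_map: SbgnMap, padding: float = 30.0) -> str:
    """Render the map as SVG.

    Glyphs are drawn first and arcs afterwards, so at a node/edge crossing the
    edge ends up on top; labels are always horizontal; flagged elements are
    stroked red; orthogonal routes get slightly rounded corners.
    """
    boxes = [g.bbox for g in sbgn_map.glyphs if g.bbox is not None]
    pts = [p for a in sbgn_map.arcs if a.route is not None for p in a.route.points]
    if boxes or pts:
        xs = [b.left for b in boxes] + [b.right for b in boxes] + [p[0] for p in pts]
        ys = [b.top for b in boxes] + [b.bottom for b in boxes] + [p[1] for p in pts]
        x0, x1 = min(xs) - padding, max(xs) + padding
        y0, y1 = min(ys) - padding, max(ys) + padding
    else:
        x0, y0, x1, y1 = 0.0, 0.0, 2 * padding, 2 * padding

    body: list[str] = []
    for g in sbgn_map.glyphs:
        if g.parent_id is None and g.bbox is not None:
            body.extend(_glyph_svg(g, sbgn_map))

    index = sbgn_map.index()
    for a in sbgn_map.arcs:
        if a.route is not None:
            pts_a = a.route.points
        else:
            sb, tb = index[a.source_id].bbox, index[a.target_id].bbox
            if sb is None or tb is None:
                continue
            pts_a = [(sb.cx, sb.cy), (tb.cx, tb.cy)]
        stroke = _FLAG_COLOR if a.flagged else _STROKE
        dash = ' stroke-dasharray="4 3"' if a.arc_class is ArcClass.EQUIVALENCE else ""
        marker = ""
        if a.arc_class is ArcClass.PRODUCTION:
            marker = f' marker-end="url(#arrow-{"red" if a.flagged else "black"})"'
        elif a.arc_class is ArcClass.CATALYSIS:
            marker = f' marker-end="url(#circle-{"red" if a.flagged else "black"})"'
        body.append(
            f'<path d="{_svg_path_d(pts_a)}" fill="none" stroke="{stroke}" '
            f'stroke-width="1.2"{dash}{marker}/>'
        )

    defs = []
    for color_name, color in (("black", _STROKE), ("red", _FLAG_COLOR)):
        defs.append(
            f'<marker id="arrow-{color_name}" markerWidth="8" markerHeight="8" '
            f'refX="7" refY="3" orient="auto"><path d="M 0 0 L 7 3 L 0 6 z" '
            f'fill="{color}"/></marker>'
        )
        defs.append(
            f'<marker id="circle-{color_name}" markerWidth="8" markerHeight="8" '
            f'refX="6" refY="3" orient="auto"><circle cx="3" cy="3" r="2.6" '
            f'fill="white" stroke="{color}"/></marker>'
        )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{_fmt(x0)} {_fmt(y0)} {_fmt(x1 - x0)} {_fmt(y1 - y0)}" '
        f'width="{_fmt(x1 - x0)}" height="{_fmt(y1 - y0)}">\n'
        f'<defs>{"".join(defs)}</defs>\n'
        f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(x1 - x0)}" '
        f'height="{_fmt(y1 - y0)}" fill="white"/>\n' + "\n".join(body) + "\n</svg>\n"
    )
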