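"""Axis-aligned rectangle primitives shared by layout, routing and rendering.

All coordinates are in the KEGG drawing frame: pixels, y growing downward,
rectangles stored by *center* plus width/height.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional


@dataclass(frozen=True)
class Rect:
    cx: float
    cy: float
    w: float
    h: float

    @property
    def left(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def right(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def top(self) -> float:
        # y is down, so "top" is the smaller y
        return self.cy - self.h / 2.0

    @property
    def bottom(self) -> float:
        return self.cy + self.h / 2.0

    def inflate(self, margin: float) -> "Rect":
        return Rect(self.cx, self.cy, self.w + 2.0 * margin, self.h + 2.0 * margin)

    def moved_to(self, cx: float, cy: float) -> "Rect":
        return Rect(cx, cy, self.w, self.h)

    def overlaps(self, other: "Rect", eps: float = 1e-9) -> bool:
        """Strict interior overlap; touching borders does not count."""
        return (
            self.left < other.right - eps
            and other.left < self.right - eps
            and self.top < other.bottom - eps
            and other.top < self.bottom - eps
        )

    def overlap_area(self, other: "Rect") -> float:
        dx = min(self.right, other.right) - max(self.left, other.left)
        dy = min(self.bottom, other.bottom) - max(self.top, other.top)
        if dx <= 0.0 or dy <= 0.0:
            return 0.0
        return dx * dy

    def contains_point(self, x: float, y: float, strict: bool = False) -> bool:
        if strict:
            return self.left < x < self.right and self.top < y < self.bottom
        return self.left <= x <= self.right and self.top <= y <= self.bottom

    def contains_rect(self, other: "Rect", tol: float = 1e-9) -> bool:
        return (
            other.left >= self.left - tol
            and other.right <= self.right + tol
            and other.top >= self.top - tol
            and other.bottom <= self.bottom + tol
        )


@dataclass
class OrthoRoute:
    """Axis-aligned polyline realizing an arc.

    Consecutive points differ in exactly one coordinate; zero-length segments
    are disallowed (collapse them with :meth:`cleaned`).
    """

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a route needs at least two points")

    def segments(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        return list(zip(self.points[:-1], self.points[1:]))

    def is_orthogonal(self, eps: float = 1e-9) -> bool:
        for (x1, y1), (x2, y2) in self.segments():
            dx, dy = abs(x1 - x2), abs(y1 - y2)
            if (dx > eps) == (dy > eps):  # diagonal or zero-length
                return False
        return True

    def length(self) -> float:
        return sum(
            abs(x2 - x1) + abs(y2 - y1) for (x1, y1), (x2, y2) in self.segments()
        )

    def bends(self, eps: float = 1e-9) -> int:
        n = 0
        segs = self.segments()
        for (p1, p2), (q1, q2) in zip(segs[:-1], segs[1:]):
            a_horiz = abs(p1[1] - p2[1]) <= eps
            b_horiz = abs(q1[1] - q2[1]) <= eps
            if a_horiz != b_horiz:
                n += 1
        return n

    def cost(self, bend_penalty: float) -> float:
        return self.length() + bend_penalty * self.bends()

    def cleaned(
        self, eps: float = 1e-9,
        keep: "Optional[set[tuple[float, float]]]" = None,
    ) -> "OrthoRoute":
        """Drop zero-length segments and merge consecutive collinear ones.

        Points in ``keep`` (e.g. routing checkpoints) survive even when they
        are collinear with their neighbors.
        """
        keep = keep or set()

        def kept(p: tuple[float, float]) -> bool:
            return any(
                abs(p[0] - q[0]) <= 1e-6 and abs(p[1] - q[1]) <= 1e-6 for q in keep
            )

        pts = [self.points[0]]
        for p in self.points[1:]:
            if abs(p[0] - pts[-1][0]) <= eps and abs(p[1] - pts[-1][1]) <= eps:
                continue
            pts.append(p)
        out = [pts[0]]
        for i in range(1, len(pts) - 1):
            a, b, c = out[-1], pts[i], pts[i + 1]
            collin_x = abs(a[0] - b[0]) <= eps and abs(b[0] - c[0]) <= eps
            collin_y = abs(a[1] - b[1]) <= eps and abs(b[1] - c[1]) <= eps
            if kept(b) or not (collin_x or collin_y):
                out.append(b)
        if len(pts) > 1:
            out.append(pts[-1])
        if len(out) < 2:
            out = [self.points[0], self.points[-1]]
        return OrthoRoute(out)


def union_rect(rects: Iterable[Rect]) -> Rect:
    rects = list(rects)
    if not rects:
        raise ValueError("union of zero rectangles")
    left = min(r.left for r in rects)
    right = max(r.right for r in rects)
    top = min(r.top for r in rects)
    bottom = max(r.bottom for r in rects)
    return Rect((left + right) / 2.0, (top + bottom) / 2.0, right - left, bottom - top)


def segment_crosses_rect(
    p: tuple[float, float], q: tuple[float, float], rect: Rect, eps: float = 1e-9
) -> bool:
    """True if the axis-aligned segment p-q passes through the strict interior of rect."""
    (x1, y1), (x2, y2) = p, q
    if abs(y1 - y2) <= eps:  # horizontal
        lo, hi = sorted((x1, x2))
        return rect.top + eps < y1 < rect.bottom - eps and lo < rect.right - eps and hi > rect.left + eps
    if abs(x1 - x2) <= eps:  # vertical
        lo, hi = sorted((y1, y2))
        return rect.left + eps < x1 < rect.right - eps and lo < rect.bottom - eps and hi > rect.top + eps
    raise ValueError("segment is not axis-aligned")
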