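"""Orthogonal object-avoiding edge routing.

Routes are computed on the orthogonal visibility structure spanned by the
"interesting" coordinates of the scene: every buffered obstacle corner plus
every connection point and checkpoint contributes a horizontal and a vertical
line; an optimal minimum-cost orthogonal path (cost = length in px +
``bend_penalty`` per direction change) always exists on the grid these lines
induce, so a Dijkstra search over (grid point, heading) states yields it
exactly.  Ports constrain the first/last heading of a route; checkpoints
split a route into consecutively solved legs, with a direction change at a
checkpoint charged like any other bend.

Process/macromolecule pairs are modeled as one expanded obstacle (the union
bounding box plus buffer) so that foreign edges cannot cross the short
catalysis arc between them.

After routing, :func:`nudge_routes` separates collinear overlapping route
segments by a uniform gap, fans terminal segments entering one node side
within the bounds of that side (recursively halving the gap when a bundle
does not fit, floor 1 px), and leaves the shared corridor of a
reaction-group bundle merged up to its checkpoint.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .geometry import OrthoRoute, Rect, segment_crosses_rect
from .sbgn_model import ArcClass, GlyphClass, Side
from .translator import TranslationResult

logger = logging.getLogger(__name__)

DEFAULT_BEND_PENALTY = 20.0
DEFAULT_BUFFER = 4.0
DEFAULT_NUDGE_GAP = 4.0
# exact global routing below this obstacle count; local cropping above
GLOBAL_ROUTING_MAX_OBSTACLES = 40

_DIR_VECTORS = {"up": (0, -1), "right": (1, 0), "down": (0, 1), "left": (-1, 0)}
_DIR_RANK = {"up": 0, "right": 1, "down": 2, "left": 3}
_OPPOSITE = {"up": "down", "down": "up", "left": "right", "right": "left"}

_SIDE_OUTWARD = {
    Side.LEFT: "left", Side.RIGHT: "right", Side.TOP: "up", Side.BOTTOM: "down",
}


@dataclass
class Obstacle:
    rect: Rect
    buffer: float = DEFAULT_BUFFER
    owners: tuple[str, ...] = ()
    expanded: bool = False

    def __post_init__(self) -> None:
        if self.buffer < 0:
            raise ValueError("obstacle buffer must be >= 0")

    @property
    def buffered(self) -> Rect:
        return self.rect.inflate(self.buffer)


@dataclass
class Port:
    owner: str
    point: tuple[float, float]
    direction: str  # outward normal: "left" | "right" | "up" | "down"


@dataclass
class ConnectorSpec:
    arc_id: str
    source_id: str
    target_id: str
    source_point: tuple[float, float]
    target_point: tuple[float, float]
    source_dir: Optional[str] = None  # forced initial heading (port)
    target_dir: Optional[str] = None  # forced final heading (into a port)
    source_is_port: bool = False
    target_is_port: bool = False
    checkpoints: list[tuple[float, float]] = field(default_factory=list)
    bundle_id: Optional[tuple] = None


class RoutingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# visibility graph (public form, used for oracle comparisons and small maps)


def build_visibility_graph(
    obstacles: list[Obstacle], anchors: list[tuple[float, float]]
) -> nx.Graph:
    """Orthogonal visibility graph over the interesting-coordinate grid.

    Vertices are grid intersections of the interesting horizontal/vertical
    lines (buffered obstacle corners and anchors) that do not lie strictly
    inside any buffered obstacle; two vertices are adjacent iff they share a
    coordinate and the segment between them crosses no buffered obstacle
    interior.  Edge weight is Euclidean length.
    """
    xs = sorted({a[0] for a in anchors} | {
        v for o in obstacles for v in (o.buffered.left, o.buffered.right)
    })
    ys = sorted({a[1] for a in anchors} | {
        v for o in obstacles for v in (o.buffered.top, o.buffered.bottom)
    })
    rects = [o.buffered for o in obstacles]

    def free(x: float, y: float) -> bool:
        return not any(r.contains_point(x, y, strict=True) for r in rects)

    graph = nx.Graph()
    for x in xs:
        for y in ys:
            if free(x, y):
                graph.add_node((x, y))
    # maximal free runs along each line; all pairs within a run see each other
    for y in ys:
        run: list[tuple[float, float]] = []
        for i, x in enumerate(xs):
            ok = (x, y) in graph
            if ok and run:
                blocked = any(
                    segment_crosses_rect(run[-1], (x, y), r) for r in rects
                )
                if blocked:
                    _connect_run(graph, run)
                    run = []
            if ok:
                run.append((x, y))
            else:
                _connect_run(graph, run)
                run = []
        _connect_run(graph, run)
    for x in xs:
        run = []
        for y in ys:
            ok = (x, y) in graph
            if ok and run:
                blocked = any(
                    segment_crosses_rect(run[-1], (x, y), r) for r in rects
                )
                if blocked:
                    _connect_run(graph, run)
                    run = []
            if ok:
                run.append((x, y))
            else:
                _connect_run(graph, run)
                run = []
        _connect_run(graph, run)
    return graph


def _connect_run(graph: nx.Graph, run: list[tuple[float, float]]) -> None:
    for a, b in itertools.combinations(run, 2):
        graph.add_edge(a, b, weight=abs(a[0] - b[0]) + abs(a[1] - b[1]))


# ---------------------------------------------------------------------------
# grid router


class _RouteGrid:
    """Interesting-coordinate grid with blocked-segment tables."""

    def __init__(
        self, obstacles: list[Obstacle], points: list[tuple[float, float]],
        region: Rect,
    ):
        rects = [o.buffered for o in obstacles]
        xs = {region.left, region.right}
        ys = {region.top, region.bottom}
        for p in points:
            xs.add(p[0])
            ys.add(p[1])
        for r in rects:
            xs.update((r.left, r.right))
            ys.update((r.top, r.bottom))
        self.xs = sorted(round(v, 9) for v in xs)
        self.ys = sorted(round(v, 9) for v in ys)
        self.xi = {v: i for i, v in enumerate(self.xs)}
        self.yi = {v: i for i, v in enumerate(self.ys)}
        self.rects = rects
        nx_, ny_ = len(self.xs), len(self.ys)
        # blocked_h[i][j]: horizontal segment xs[i]..xs[i+1] at ys[j]
        self.blocked_h = [[False] * ny_ for _ in range(max(nx_ - 1, 0))]
        self.blocked_v = [[False] * max(ny_ - 1, 0) for _ in range(nx_)]
        eps = 1e-9
        for r in rects:
            for i in range(nx_ - 1):
                if r.left - eps <= self.xs[i] and self.xs[i + 1] <= r.right + eps:
                    for j, y in enumerate(self.ys):
                        if r.top + eps < y < r.bottom - eps:
                            self.blocked_h[i][j] = True
            for j in range(ny_ - 1):
                if r.top - eps <= self.ys[j] and self.ys[j + 1] <= r.bottom + eps:
                    for i, x in enumerate(self.xs):
                        if r.left + eps < x < r.right - eps:
                            self.blocked_v[i][j] = True

    def node(self, p: tuple[float, float]) -> tuple[int, int]:
        return self.xi[round(p[0], 9)], self.yi[round(p[1], 9)]

    def neighbors(self, i: int, j: int):
        if i + 1 < len(self.xs) and not self.blocked_h[i][j]:
            yield (i + 1, j), "right", self.xs[i + 1] - self.xs[i]
        if i > 0 and not self.blocked_h[i - 1][j]:
            yield (i - 1, j), "left", self.xs[i] - self.xs[i - 1]
        if j + 1 < len(self.ys) and not self.blocked_v[i][j]:
            yield (i, j + 1), "down", self.ys[j + 1] - self.ys[j]
        if j > 0 and not self.blocked_v[i][j - 1]:
            yield (i, j - 1), "up", self.ys[j] - self.ys[j - 1]

    def dijkstra(
        self,
        start: tuple[float, float],
        goal: tuple[float, float],
        bend_penalty: float,
        start_dir: Optional[str] = None,
        force_start: bool = False,
    ) -> dict[str, tuple[float, int, list[tuple[float, float]]]]:
        """Minimum-cost orthogonal paths from start to goal, one per arrival
        heading: ``{dir: (cost, bends, points)}``.

        ``start_dir`` is the incoming heading (a different first move is one
        bend); with ``force_start`` the first move *must* follow it (port
        semantics).  Ties break on fewer bends, then on the heading order up,
        right, down, left, which makes routes deterministic.
        """
        s = self.node(start)
        t = self.node(goal)
        best: dict[tuple[int, int, Optional[str]], tuple[float, int]] = {}
        counter = itertools.count()
        pq: list = [(0.0, 0, 4, next(counter), s, start_dir, None)]
        prev: dict = {}
        out: dict[str, tuple[float, int, list[tuple[float, float]]]] = {}
        while pq:
            cost, bends, _rank, _c, node, direction, parent = heapq.heappop(pq)
            key = (node[0], node[1], direction)
            if key in best:
                continue
            best[key] = (cost, bends)
            prev[key] = parent
            if node == t and direction is not None and direction not in out:
                pts = []
                k = key
                while k is not None:
                    pts.append((self.xs[k[0]], self.ys[k[1]]))
                    k = prev[k]
                pts.reverse()
                out[direction] = (cost, bends, pts)
                if len(out) == 4:
                    return out
            for (ni, nj), d, dist in self.neighbors(*node):
                if (
                    force_start and parent is None and start_dir is not None
                    and d != start_dir
                ):
                    continue
                if direction is not None and d == _OPPOSITE[direction]:
                    continue  # a 180-degree turn would overlap itself
                bend = 0
                if direction is not None and d != direction:
                    bend = 1
                nkey = (ni, nj, d)
                ncost = cost + dist + bend_penalty * bend
                if nkey in best:
                    continue
                heapq.heappush(
                    pq,
                    (ncost, bends + bend, _DIR_RANK[d], next(counter),
                     (ni, nj), d, key),
                )
        return out


def _route_region(
    points: list[tuple[float, float]], obstacles: list[Obstacle], pad: float,
    margin: float = 60.0,
) -> tuple[Rect, list[Obstacle]]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    candidate = Rect(
        (min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0,
        max(xs) - min(xs) + 2 * pad, max(ys) - min(ys) + 2 * pad,
    )
    local = [o for o in obstacles if candidate.overlaps(o.buffered)]
    # shrink to the relevant scene plus a perimeter margin so detour lines
    # stay close to the content even when the requested pad is "everything"
    for o in local:
        xs.extend((o.buffered.left, o.buffered.right))
        ys.extend((o.buffered.top, o.buffered.bottom))
    region = Rect(
        (min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0,
        max(xs) - min(xs) + 2 * margin, max(ys) - min(ys) + 2 * margin,
    )
    return region, local


def route_connector(
    spec: ConnectorSpec,
    obstacles: list[Obstacle],
    bend_penalty: float = DEFAULT_BEND_PENALTY,
    initial_pad: float = 120.0,
) -> tuple[OrthoRoute, float]:
    """Route one connector through its checkpoints.

    Obstacles owned by the connector's endpoints must already be excluded by
    the caller.  Raises :class:`RoutingError` when free space is disconnected.
    """
    waypoints = (
        [spec.source_point] + list(spec.checkpoints) + [spec.target_point]
    )
    use_global = len(obstacles) <= GLOBAL_ROUTING_MAX_OBSTACLES
    pads = [initial_pad, initial_pad * 4, 1e9] if not use_global else [1e9]
    last_error = "no path"
    for pad in pads:
        region, local = _route_region(waypoints, obstacles, max(pad, 40.0))
        grid = _RouteGrid(local, waypoints, region)
        # dynamic program over arrival headings at each checkpoint: a heading
        # change at a checkpoint costs one bend (charged in the next leg)
        states: dict[Optional[str], tuple[float, list[tuple[float, float]]]] = {}
        ok = True
        for li, (a, b) in enumerate(zip(waypoints[:-1], waypoints[1:])):
            new_states: dict[str, tuple[float, list[tuple[float, float]]]] = {}
            if li == 0:
                starts = [(spec.source_dir, 0.0, [a])]
                force = spec.source_dir is not None
            else:
                starts = [
                    (d, c, pts) for d, (c, pts) in sorted(states.items())
                ]
                force = False
            for d_prev, base_cost, base_pts in starts:
                res = grid.dijkstra(a, b, bend_penalty, d_prev, force)
                for d_arr, (c, _bends, leg_pts) in res.items():
                    tot = base_cost + c
                    cur = new_states.get(d_arr)
                    if cur is None or tot < cur[0] - 1e-12:
                        new_states[d_arr] = (tot, base_pts + leg_pts[1:])
            if not new_states:
                ok = False
                last_error = f"leg {li}: free space disconnected"
                break
            states = dict(new_states)
        if ok:
            if spec.target_dir is not None:
                if spec.target_dir not in states:
                    last_error = "no route arrives with the port direction"
                    continue
                cost, pts = states[spec.target_dir]
            else:
                cost, pts = min(
                    states.values(), key=lambda cp: (cp[0], cp[1])
                )
            return OrthoRoute(pts).cleaned(keep=set(spec.checkpoints)), cost
    raise RoutingError(f"arc {spec.arc_id}: {last_error}")


# ---------------------------------------------------------------------------
# obstacles & ports for a translated map


def build_obstacles(
    result: TranslationResult, buffer: float = DEFAULT_BUFFER
) -> list[Obstacle]:
    """One obstacle per top-level glyph; each enzyme/process pair is merged
    into a single expanded obstacle so foreign edges avoid the catalysis arc."""
    from .geometry import union_rect

    paired: dict[str, tuple[str, str]] = {}
    for p in result.enzyme_pairs:
        paired[p.macromolecule_id] = (p.macromolecule_id, p.process_id)
        paired[p.process_id] = (p.macromolecule_id, p.process_id)
    obstacles: list[Obstacle] = []
    done: set[tuple[str, str]] = set()
    for g in result.map.glyphs:
        if g.parent_id is not None:  # children live inside their parent
            continue
        if g.glyph_id in paired:
            pair = paired[g.glyph_id]
            if pair in done:
                continue
            done.add(pair)
            rects = [result.map.glyph(x).bbox for x in pair]
            obstacles.append(
                Obstacle(union_rect(rects), buffer, owners=pair, expanded=True)
            )
        else:
            obstacles.append(Obstacle(g.bbox, buffer, owners=(g.glyph_id,)))
    return obstacles


def _process_axes(result: TranslationResult, info) -> str:
    """'x' when the substrate->product flow is horizontal, else 'y'."""
    index = result.map.index()

    def mean(ids):
        pts = [index[i].bbox for i in ids if i in index]
        if not pts:
            return None
        return (
            sum(b.cx for b in pts) / len(pts), sum(b.cy for b in pts) / len(pts),
        )

    s, p = mean(info.substrate_ids), mean(info.product_ids)
    if s is None or p is None:
        return "x"
    return "x" if abs(p[0] - s[0]) >= abs(p[1] - s[1]) else "y"


def assign_ports(result: TranslationResult) -> dict[str, dict[str, Port]]:
    """Ports per arc (keys "source"/"target" where a port applies).

    Consumption and production attach to the centers of opposite process
    sides along the flow axis; catalysis uses one of the two other sides,
    the one nearer the macromolecule; terminals force the edge out through
    the submap border they sit on.  Everything else attaches to the center
    and is trimmed to the border after routing.
    """
    index = result.map.index()
    ports: dict[str, dict[str, Port]] = {}

    def set_port(arc_id: str, end: str, port: Port) -> None:
        ports.setdefault(arc_id, {})[end] = port

    arc_by_id = {a.arc_id: a for a in result.map.arcs}
    for info in result.processes:
        pn = index[info.process_id].bbox
        axis = _process_axes(result, info)
        if axis == "x":
            sub_port = Port(info.process_id, (pn.left, pn.cy), "left")
            prod_port = Port(info.process_id, (pn.right, pn.cy), "right")
            cat_sides = {
                "up": Port(info.process_id, (pn.cx, pn.top), "up"),
                "down": Port(info.process_id, (pn.cx, pn.bottom), "down"),
            }
        else:
            sub_port = Port(info.process_id, (pn.cx, pn.top), "up")
            prod_port = Port(info.process_id, (pn.cx, pn.bottom), "down")
            cat_sides = {
                "left": Port(info.process_id, (pn.left, pn.cy), "left"),
                "right": Port(info.process_id, (pn.right, pn.cy), "right"),
            }
        # orient the pair of flow ports toward the actual neighbors
        sub_boxes = [index[i].bbox for i in info.substrate_ids if i in index]
        if sub_boxes:
            mean_sub = (
                sum(b.cx for b in sub_boxes) / len(sub_boxes),
                sum(b.cy for b in sub_boxes) / len(sub_boxes),
            )
            if axis == "x" and mean_sub[0] > pn.cx:
                sub_port, prod_port = (
                    Port(info.process_id, (pn.right, pn.cy), "right"),
                    Port(info.process_id, (pn.left, pn.cy), "left"),
                )
            elif axis == "y" and mean_sub[1] > pn.cy:
                sub_port, prod_port = (
                    Port(info.process_id, (pn.cx, pn.bottom), "down"),
                    Port(info.process_id, (pn.cx, pn.top), "up"),
                )
        for arc_id in info.consumption_arcs:
            set_port(arc_id, "target", sub_port)
        for arc_id in info.production_arcs:
            arc = arc_by_id[arc_id]
            if arc.target_id in info.substrate_ids:
                set_port(arc_id, "source", sub_port)
            else:
                set_port(arc_id, "source", prod_port)
        if info.catalysis_arc is not None and info.macromolecule_id:
            mm = index[info.macromolecule_id].bbox
            if axis == "x":
                choice = cat_sides["up" if mm.cy <= pn.cy else "down"]
            else:
                choice = cat_sides["left" if mm.cx <= pn.cx else "right"]
            set_port(info.catalysis_arc, "target", choice)

    for te_id in result.terminal_partner:
        te = index[te_id]
        side = te.terminal_side or Side.LEFT
        b = te.bbox
        point = {
            Side.LEFT: (b.left, b.cy), Side.RIGHT: (b.right, b.cy),
            Side.TOP: (b.cx, b.top), Side.BOTTOM: (b.cx, b.bottom),
        }[side]
        for a in result.map.arcs:
            if a.arc_class is ArcClass.EQUIVALENCE and te_id in (
                a.source_id, a.target_id
            ):
                end = "source" if a.source_id == te_id else "target"
                set_port(a.arc_id, end, Port(te_id, point, _SIDE_OUTWARD[side]))
    return ports


def build_connector_specs(
    result: TranslationResult, ports: dict[str, dict[str, Port]]
) -> list[ConnectorSpec]:
    index = result.map.index()
    specs = []
    for a in result.map.arcs:
        p = ports.get(a.arc_id, {})
        sp = p.get("source")
        tp = p.get("target")
        sb, tb = index[a.source_id].bbox, index[a.target_id].bbox
        specs.append(
            ConnectorSpec(
                arc_id=a.arc_id,
                source_id=a.source_id,
                target_id=a.target_id,
                source_point=sp.point if sp else (sb.cx, sb.cy),
                target_point=tp.point if tp else (tb.cx, tb.cy),
                source_dir=sp.direction if sp else None,
                target_dir=_OPPOSITE[tp.direction] if tp else None,
                source_is_port=sp is not None,
                target_is_port=tp is not None,
            )
        )
    return specs


def bundle_reaction_groups(
    result: TranslationResult,
    specs: list[ConnectorSpec],
    obstacles: list[Obstacle],
    clearance: float = 12.0,
) -> None:
    """Attach one checkpoint per (reaction group, compound side) so the
    bundled routes share the compound->checkpoint corridor and diverge there."""
    index = result.map.index()
    spec_by_arc = {s.arc_id: s for s in specs}
    for gi, group in enumerate(result.groups):
        first = index[group.process_ids[0]].bbox
        last = index[group.process_ids[-1]].bbox
        vertical = group.orientation == "vertical"
        for side, (cpd_id, pn_box, sign) in enumerate(
            ((group.compound_a_id, first, -1), (group.compound_b_id, last, +1))
        ):
            if vertical:
                cp = (pn_box.cx, (pn_box.top if sign < 0 else pn_box.bottom)
                      + sign * clearance)
                step = (0.0, sign * 4.0)
            else:
                cp = ((pn_box.left if sign < 0 else pn_box.right)
                      + sign * clearance, pn_box.cy)
                step = (sign * 4.0, 0.0)
            for _ in range(50):  # push out of any obstacle interior
                if not any(
                    o.buffered.contains_point(cp[0], cp[1], strict=True)
                    for o in obstacles
                ):
                    break
                cp = (cp[0] + step[0], cp[1] + step[1])
            bundle = ("grp", gi, "a" if sign < 0 else "b")
            for info in (result.process_by_id(p) for p in group.process_ids):
                arc_ids = (
                    info.consumption_arcs + info.production_arcs
                )
                for arc_id in arc_ids:
                    spec = spec_by_arc.get(arc_id)
                    if spec is None:
                        continue
                    other = (
                        spec.target_id if spec.source_id == info.process_id
                        else spec.source_id
                    )
                    if other != cpd_id:
                        continue
                    spec.checkpoints = [cp]
                    spec.bundle_id = bundle


def route_all(
    result: TranslationResult,
    bend_penalty: float = DEFAULT_BEND_PENALTY,
    buffer: float = DEFAULT_BUFFER,
    nudge_gap: float = DEFAULT_NUDGE_GAP,
) -> dict:
    """Route every arc of a laid-out map: ports, bundling, grid routing,
    border trimming and nudging.  Routes are written onto the arcs; a report
    of fallbacks and corridor failures is returned."""
    ports = assign_ports(result)
    obstacles = build_obstacles(result, buffer)
    specs = build_connector_specs(result, ports)
    bundle_reaction_groups(result, specs, obstacles)
    index = result.map.index()
    arc_by_id = {a.arc_id: a for a in result.map.arcs}

    report = {"fallbacks": [], "corridor_failures": []}
    routes: dict[str, OrthoRoute] = {}
    for spec in specs:
        endpoint_roots = set()
        for gid in (spec.source_id, spec.target_id):
            g = index[gid]
            while g.parent_id is not None:
                g = index[g.parent_id]
            endpoint_roots.add(g.glyph_id)
        local_obstacles = []
        for o in obstacles:
            if any(gid in endpoint_roots for gid in o.owners):
                if o.expanded:
                    # keep the pair partner solid unless it is an endpoint too
                    for gid in o.owners:
                        if gid not in endpoint_roots:
                            local_obstacles.append(
                                Obstacle(index[gid].bbox, o.buffer, (gid,))
                            )
                continue
            local_obstacles.append(o)
        try:
            route, _cost = route_connector(spec, local_obstacles, bend_penalty)
        except RoutingError as exc:
            logger.warning("%s; falling back to a straight connector", exc)
            report["fallbacks"].append(spec.arc_id)
            arc_by_id[spec.arc_id].flagged = True
            route = OrthoRoute([spec.source_point, spec.target_point])
        routes[spec.arc_id] = route

    for spec in specs:
        route = routes[spec.arc_id]
        if route.is_orthogonal():
            keep = set(spec.checkpoints)
            if not spec.source_is_port:
                route = trim_to_border(
                    route, index[spec.source_id].bbox, at_start=True, keep=keep
                )
            if not spec.target_is_port:
                route = trim_to_border(
                    route, index[spec.target_id].bbox, at_start=False, keep=keep
                )
        routes[spec.arc_id] = route

    failures = nudge_routes(routes, specs, index, nudge_gap, obstacles=obstacles)
    report["corridor_failures"] = failures
    report["bundles"] = {
        s.arc_id: s.bundle_id for s in specs if s.bundle_id is not None
    }
    report["checkpoints"] = {
        s.arc_id: list(s.checkpoints) for s in specs if s.checkpoints
    }

    for spec in specs:
        arc_by_id[spec.arc_id].route = routes[spec.arc_id]
    return report


# ---------------------------------------------------------------------------
# trimming & nudging


def trim_to_border(
    route: OrthoRoute, rect: Rect, at_start: bool,
    keep: Optional[set[tuple[float, float]]] = None,
) -> OrthoRoute:
    """Replace a center attachment by the border intersection of the final
    segment, preserving its direction and orthogonality."""
    pts = list(route.points)
    if at_start:
        pts.reverse()
    # drop trailing points inside the rect, then clip the crossing segment
    while len(pts) >= 2 and rect.contains_point(*pts[-2]):
        pts.pop()
    if len(pts) < 2:
        return route
    (ox, oy), (ix, iy) = pts[-2], pts[-1]
    if abs(oy - iy) <= 1e-9:  # horizontal entry
        bx = rect.left if ox < rect.cx else rect.right
        pts[-1] = (bx, iy)
    else:
        by = rect.top if oy < rect.cy else rect.bottom
        pts[-1] = (ix, by)
    if at_start:
        pts.reverse()
    return OrthoRoute(pts).cleaned(keep=keep)


@dataclass
class _Seg:
    arc_id: str
    seg_index: int
    horizontal: bool
    cross: float  # y for horizontal segments, x for vertical
    lo: float
    hi: float
    is_first: bool
    is_last: bool
    bundle_corridor: Optional[tuple] = None  # bundle id when on shared prefix
    attach_glyph: Optional[str] = None  # glyph whose side the segment enters
    attach_side_len: float = 0.0
    # allowed (lo, hi) cross-shift keeping attachments on their node side
    attach_room: Optional[tuple[float, float]] = None
    exempt_gids: frozenset = frozenset()  # endpoint owners: obstacles to ignore


def _route_segments(
    arc_id: str, route: OrthoRoute, spec: ConnectorSpec, index
) -> list[_Seg]:
    out = []
    pts = route.points
    cp = spec.checkpoints[0] if spec.checkpoints else None
    cp_index = None
    if cp is not None:
        for i, p in enumerate(pts):
            if abs(p[0] - cp[0]) <= 1e-6 and abs(p[1] - cp[1]) <= 1e-6:
                cp_index = i
                break
    # which route end touches the bundle's compound: the non-process end
    for si, (a, b) in enumerate(zip(pts[:-1], pts[1:])):
        horizontal = abs(a[1] - b[1]) <= 1e-9
        cross = a[1] if horizontal else a[0]
        lo, hi = sorted((a[0], b[0]) if horizontal else (a[1], b[1]))
        seg = _Seg(
            arc_id, si, horizontal, round(cross, 6), lo, hi,
            is_first=(si == 0), is_last=(si == len(pts) - 2),
        )
        if cp_index is not None and spec.bundle_id is not None:
            # corridor = portion between the compound endpoint and checkpoint
            source_side = spec.source_is_port is False  # compound/center end
            if source_side and si < cp_index:
                seg.bundle_corridor = spec.bundle_id
            if not source_side and si >= cp_index:
                seg.bundle_corridor = spec.bundle_id
        roots = set()
        for gid in (spec.source_id, spec.target_id):
            g = index[gid]
            while g.parent_id is not None:
                g = index[g.parent_id]
            roots.add(g.glyph_id)
            roots.add(gid)
        seg.exempt_gids = frozenset(roots)
        ends = []
        if seg.is_first:
            ends.append((pts[0], spec.source_id))
        if seg.is_last:
            ends.append((pts[-1], spec.target_id))
        for p, gid in ends:
            rect = index[gid].bbox
            on_vertical_side = (
                abs(p[0] - rect.left) <= 1e-6 or abs(p[0] - rect.right) <= 1e-6
            )
            on_horizontal_side = (
                abs(p[1] - rect.top) <= 1e-6 or abs(p[1] - rect.bottom) <= 1e-6
            )
            room = None
            if horizontal and on_vertical_side:
                # final segment slides along the vertical side: shift is in y
                room = (rect.top - p[1], rect.bottom - p[1])
                side_len = rect.h
            elif not horizontal and on_horizontal_side:
                room = (rect.left - p[0], rect.right - p[0])
                side_len = rect.w
            if room is not None:
                seg.attach_glyph = gid
                seg.attach_side_len = (
                    min(seg.attach_side_len, side_len)
                    if seg.attach_side_len else side_len
                )
                if seg.attach_room is None:
                    seg.attach_room = room
                else:
                    seg.attach_room = (
                        max(seg.attach_room[0], room[0]),
                        min(seg.attach_room[1], room[1]),
                    )
        out.append(seg)
    return out


def nudge_routes(
    routes: dict[str, OrthoRoute],
    specs: list[ConnectorSpec],
    index,
    initial_gap: float = DEFAULT_NUDGE_GAP,
    obstacles: Optional[list[Obstacle]] = None,
) -> list[str]:
    """Separate collinear overlapping segments of distinct routes.

    Shared corridors of one bundle stay merged (pinned at offset 0); the
    other overlapping units get distinct offsets chosen nearest to zero that
    (a) keep attachment points strictly within the node side they enter,
    (b) avoid buffered obstacle interiors and (c) do not land on another
    already-placed route segment.  When a corridor cannot fit at the current
    gap the whole cluster is retried at recursively halved nudging distances
    (floor 1 px); a corridor failing even then is reported (and fanned
    ignoring obstacles so routes at least remain distinct).
    """
    obstacles = obstacles or []
    spec_by_arc = {s.arc_id: s for s in specs}
    failures: list[str] = []
    # moving a segment stretches its perpendicular neighbors, which can
    # create fresh overlap elsewhere; iterate to a fixpoint (bounded)
    for _ in range(4):
        changed = _nudge_pass(routes, spec_by_arc, index, initial_gap,
                              obstacles, failures)
        if not changed:
            break
    return failures


def _nudge_pass(
    routes: dict[str, OrthoRoute],
    spec_by_arc: dict[str, ConnectorSpec],
    index,
    initial_gap: float,
    obstacles: list[Obstacle],
    failures: list[str],
) -> bool:
    segs: list[_Seg] = []
    for arc_id, route in routes.items():
        if not route.is_orthogonal():
            continue
        segs.extend(_route_segments(arc_id, route, spec_by_arc[arc_id], index))

    # all segments at their current coordinates; updated as clusters resolve
    placed: dict[tuple[str, int], tuple[bool, float, float, float, Optional[tuple]]] = {
        (s.arc_id, s.seg_index): (s.horizontal, s.cross, s.lo, s.hi, s.bundle_corridor)
        for s in segs
    }
    offsets: dict[tuple[str, int], float] = {}

    def seg_candidate_ok(s: _Seg, off: float, cluster_keys: set) -> bool:
        if s.attach_room is not None:
            if not (s.attach_room[0] + 1e-9 < off < s.attach_room[1] - 1e-9):
                return False
        new_cross = s.cross + off
        if s.horizontal:
            a, b = (s.lo, new_cross), (s.hi, new_cross)
        else:
            a, b = (new_cross, s.lo), (new_cross, s.hi)
        for o in obstacles:
            if s.exempt_gids.intersection(o.owners):
                continue
            if segment_crosses_rect(a, b, o.buffered):
                return False
        for (pid, pseg), (ph, pcross, plo, phi, pbundle) in placed.items():
            if pid == s.arc_id or (pid, pseg) in cluster_keys:
                continue
            if ph != s.horizontal or abs(pcross - new_cross) > 0.5:
                continue
            if pbundle is not None and pbundle == s.bundle_corridor:
                continue
            if min(phi, s.hi) - max(plo, s.lo) > 1e-6:
                return False
        return True

    def try_assign(
        ordered: list, gap: float, cluster_keys: set, strict: bool
    ) -> Optional[dict]:
        taken: list[float] = []
        assign: dict = {}
        # ideal offsets: pinned bundle corridors stay at 0, the rest fan
        # symmetrically around the corridor (or around the pinned corridor)
        free_count = sum(1 for key, _ in ordered if key[0] != "bundle")
        if free_count < len(ordered):
            fan = iter(_fan_offsets_excluding_zero(free_count, gap))
            ideals = [
                0.0 if key[0] == "bundle" else next(fan) for key, _ in ordered
            ]
        else:
            ideals = [
                (u - (free_count - 1) / 2.0) * gap for u in range(len(ordered))
            ]
        for (key, members_u), ideal in zip(ordered, ideals):
            if key[0] == "bundle":
                assign[key] = 0.0
                taken.append(0.0)
                continue
            chosen = None
            for step in range(0, 2 * max(len(ordered), 4) + 1):
                off = ideal + ((step + 1) // 2) * gap * (1 if step % 2 else -1)
                if step == 0:
                    off = ideal
                if any(abs(off - t) < 1e-9 for t in taken):
                    continue
                if strict and not all(
                    seg_candidate_ok(s, off, cluster_keys) for s in members_u
                ):
                    continue
                if not strict:
                    # still honor attachment-side bounds when possible
                    if any(
                        s.attach_room is not None
                        and not (s.attach_room[0] + 1e-9 < off < s.attach_room[1] - 1e-9)
                        for s in members_u
                    ):
                        continue
                chosen = off
                break
            if chosen is None:
                return None
            assign[key] = chosen
            taken.append(chosen)
        return assign

    for horizontal in (True, False):
        pool = [s for s in segs if s.horizontal == horizontal]
        by_cross: dict[float, list[_Seg]] = {}
        for s in pool:
            by_cross.setdefault(s.cross, []).append(s)
        for cross, members in sorted(by_cross.items()):
            for cluster in _overlap_clusters(members):
                if len({s.arc_id for s in cluster}) < 2:
                    continue
                # units: one per bundle corridor, one per remaining segment
                units: dict = {}
                for s in cluster:
                    key = (
                        ("bundle", s.bundle_corridor)
                        if s.bundle_corridor is not None
                        else ("seg", s.arc_id, s.seg_index)
                    )
                    units.setdefault(key, []).append(s)
                if len(units) < 2:
                    continue  # a single bundle sharing its corridor: allowed
                ordered = sorted(
                    units.items(),
                    key=lambda kv: (_far_coordinate(kv[1], routes, horizontal),
                                    str(kv[0])),
                )
                cluster_keys = {(s.arc_id, s.seg_index) for s in cluster}
                gap = initial_gap
                assign = None
                while True:
                    assign = try_assign(ordered, gap, cluster_keys, strict=True)
                    if assign is not None or gap <= 1.0:
                        break
                    gap = max(gap / 2.0, 1.0)
                if assign is None:
                    failures.append(
                        f"{'h' if horizontal else 'v'}-corridor at {cross}: "
                        f"{len(units)} routes do not fit even at a 1px gap"
                    )
                    assign = try_assign(ordered, 1.0, cluster_keys, strict=False)
                if assign is None:  # pathological; leave the cluster in place
                    continue
                for key, members_u in ordered:
                    off = assign[key]
                    for s in members_u:
                        offsets[(s.arc_id, s.seg_index)] = off
                        placed[(s.arc_id, s.seg_index)] = (
                            s.horizontal, s.cross + off, s.lo, s.hi,
                            s.bundle_corridor,
                        )

    changed = False
    for arc_id, route in routes.items():
        route_segs = sorted(
            (s for s in segs if s.arc_id == arc_id), key=lambda s: s.seg_index
        )
        if not any(offsets.get((arc_id, s.seg_index)) for s in route_segs):
            continue
        changed = True
        routes[arc_id] = _apply_offsets(
            route, route_segs,
            {s.seg_index: offsets.get((arc_id, s.seg_index), 0.0)
             for s in route_segs},
            keep=set(spec_by_arc[arc_id].checkpoints),
        )
    return changed


def _apply_offsets(
    route: OrthoRoute, route_segs: list[_Seg], offsets: dict[int, float],
    keep: set[tuple[float, float]],
) -> OrthoRoute:
    """Shift segments perpendicular by their offsets and reconnect junctions.

    A junction of two perpendicular segments becomes their crossing point; a
    junction of two collinear segments with different offsets gets a small
    perpendicular jog so the route stays orthogonal (this is what keeps a
    bundle's pinned corridor connected to its nudged continuation)."""
    pts = route.points
    # cross coordinate per segment after offsetting
    cross = {
        s.seg_index: s.cross + offsets.get(s.seg_index, 0.0) for s in route_segs
    }
    horiz = {s.seg_index: s.horizontal for s in route_segs}
    n = len(pts) - 1  # number of segments
    out: list[tuple[float, float]] = []
    first = pts[0]
    out.append(
        (first[0], cross[0]) if horiz[0] else (cross[0], first[1])
    )
    for j in range(1, n):
        p = pts[j]
        if horiz[j - 1] != horiz[j]:
            # the vertical segment supplies x, the horizontal one y
            x = cross[j - 1] if not horiz[j - 1] else cross[j]
            y = cross[j - 1] if horiz[j - 1] else cross[j]
            out.append((x, y))
        else:
            if abs(cross[j - 1] - cross[j]) <= 1e-9:
                out.append(
                    (p[0], cross[j]) if horiz[j] else (cross[j], p[1])
                )
            elif horiz[j]:  # collinear horizontal with a vertical jog at x=p[0]
                out.append((p[0], cross[j - 1]))
                out.append((p[0], cross[j]))
            else:  # collinear vertical with a horizontal jog at y=p[1]
                out.append((cross[j - 1], p[1]))
                out.append((cross[j], p[1]))
    last = pts[-1]
    out.append(
        (last[0], cross[n - 1]) if horiz[n - 1] else (cross[n - 1], last[1])
    )
    return OrthoRoute(out).cleaned(keep=keep)


def _overlap_clusters(members: list[_Seg]) -> list[list[_Seg]]:
    """Union of segments on one line whose intervals overlap with positive length."""
    members = sorted(members, key=lambda s: (s.lo, s.hi, s.arc_id, s.seg_index))
    clusters: list[list[_Seg]] = []
    cur: list[_Seg] = []
    cur_hi = -float("inf")
    for s in members:
        if cur and s.lo < cur_hi - 1e-9:
            cur.append(s)
            cur_hi = max(cur_hi, s.hi)
        else:
            if len(cur) > 1:
                clusters.append(cur)
            cur = [s]
            cur_hi = s.hi
    if len(cur) > 1:
        clusters.append(cur)
    return clusters


def _far_coordinate(
    unit_segs: list[_Seg], routes: dict[str, OrthoRoute], horizontal: bool
) -> float:
    """Order key for fanning: the cross-axis coordinate of the route's far end."""
    s = unit_segs[0]
    pts = routes[s.arc_id].points
    far = pts[-1] if s.seg_index < len(pts) / 2 else pts[0]
    return far[1] if horizontal else far[0]


def _fan_offsets_excluding_zero(k: int, gap: float) -> list[float]:
    """Deterministic alternation g, -g, 2g, -2g, ... around a pinned zero."""
    out = []
    i = 1
    while len(out) < k:
        out.append(((i + 1) // 2) * gap * (1 if i % 2 else -1))
        i += 1
    return out
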