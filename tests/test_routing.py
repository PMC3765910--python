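import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import translated
from kgml2sbgn import checks
from kgml2sbgn.geometry import OrthoRoute, Rect, segment_crosses_rect
from kgml2sbgn.routing import (
    ConnectorSpec,
    Obstacle,
    Port,
    RoutingError,
    assign_ports,
    build_connector_specs,
    build_obstacles,
    build_visibility_graph,
    bundle_reaction_groups,
    nudge_routes,
    route_all,
    route_connector,
    trim_to_border,
)
from kgml2sbgn.sbgn_model import ArcClass
from oracles import brute_force_route_cost


def spec(arc_id, src, tgt, **kw):
    return ConnectorSpec(
        arc_id, "s", "t", source_point=src, target_point=tgt, **kw
    )


def random_obstacles(rng, n):
    out = []
    while len(out) < n:
        r = Rect(
            float(rng.uniform(40, 360)), float(rng.uniform(40, 260)),
            float(rng.uniform(15, 50)), float(rng.uniform(10, 30)),
        )
        out.append(Obstacle(r, buffer=4.0))
    return out


def free_point(rng, obstacles, span=((0, 400), (0, 300))):
    while True:
        p = (float(rng.uniform(*span[0])), float(rng.uniform(*span[1])))
        if not any(
            o.buffered.contains_point(p[0], p[1], strict=True) for o in obstacles
        ):
            return p


class TestVisibilityGraph:
    def test_two_anchors_no_obstacles_one_corner(self):
        g = build_visibility_graph([], [(0.0, 0.0), (50.0, 30.0)])
        path = nx.shortest_path(g, (0.0, 0.0), (50.0, 30.0))
        assert len(path) <= 3  # at most one intermediate corner point

    def test_blocking_obstacle_kills_direct_edge(self):
        obs = [Obstacle(Rect(50, 0, 20, 20), buffer=0.0)]
        g = build_visibility_graph(obs, [(0.0, 0.0), (100.0, 0.0)])
        assert not g.has_edge((0.0, 0.0), (100.0, 0.0))

    @pytest.mark.parametrize("seed", range(6))
    def test_adjacency_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        obstacles = random_obstacles(rng, 5)
        anchors = [free_point(rng, obstacles) for _ in range(2)]
        g = build_visibility_graph(obstacles, anchors)
        rects = [o.buffered for o in obstacles]
        for a, b in itertools.combinations(g.nodes, 2):
            if a[0] != b[0] and a[1] != b[1]:
                assert not g.has_edge(a, b)
                continue
            blocked = any(segment_crosses_rect(a, b, r) for r in rects)
            assert g.has_edge(a, b) == (not blocked), (a, b)


class TestRouteConnector:
    def test_clear_corridor_straight_two_points(self):
        route, cost = route_connector(spec("a", (0.0, 50.0), (100.0, 50.0)), [])
        assert route.points == [(0.0, 50.0), (100.0, 50.0)]
        assert route.bends() == 0 and cost == pytest.approx(100.0)

    def test_blocking_obstacle_two_bend_detour_matches_oracle(self):
        obs = [Obstacle(Rect(50.0, 50.0, 20.0, 20.0), buffer=4.0)]
        route, cost = route_connector(spec("a", (0.0, 50.0), (100.0, 50.0)), obs)
        expected = brute_force_route_cost(
            [o.buffered for o in obs], (0.0, 50.0), (100.0, 50.0), 20.0
        )
        assert cost == pytest.approx(expected)
        assert route.bends() == 2
        assert not any(
            segment_crosses_rect(p, q, obs[0].buffered) for p, q in route.segments()
        )

    def test_checkpoint_visited_and_cost_piecewise_optimal(self):
        cp = (50.0, 80.0)
        start, goal = (0.0, 50.0), (100.0, 50.0)
        s = spec("a", start, goal, checkpoints=[cp])
        route, cost = route_connector(s, [])
        assert checks.visits_checkpoints(route, [cp])
        # oracle: concatenation of the two optimal sub-routes over every
        # possible heading at the checkpoint; a heading change there costs
        # one bend (charged at the start of the second leg)
        combos = []
        for d in ("up", "down", "left", "right"):
            l1 = brute_force_route_cost([], start, cp, 20.0, goal_dir=d)
            l2 = brute_force_route_cost([], cp, goal, 20.0, start_dir=d)
            if l1 is not None and l2 is not None:
                combos.append(l1 + l2)
        assert cost == pytest.approx(min(combos))

    @pytest.mark.parametrize("seed", range(6))
    def test_checkpoint_cost_matches_piecewise_oracle_with_obstacles(self, seed):
        rng = np.random.default_rng(300 + seed)
        obstacles = random_obstacles(rng, 4)
        rects = [o.buffered for o in obstacles]
        a = free_point(rng, obstacles)
        b = free_point(rng, obstacles)
        cp = free_point(rng, obstacles)
        legs = {}
        for d in ("up", "down", "left", "right"):
            l1 = brute_force_route_cost(rects, a, cp, 20.0, goal_dir=d)
            l2 = brute_force_route_cost(rects, cp, b, 20.0, start_dir=d)
            if l1 is not None and l2 is not None:
                legs[d] = l1 + l2
        if not legs:
            return
        route, cost = route_connector(
            spec("x", a, b, checkpoints=[cp]), obstacles
        )
        assert cost == pytest.approx(min(legs.values()))
        assert checks.visits_checkpoints(route, [cp])

    def test_port_forces_first_segment_direction(self):
        s = spec(
            "a", (0.0, 50.0), (100.0, 50.0), source_dir="up", source_is_port=True
        )
        route, cost = route_connector(s, [])
        (x0, y0), (x1, y1) = route.points[0], route.points[1]
        assert x0 == x1 and y1 < y0  # leaves upward despite the detour cost

    def test_disconnected_free_space_raises(self):
        # a solid ring of obstacles around the source
        ring = [
            Obstacle(Rect(0.0, -30.0, 80.0, 10.0), buffer=2.0),
            Obstacle(Rect(0.0, 30.0, 80.0, 10.0), buffer=2.0),
            Obstacle(Rect(-30.0, 0.0, 10.0, 80.0), buffer=2.0),
            Obstacle(Rect(30.0, 0.0, 10.0, 80.0), buffer=2.0),
        ]
        with pytest.raises(RoutingError):
            route_connector(spec("a", (0.0, 0.0), (200.0, 0.0)), ring)

    @pytest.mark.parametrize("seed", range(10))
    def test_cost_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        obstacles = random_obstacles(rng, int(rng.integers(1, 8)))
        a = free_point(rng, obstacles)
        b = free_point(rng, obstacles)
        expected = brute_force_route_cost(
            [o.buffered for o in obstacles], a, b, 20.0
        )
        if expected is None:
            return
        route, cost = route_connector(spec("x", a, b), obstacles)
        assert cost == pytest.approx(expected)
        assert route.is_orthogonal()


class TestAssignPorts:
    def test_horizontal_reaction_ports(self, simple_irreversible_kgml):
        from kgml2sbgn.layout import layout_map

        res = translated(simple_irreversible_kgml)
        layout_map(res)
        ports = assign_ports(res)
        pn = res.map.glyph("pn3_r1").bbox
        cons = next(
            ports[a.arc_id]["target"] for a in res.map.arcs
            if a.arc_class is ArcClass.CONSUMPTION
        )
        prod = next(
            ports[a.arc_id]["source"] for a in res.map.arcs
            if a.arc_class is ArcClass.PRODUCTION
        )
        cat = next(
            ports[a.arc_id]["target"] for a in res.map.arcs
            if a.arc_class is ArcClass.CATALYSIS
        )
        assert cons.point == (pn.left, pn.cy) and cons.direction == "left"
        assert prod.point == (pn.right, pn.cy) and prod.direction == "right"
        assert cat.point == (pn.cx, pn.top) and cat.direction == "up"

    def test_vertical_reaction_ports(self, multi_reaction_kgml):
        from kgml2sbgn.layout import layout_map

        res = translated(multi_reaction_kgml)
        layout_map(res)
        ports = assign_ports(res)
        for info in res.processes:
            pn = res.map.glyph(info.process_id).bbox
            tgt = ports[info.consumption_arcs[0]]["target"]
            assert tgt.point == (pn.cx, pn.top)  # flow is downward
            cat = ports[info.catalysis_arc]["target"]
            assert cat.direction in ("left", "right")

    def test_terminal_port_points_outward(self, maplink_kgml):
        from kgml2sbgn.layout import layout_map

        res = translated(maplink_kgml)
        layout_map(res)
        ports = assign_ports(res)
        eq = next(a for a in res.map.arcs if a.arc_class is ArcClass.EQUIVALENCE)
        p = ports[eq.arc_id]["source"]
        te = res.map.glyph("sm2_t1").bbox
        assert p.direction == "left"
        assert p.point == (te.left, te.cy)


class TestBundling:
    def routed(self, kgml):
        from kgml2sbgn.layout import layout_map

        res = translated(kgml)
        layout_map(res)
        report = route_all(res)
        return res, report

    def test_group_routes_share_corridor_then_diverge(self, multi_reaction_kgml):
        res, report = self.routed(multi_reaction_kgml)
        cps = report["checkpoints"]
        group = res.groups[0]
        upper = group.compound_a_id
        shared = []
        for a in res.map.arcs:
            if a.arc_class is ArcClass.CONSUMPTION and a.source_id == upper:
                assert a.arc_id in cps
                assert checks.visits_checkpoints(a.route, cps[a.arc_id])
                shared.append(a.route.points)
        assert len(shared) == 2
        # identical prefix from the compound down to the divergence point
        assert shared[0][0] == shared[1][0]
        assert shared[0][1] == shared[1][1]

    def test_no_groups_no_checkpoints(self, simple_irreversible_kgml):
        _, report = self.routed(simple_irreversible_kgml)
        assert report["checkpoints"] == {}

    def test_group_of_three_divergence(self):
        from conftest import entry, kgml_doc, reaction

        body = (
            entry("1", "compound", 100, 50)
            + entry("2", "compound", 100, 290)
            + "".join(
                entry(str(10 + i), "gene", 135, 120 + 50 * i, w=46, h=17,
                      reaction=f"rn:r{i}")
                + reaction(f"r{i}", ["1"], ["2"])
                for i in range(3)
            )
        )
        res, report = self.routed(kgml_doc(body))
        assert len(res.groups) == 1 and len(res.groups[0].process_ids) == 3
        for arc_id, cps in report["checkpoints"].items():
            arc = next(a for a in res.map.arcs if a.arc_id == arc_id)
            assert checks.visits_checkpoints(arc.route, cps)


class FakeGlyph:
    def __init__(self, glyph_id, bbox):
        self.glyph_id = glyph_id
        self.bbox = bbox
        self.parent_id = None


def fake_index(**rects):
    return {k: FakeGlyph(k, r) for k, r in rects.items()}


class TestNudging:
    def test_single_route_unchanged(self):
        r = OrthoRoute([(0.0, 0.0), (100.0, 0.0)])
        routes = {"a": r}
        specs = [spec("a", (0.0, 0.0), (100.0, 0.0))]
        index = fake_index(s=Rect(-10, 0, 10, 10), t=Rect(110, 0, 10, 10))
        nudge_routes(routes, specs, index, 4.0)
        assert routes["a"].points == [(0.0, 0.0), (100.0, 0.0)]

    def test_shared_corridor_offsets_apart(self):
        # two mid-route segments sharing a 100 px corridor at y=50
        routes = {
            "a": OrthoRoute([(0.0, 20.0), (0.0, 50.0), (100.0, 50.0),
                             (100.0, 20.0)]),
            "b": OrthoRoute([(0.0, 80.0), (0.0, 50.0), (100.0, 50.0),
                             (100.0, 80.0)]),
        }
        specs = [
            spec("a", (0.0, 20.0), (100.0, 20.0)),
            spec("b", (0.0, 80.0), (100.0, 80.0)),
        ]
        index = fake_index(s=Rect(-20, 50, 10, 120), t=Rect(120, 50, 10, 120))
        nudge_routes(routes, specs, index, 4.0)
        crossings_a = {p[1] for p in routes["a"].points[1:3]}
        crossings_b = {p[1] for p in routes["b"].points[1:3]}
        assert crossings_a == {48.0} and crossings_b == {52.0}
        assert checks.collinear_overlap_length(routes) == pytest.approx(0.0)

    def test_five_arcs_into_narrow_side_gap_reduced(self):
        # five parallel final segments entering the top side of a 20px node
        target = Rect(50.0, 100.0, 20.0, 14.0)
        index = fake_index(t=target, s=Rect(50.0, 0.0, 200.0, 10.0))
        routes = {}
        specs = []
        for i in range(5):
            aid = f"a{i}"
            routes[aid] = OrthoRoute(
                [(-40.0 + 20 * i, 20.0), (50.0, 20.0), (50.0, target.top)]
            )
            specs.append(
                ConnectorSpec(aid, "s", "t", (-40.0 + 20 * i, 20.0),
                              (50.0, target.top))
            )
        failures = nudge_routes(routes, specs, index, initial_gap=10.0)
        assert failures == []
        ends = sorted(r.points[-1][0] for r in routes.values())
        # all five attachment points distinct, strictly inside the 20px side
        assert len(set(ends)) == 5
        assert all(target.left < x < target.right for x in ends)
        # recursive halving brought the 10px request down to a fitting gap
        gaps = {round(b - a, 6) for a, b in zip(ends[:-1], ends[1:])}
        assert max(gaps) <= 4.0

    def test_pipeline_maps_have_no_residual_collinear_overlap(self):
        from kgml2sbgn import convert_kgml, generate_kgml, SynthSpec

        for seed in (1, 3, 5):
            text, _ = generate_kgml(SynthSpec(seed=seed))
            out = convert_kgml(text)
            routes = {a.arc_id: a.route for a in out.map.arcs if a.route}
            assert checks.collinear_overlap_length(
                routes, out.routing_report["bundles"]
            ) == pytest.approx(0.0)


class TestTrimToBorder:
    def test_horizontal_entry_moved_to_vertical_border(self):
        r = OrthoRoute([(0.0, 0.0), (100.0, 0.0)])
        trimmed = trim_to_border(r, Rect(100.0, 0.0, 40.0, 20.0), at_start=False)
        assert trimmed.points[-1] == (80.0, 0.0)

    def test_port_attached_endpoint_unchanged(self):
        # trimming is only applied to center attachments; a port point on the
        # border is already final
        r = OrthoRoute([(0.0, 0.0), (80.0, 0.0)])
        trimmed = trim_to_border(r, Rect(100.0, 0.0, 40.0, 20.0), at_start=False)
        assert trimmed.points[-1] == (80.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trimmed_routes_stay_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        obstacles = random_obstacles(rng, 3)
        a = free_point(rng, obstacles)
        b = free_point(rng, obstacles)
        try:
            route, _ = route_connector(spec("x", a, b), obstacles)
        except RoutingError:
            return
        glyph = Rect(a[0], a[1], 18.0, 12.0)
        trimmed = trim_to_border(route, glyph, at_start=True)
        assert trimmed.is_orthogonal()
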