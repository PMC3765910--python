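"""Constraint-based node placement.

The placement problem per axis is a convex quadratic program: place every
variable (node center or alignment guide) as close as possible to its desired
position, subject to separation constraints ``u + g <= v`` and ``u + g = v``.
:func:`project_positions` solves it exactly with a block-merging active-set
method: equalities are eliminated up front by merging variables into rigid
blocks with fixed internal offsets; a violated inequality then merges the two
blocks it spans (making it active), and an active inequality whose Lagrange
multiplier goes negative is retracted, splitting its block.  At termination
the KKT conditions hold, so the result is the exact QP minimizer.

Non-overlap is handled at a lower priority by :func:`resolve_overlaps`: each
overlapping sibling pair can be separated "above", "below", "left" or
"right"; the four alternatives are ranked by the total node movement an exact
trial projection would cause and tried in rank order, backtracking (resetting
positions) whenever an alternative makes the system infeasible.  Containment
hierarchies relax non-overlap: children are kept inside their parents by
margin separations and only siblings are separated from each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .constraints import ConstraintSet, SeparationConstraint
from .geometry import Rect

logger = logging.getLogger(__name__)

DEFAULT_NODE_MARGIN = 10.0
_TOL = 1e-9
GUIDE_EPS_WEIGHT = 1e-7  # only used if a guide ends up in a memberless block


class InfeasibleError(ValueError):
    """Raised when the separation system admits no solution; the message
    names a violated cycle when one could be extracted."""


# ---------------------------------------------------------------------------
# exact separation-QP solver


class _UnionFind:
    """Union-find with positional offsets: pos(i) = pos(root) + off(i)."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.off = [0.0] * n

    def find(self, i: int) -> tuple[int, float]:
        if self.parent[i] == i:
            return i, 0.0
        root, off = self.find(self.parent[i])
        self.parent[i] = root
        self.off[i] += off
        return root, self.off[i]

    def union(self, u: int, v: int, gap: float) -> bool:
        """Impose pos(v) = pos(u) + gap. Returns False on contradiction."""
        ru, ou = self.find(u)
        rv, ov = self.find(v)
        if ru == rv:
            return abs(ou + gap - ov) <= 1e-9
        # attach rv under ru: pos under rv-frame shifts by (ou + gap - ov)
        self.parent[rv] = ru
        self.off[rv] = ou + gap - ov
        return True


def _find_positive_cycle(
    n: int, edges: list[tuple[int, int, float]], names: list[str]
) -> Optional[list[str]]:
    """Bellman-Ford style search for a cycle with positive total gap
    (equivalently a negative cycle on negated weights)."""
    dist = [0.0] * n
    pred: list[Optional[tuple[int, int]]] = [None] * n
    x = None
    for _ in range(n):
        x = None
        for k, (u, v, g) in enumerate(edges):
            if dist[u] + g > dist[v] + 1e-12:
                dist[v] = dist[u] + g
                pred[v] = (u, k)
                x = v
        if x is None:
            return None
    # walk back n steps to land inside the cycle
    for _ in range(n):
        x = pred[x][0]
    cycle = [x]
    cur = pred[x][0]
    while cur != x:
        cycle.append(cur)
        cur = pred[cur][0]
    cycle.reverse()
    return [names[i] for i in cycle]


def solve_separation_qp(
    desired: np.ndarray,
    weights: np.ndarray,
    equalities: list[tuple[int, int, float]],
    inequalities: list[tuple[int, int, float]],
    names: Optional[list[str]] = None,
) -> np.ndarray:
    """Minimize sum_i w_i (x_i - d_i)^2 subject to x_u + g <= x_v (and = for
    equalities).  Exact minimizer via block merging/splitting."""
    n = len(desired)
    names = names or [str(i) for i in range(n)]
    uf = _UnionFind(n)
    for (u, v, g) in equalities:
        if not uf.union(u, v, g):
            cyc = _find_positive_cycle(
                n, [(a, b, c) for a, b, c in equalities]
                + [(b, a, -c) for a, b, c in equalities], names,
            )
            raise InfeasibleError(
                f"contradictory equality between {names[u]} and {names[v]}"
                + (f"; cycle: {' -> '.join(cyc)}" if cyc else "")
            )

    roots: list[int] = []
    root_index: dict[int, int] = {}
    rel = np.zeros(n)
    for i in range(n):
        r, off = uf.find(i)
        if r not in root_index:
            root_index[r] = len(roots)
            roots.append(r)
        rel[i] = off
    nr = len(roots)
    var_root = np.array([root_index[uf.find(i)[0]] for i in range(n)])

    W = np.zeros(nr)
    S = np.zeros(nr)  # sum of w_i * (d_i - rel_i)
    for i in range(n):
        W[var_root[i]] += weights[i]
        S[var_root[i]] += weights[i] * (desired[i] - rel[i])
    memberless = W <= 0.0
    if memberless.any():
        # pure-guide blocks: tiny weight toward the mean of raw desireds
        for r in np.nonzero(memberless)[0]:
            members = np.nonzero(var_root == r)[0]
            W[r] = GUIDE_EPS_WEIGHT
            S[r] = GUIDE_EPS_WEIGHT * float(
                np.mean(desired[members] - rel[members])
            )

    cons: list[tuple[int, int, float]] = []
    for (u, v, g) in inequalities:
        ru, rv = var_root[u], var_root[v]
        gg = g + rel[u] - rel[v]
        if ru == rv:
            if gg > 1e-9:
                raise InfeasibleError(
                    f"inequality {names[u]} + {g} <= {names[v]} contradicts the "
                    f"equalities merging them"
                )
            continue
        cons.append((int(ru), int(rv), float(gg)))

    m = len(cons)
    x = _vpsc(nr, W, S, cons, names=[names[roots[r]] for r in range(nr)])
    return x[var_root] + rel


def _vpsc(
    nr: int, W: np.ndarray, S: np.ndarray, cons: list[tuple[int, int, float]],
    names: list[str],
) -> np.ndarray:
    """Block-based active-set solve over root variables."""
    m = len(cons)
    if m == 0:
        return S / W
    L = np.array([c[0] for c in cons])
    R = np.array([c[1] for c in cons])
    G = np.array([c[2] for c in cons])

    bid = np.arange(nr)  # block id per root
    boff = np.zeros(nr)  # offset within block
    blkW = W.copy()  # indexed by block id (stale entries ignored)
    blkS = S.copy()
    active: set[int] = set()
    # adjacency over active constraints: root -> list of (cons_idx, other_root)
    adj: dict[int, list[tuple[int, int]]] = {}

    def positions() -> np.ndarray:
        Y = blkS[bid] / blkW[bid]
        return Y + boff

    def members_of(block: int) -> np.ndarray:
        return np.nonzero(bid == block)[0]

    def merge(ci: int) -> None:
        u, v, g = int(L[ci]), int(R[ci]), float(G[ci])
        bu, bv = bid[u], bid[v]
        delta = boff[u] + g - boff[v]
        mv = members_of(bv)
        boff[mv] += delta
        bid[mv] = bu
        blkW[bu] += blkW[bv]
        blkS[bu] += blkS[bv] - delta * blkW[bv]
        # blkS holds sum w_i (t_i - boff_i); shifting boff by delta subtracts
        active.add(ci)
        adj.setdefault(u, []).append((ci, v))
        adj.setdefault(v, []).append((ci, u))

    def split(ci: int) -> None:
        active.discard(ci)
        u, v = int(L[ci]), int(R[ci])
        adj[u] = [(c, o) for (c, o) in adj[u] if c != ci]
        adj[v] = [(c, o) for (c, o) in adj[v] if c != ci]
        block = bid[u]
        comp = _component(u)
        rest = [int(r) for r in members_of(block) if int(r) not in comp]
        # rebuild both components with fresh block stats
        for group in (sorted(comp), rest):
            if not group:
                continue
            gid = group[0]
            anchor = float(boff[gid])
            for r in group:
                bid[r] = gid
                boff[r] -= anchor
            blkW[gid] = float(W[group].sum())
            blkS[gid] = float(sum(S[r] - W[r] * boff[r] for r in group))

    def _component(start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for (c, other) in adj.get(cur, []):
                if c in active and other not in seen:
                    seen.add(other)
                    stack.append(other)
        return seen

    def multipliers() -> dict[int, float]:
        """Lagrange multipliers of the active (tree-structured) constraints,
        by iterative leaf peeling of the KKT stationarity system."""
        pos = positions()
        # force per root: dPhi/dx_r = 2 w_r (x_r - t_r)
        res = (2.0 * (W * pos - S)).astype(float)
        deg: dict[int, int] = {}
        for ci in active:
            deg[int(L[ci])] = deg.get(int(L[ci]), 0) + 1
            deg[int(R[ci])] = deg.get(int(R[ci]), 0) + 1
        remaining = set(active)
        lam: dict[int, float] = {}
        leaf = [r for r in deg if deg[r] == 1]
        while leaf:
            r = leaf.pop()
            edge = next(
                ((c, o) for (c, o) in adj.get(r, []) if c in remaining), None
            )
            if edge is None:
                continue
            ci, other = edge
            # stationarity: F_r + lam (r left) - lam (r right) = 0; the solved
            # multiplier folds into the other endpoint's force
            if int(L[ci]) == r:
                lam[ci] = -res[r]
                res[other] -= lam[ci]
            else:
                lam[ci] = res[r]
                res[other] += lam[ci]
            remaining.discard(ci)
            deg[other] -= 1
            deg[r] -= 1
            if deg[other] == 1:
                leaf.append(other)
        return lam

    max_iter = 200 + 20 * (m + nr)
    it = 0
    while True:
        it += 1
        if it > max_iter:
            cyc = _find_positive_cycle(nr, cons, names)
            raise InfeasibleError(
                "separation system appears infeasible"
                + (f"; violated cycle: {' -> '.join(cyc)}" if cyc else "")
            )
        pos = positions()
        viol = pos[L] + G - pos[R]
        if active:
            viol = viol.copy()
            viol[list(active)] = -np.inf  # active constraints are tight
        ci = int(np.argmax(viol))
        if viol[ci] > _TOL:
            if bid[L[ci]] != bid[R[ci]]:
                merge(ci)
            else:
                _expand(ci, adj, active, L, R, multipliers, split, merge, names)
            continue
        lam = multipliers()
        if lam:
            worst = min(lam, key=lambda c: (lam[c], c))
            if lam[worst] < -1e-7:
                split(worst)
                continue
        return positions()


def _expand(ci, adj, active, L, R, multipliers, split, merge, names) -> None:
    """A violated constraint inside one block: retract the weakest *forward*
    active constraint on the path between its endpoints, then activate it.

    Only forward-oriented path edges are candidates: splitting one lets the
    two sides move apart in the direction that relieves the violation without
    re-violating the split edge.  A path with no forward edge closes a
    positive-gap cycle with the violated constraint, i.e. the system is
    infeasible.
    """
    u, v = int(L[ci]), int(R[ci])
    # path u -> v over active edges, remembering traversal orientation
    prev: dict[int, tuple[int, int]] = {}
    stack = [u]
    seen = {u}
    while stack:
        cur = stack.pop()
        if cur == v:
            break
        for (c, other) in adj.get(cur, []):
            if c in active and other not in seen:
                seen.add(other)
                prev[other] = (cur, c)
                stack.append(other)
    if v not in prev and v != u:
        raise InfeasibleError(
            "internal: endpoints of an intra-block constraint are not "
            "connected by active constraints"
        )
    path: list[tuple[int, bool]] = []  # (cons index, traversed left->right)
    nodes = [v]
    cur = v
    while cur != u:
        p, c = prev[cur]
        path.append((c, int(L[c]) == p and int(R[c]) == cur))
        nodes.append(p)
        cur = p
    forward = [c for (c, fwd) in path if fwd]
    if not forward:
        cyc = " -> ".join(names[n] for n in reversed(nodes))
        raise InfeasibleError(
            f"separation constraints are infeasible; violated cycle: {cyc}"
        )
    lam = multipliers()
    weakest = min(forward, key=lambda c: (lam.get(c, 0.0), c))
    split(weakest)
    merge(ci)


# ---------------------------------------------------------------------------
# public projection API


def project_positions(
    desired: Mapping[str, float],
    separations: Iterable[SeparationConstraint | tuple],
    weights: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Project desired per-axis positions onto a set of separation
    constraints: the returned positions minimize the weighted squared
    displacement while satisfying every constraint.

    ``separations`` may be :class:`SeparationConstraint` objects (their axis
    field is ignored here) or raw ``(left, right, gap, is_equality)`` tuples.
    Guides absent from ``desired`` are created as zero-weight free variables.
    """
    keys = list(desired.keys())
    key_index = {k: i for i, k in enumerate(keys)}
    eqs: list[tuple[int, int, float]] = []
    ineqs: list[tuple[int, int, float]] = []

    def index_of(k: str) -> int:
        if k not in key_index:
            key_index[k] = len(keys)
            keys.append(k)
        return key_index[k]

    sep_list = []
    for s in separations:
        if isinstance(s, SeparationConstraint):
            sep_list.append((s.left, s.right, s.gap, s.is_equality))
        else:
            left, right, gap, *rest = s
            sep_list.append((left, right, gap, bool(rest[0]) if rest else False))
    for (left, right, gap, is_eq) in sep_list:
        tri = (index_of(left), index_of(right), float(gap))
        (eqs if is_eq else ineqs).append(tri)

    d = np.array([desired.get(k, 0.0) for k in keys], dtype=float)
    w = np.ones(len(keys))
    for i, k in enumerate(keys):
        if k not in desired:
            w[i] = 0.0
        elif weights is not None:
            w[i] = weights.get(k, 1.0)
    x = solve_separation_qp(d, w, eqs, ineqs, names=keys)
    return {k: float(x[key_index[k]]) for k in keys}


# ---------------------------------------------------------------------------
# layout problem & greedy non-overlap


@dataclass
class LayoutProblem:
    nodes: dict[str, Rect]  # desired centers with *actual* sizes
    constraint_set: ConstraintSet
    hierarchy: dict[str, Optional[str]]  # node -> parent (None at root level)
    node_margin: float = DEFAULT_NODE_MARGIN

    def enlarged(self, key: str) -> Rect:
        return self.nodes[key].inflate(self.node_margin)


@dataclass
class LayoutResult:
    centers: dict[str, tuple[float, float]]
    guide_values: dict[str, tuple[Optional[float], Optional[float]]]
    movement: float
    unresolved_overlaps: list[tuple[str, str]]
    violations: list[str]
    accepted_nonoverlap: int = 0


@dataclass
class _AxisSystem:
    desired: dict[str, float]
    weights: dict[str, float]
    eqs: list[tuple[str, str, float]]
    ineqs: list[tuple[str, str, float]]

    def solve(self) -> dict[str, float]:
        seps = [(l, r, g, True) for (l, r, g) in self.eqs] + [
            (l, r, g, False) for (l, r, g) in self.ineqs
        ]
        return project_positions(self.desired, seps, self.weights)


def _build_axis_system(problem: LayoutProblem, axis: str) -> _AxisSystem:
    cset = problem.constraint_set
    desired = {
        k: (r.cx if axis == "x" else r.cy) for k, r in problem.nodes.items()
    }
    weights = {k: 1.0 for k in problem.nodes}
    for a in cset.alignments:
        if a.axis == axis:
            desired.setdefault(a.guide, a.guide_pos)
            weights[a.guide] = 0.0
    eqs, ineqs = cset.compile_axis(axis, problem.nodes)
    return _AxisSystem(desired, weights, eqs, ineqs)


def _equality_roots(system: _AxisSystem) -> dict[str, str]:
    """Representative per variable under the axis equality constraints."""
    parent: dict[str, str] = {}

    def find(k: str) -> str:
        parent.setdefault(k, k)
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for (left, right, _gap) in system.eqs:
        ra, rb = find(left), find(right)
        if ra != rb:
            parent[ra] = rb
    return {k: find(k) for k in system.desired}


def resolve_overlaps(
    problem: LayoutProblem,
    systems: dict[str, _AxisSystem],
    positions: dict[str, dict[str, float]],
    max_retractions: int = 1000,
) -> tuple[list[tuple[str, str]], int]:
    """Greedy removal of sibling overlaps with the four ranked alternatives.

    Mutates ``systems`` (accepted separations are appended) and ``positions``
    (re-solved after each accepted alternative).  Returns the unresolved
    overlapping pairs and the number of accepted constraints.
    """
    roots = {axis: _equality_roots(systems[axis]) for axis in ("x", "y")}
    failed: set[tuple[str, str]] = set()
    accepted = 0
    retractions = 0

    def current_rect(key: str) -> Rect:
        r = problem.enlarged(key)
        return r.moved_to(positions["x"][key], positions["y"][key])

    def overlapping_pairs() -> list[tuple[float, str, str]]:
        keys = sorted(problem.nodes)
        out = []
        for i, a in enumerate(keys):
            ra = current_rect(a)
            for b in keys[i + 1 :]:
                if problem.hierarchy.get(a) != problem.hierarchy.get(b):
                    continue  # non-overlap applies between siblings only
                if (a, b) in failed:
                    continue
                if roots["x"][a] == roots["x"][b] and roots["y"][a] == roots["y"][b]:
                    # rigidly co-located by equality constraints on both axes
                    # (enzyme pairs, chained group processes): deliberate
                    continue
                rb = current_rect(b)
                area = ra.overlap_area(rb)
                if area > 1e-9 and ra.overlaps(rb):
                    out.append((area, a, b))
        out.sort(key=lambda t: (-t[0], t[1], t[2]))
        return out

    while True:
        pairs = overlapping_pairs()
        if not pairs or retractions >= max_retractions:
            break
        _, a, b = pairs[0]
        ea, eb = problem.enlarged(a), problem.enlarged(b)
        gap_x = (ea.w + eb.w) / 2.0
        gap_y = (ea.h + eb.h) / 2.0
        # candidate order: x before y, negative (a before b) before positive
        candidates = [
            ("x", a, b, gap_x),
            ("x", b, a, gap_x),
            ("y", a, b, gap_y),
            ("y", b, a, gap_y),
        ]
        trials = []
        for idx, (axis, left, right, gap) in enumerate(candidates):
            system = systems[axis]
            trial = _AxisSystem(
                system.desired, system.weights, system.eqs,
                system.ineqs + [(left, right, gap)],
            )
            try:
                new_pos = trial.solve()
            except InfeasibleError:
                retractions += 1
                continue
            movement = sum(
                abs(new_pos[k] - positions[axis][k]) for k in problem.nodes
            )
            trials.append((movement, idx, axis, (left, right, gap), new_pos))
        if not trials:
            failed.add((a, b))
            logger.warning("overlap %s/%s unresolved: all four alternatives failed", a, b)
            continue
        trials.sort(key=lambda t: (t[0], t[1]))
        movement, _idx, axis, tri, new_pos = trials[0]
        systems[axis].ineqs.append(tri)
        positions[axis] = new_pos
        accepted += 1
    return [(a, b) for (_, a, b) in overlapping_pairs()], accepted


def solve_layout(problem: LayoutProblem) -> LayoutResult:
    """Full placement: project per axis onto the hard constraints, then
    resolve residual overlaps greedily at the lower priority."""
    systems = {axis: _build_axis_system(problem, axis) for axis in ("x", "y")}
    positions = {axis: systems[axis].solve() for axis in ("x", "y")}

    unresolved, accepted = resolve_overlaps(problem, systems, positions)

    centers = {
        k: (positions["x"][k], positions["y"][k]) for k in problem.nodes
    }
    guides: dict[str, tuple[Optional[float], Optional[float]]] = {}
    for a in problem.constraint_set.alignments:
        gx = positions["x"].get(a.guide) if a.axis == "x" else None
        gy = positions["y"].get(a.guide) if a.axis == "y" else None
        guides[a.guide] = (gx, gy)
    movement = sum(
        abs(centers[k][0] - problem.nodes[k].cx)
        + abs(centers[k][1] - problem.nodes[k].cy)
        for k in problem.nodes
    )
    violations = check_hard_constraints(systems, positions)
    return LayoutResult(
        centers=centers,
        guide_values=guides,
        movement=movement,
        unresolved_overlaps=unresolved,
        violations=violations,
        accepted_nonoverlap=accepted,
    )


def check_hard_constraints(
    systems: dict[str, _AxisSystem],
    positions: dict[str, dict[str, float]],
    tol: float = 1e-6,
) -> list[str]:
    out = []
    for axis, system in systems.items():
        pos = positions[axis]
        for (left, right, gap) in system.eqs:
            if abs(pos[left] + gap - pos[right]) > tol:
                out.append(f"{axis}: {left} + {gap} = {right} violated")
        for (left, right, gap) in system.ineqs:
            if pos[left] + gap - pos[right] > tol:
                out.append(f"{axis}: {left} + {gap} <= {right} violated")
    return out


def layout_map(
    result, node_margin: float = DEFAULT_NODE_MARGIN, cset: Optional[ConstraintSet] = None,
    **constraint_kwargs,
) -> LayoutResult:
    """Convenience wrapper: build constraints for a translated map, solve the
    layout and write the final centers back into the glyph bboxes."""
    from .constraints import build_constraint_set

    if cset is None:
        cset = build_constraint_set(result, node_margin=node_margin, **constraint_kwargs)
    hierarchy = {g.glyph_id: g.parent_id for g in result.map.glyphs}
    nodes = {g.glyph_id: g.bbox for g in result.map.glyphs}
    problem = LayoutProblem(nodes, cset, hierarchy, node_margin)
    layout_result = solve_layout(problem)
    for g in result.map.glyphs:
        cx, cy = layout_result.centers[g.glyph_id]
        g.bbox = g.bbox.moved_to(cx, cy)
    return layout_result
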