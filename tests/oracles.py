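"""Independent oracles for cross-checking the package's core algorithms.

These deliberately use different computational routes from the
implementation: exhaustive active-set enumeration with dense KKT solves for
the separation QP, and an O(V^2) geometric visibility graph with a
(vertex, heading) Dijkstra for orthogonal routing.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

from kgml2sbgn.geometry import Rect, segment_crosses_rect


def qp_oracle(
    desired: np.ndarray,
    weights: np.ndarray,
    equalities: list[tuple[int, int, float]],
    inequalities: list[tuple[int, int, float]],
) -> np.ndarray | None:
    """Exact minimizer of sum w_i (x_i - d_i)^2 under separation constraints
    by enumerating every active subset of the inequalities and solving the
    KKT system densely.  Returns None when infeasible."""
    n = len(desired)
    W = np.diag(2.0 * np.maximum(weights, 1e-9))

    def row(u: int, v: int) -> np.ndarray:
        r = np.zeros(n)
        r[u] = 1.0
        r[v] = -1.0
        return r

    best = None
    best_obj = np.inf
    m = len(inequalities)
    for mask in range(1 << m):
        active = [inequalities[i] for i in range(m) if mask >> i & 1]
        rows = [row(u, v) for (u, v, _) in equalities + active]
        rhs = [-g for (_, _, g) in equalities + active]
        if rows:
            A = np.vstack(rows)
            b = np.array(rhs)
            kkt = np.block([[W, A.T], [A, np.zeros((len(rows), len(rows)))]])
            vec = np.concatenate([W @ desired, b])
            sol, *_ = np.linalg.lstsq(kkt, vec, rcond=None)
            x = sol[:n]
            lam = sol[n:]
            # KKT residual must vanish (lstsq also "solves" inconsistent systems)
            if np.linalg.norm(kkt @ sol - vec) > 1e-6:
                continue
            lam_ineq = lam[len(equalities):]
        else:
            x = desired.copy()
            lam_ineq = np.array([])
        feasible = all(
            x[u] + g <= x[v] + 1e-8 for (u, v, g) in inequalities
        ) and all(abs(x[u] + g - x[v]) <= 1e-8 for (u, v, g) in equalities)
        if not feasible:
            continue
        if len(lam_ineq) and lam_ineq.min() < -1e-8:
            continue
        obj = float(np.sum(np.maximum(weights, 0) * (x - desired) ** 2))
        if obj < best_obj - 1e-12:
            best_obj = obj
            best = x
    return best


def brute_force_route_cost(
    obstacles: list[Rect],
    start: tuple[float, float],
    goal: tuple[float, float],
    bend_penalty: float,
    start_dir: str | None = None,
    goal_dir: str | None = None,
) -> float | None:
    """Minimum cost of an orthogonal obstacle-avoiding path on the full
    interesting-coordinate grid with all-pairs visibility edges."""
    xs = sorted({start[0], goal[0]} | {v for r in obstacles for v in (r.left, r.right)})
    ys = sorted({start[1], goal[1]} | {v for r in obstacles for v in (r.top, r.bottom)})
    vertices = [
        (x, y) for x in xs for y in ys
        if not any(r.contains_point(x, y, strict=True) for r in obstacles)
    ]
    vset = set(vertices)
    if start not in vset or goal not in vset:
        return None

    def opp_of(d: str) -> str:
        return {"up": "down", "down": "up", "left": "right", "right": "left"}[d]
    edges: dict[tuple, list[tuple[tuple, str, float]]] = {v: [] for v in vertices}
    for a, b in itertools.combinations(vertices, 2):
        if a[0] != b[0] and a[1] != b[1]:
            continue
        if any(segment_crosses_rect(a, b, r) for r in obstacles):
            continue
        d = abs(a[0] - b[0]) + abs(a[1] - b[1])
        if d == 0:
            continue
        if a[0] == b[0]:
            d1 = "down" if b[1] > a[1] else "up"
        else:
            d1 = "right" if b[0] > a[0] else "left"
        opp = {"up": "down", "down": "up", "left": "right", "right": "left"}
        edges[a].append((b, d1, d))
        edges[b].append((a, opp[d1], d))
    best: dict[tuple, float] = {}
    pq = [(0.0, 0, start, start_dir)]
    counter = itertools.count()
    while pq:
        cost, _, node, direction = heapq.heappop(pq)
        key = (node, direction)
        if key in best:
            continue
        best[key] = cost
        if node == goal and (goal_dir is None or direction == goal_dir):
            return cost
        for (other, d, dist) in edges[node]:
            if direction is not None and d == opp_of(direction):
                continue  # 180-degree reversals retrace the route; disallowed
            bend = 1 if direction is not None and d != direction else 0
            nkey = (other, d)
            ncost = cost + dist + bend_penalty * bend
            if nkey not in best:
                heapq.heappush(pq, (ncost, next(counter), other, d))
    return None


def single_linkage_1d_brute(coords: list[float], tol: float) -> list[list[float]]:
    """Reference single-linkage clustering by repeated pairwise merging."""
    clusters = [[c] for c in coords]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(a - b) <= tol for a in clusters[i] for b in clusters[j]
                ):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return [sorted(c) for c in clusters]
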