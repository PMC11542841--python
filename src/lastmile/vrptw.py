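"""Single-depot vehicle routing with a daily time window.

Each community health worker (a "unit") walks a route that starts and
ends at the depot, visiting a subset of targets; every target is
serviced exactly once, and each route's duration (walking plus service)
must fit within the workday horizon.  The objective is the total
duration of the fleet for a fixed number of units.

The solver is a Solomon-style sequential cheapest-insertion
construction — routes are opened one at a time, seeded with the
farthest unrouted target, and grown by the insertion that increases
duration least while respecting the horizon — followed by
best-improvement local search over relocate, inter-route exchange and
intra-route 2-opt moves until no improving move remains.  Randomness
enters only through restart perturbation (a fixed number of restarts
with randomized route seeds); results are deterministic for a fixed
seed.

``brute_force_solve`` is an exact oracle for small instances
(Held–Karp optimal route per subset, then an exact set-partition DP),
intended for testing the heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoutingInstance",
    "Itinerary",
    "Solution",
    "fold_service_times",
    "solve",
    "brute_force_solve",
    "check_solution",
]

_EPS = 1e-9
_FEAS_EPS = 1e-9


@dataclass
class RoutingInstance:
    """A VRPTW instance: travel matrix, service times, horizon, fleet size.

    Index 0 is the depot; indices 1..m are targets.  The augmented arc
    cost i -> j is travel(i, j) + service(j), with no service at the
    depot, so a route's duration is the sum of its augmented arcs.
    """

    travel_min: np.ndarray          # (m+1, m+1) walking minutes
    service_min: np.ndarray         # (m+1,), [0] == 0
    horizon_min: float = 480.0
    n_units: int = 1
    target_ids: list[int] = field(default_factory=list)  # external ids, rows 1..m
    speed_kmh: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.travel_min, dtype=float)
        s = np.asarray(self.service_min, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("travel matrix must be square")
        if s.shape != (t.shape[0],):
            raise ValueError("service vector length must match matrix")
        if s[0] != 0.0:
            raise ValueError("depot carries no service time")
        if (t < 0).any() or (s < 0).any():
            raise ValueError("negative travel or service time")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        self.travel_min = t
        self.service_min = s
        if not self.target_ids:
            self.target_ids = list(range(1, t.shape[0]))
        if len(self.target_ids) != t.shape[0] - 1:
            raise ValueError("target_ids length must be m")

    @property
    def n_targets(self) -> int:
        return self.travel_min.shape[0] - 1

    @property
    def augmented_minutes(self) -> np.ndarray:
        """Arc cost matrix with destination service folded in."""
        return self.travel_min + self.service_min[None, :]

    def replace(self, **kwargs) -> "RoutingInstance":
        d = dict(
            travel_min=self.travel_min,
            service_min=self.service_min,
            horizon_min=self.horizon_min,
            n_units=self.n_units,
            target_ids=list(self.target_ids),
            speed_kmh=self.speed_kmh,
        )
        d.update(kwargs)
        return RoutingInstance(**d)


@dataclass
class Itinerary:
    """One person-day: an ordered depot-to-depot visit sequence with times."""

    unit_index: int
    visit_order: list[int]        # external target ids
    arrivals_min: list[float]     # clock minutes from day start, per stop
    departures_min: list[float]
    travel_min: float
    service_min: float

    @property
    def total_min(self) -> float:
        return self.travel_min + self.service_min

    @property
    def n_stops(self) -> int:
        return len(self.visit_order)


@dataclass
class Solution:
    """Solver output: one itinerary per used unit plus the objective."""

    itineraries: list[Itinerary]
    objective_min: float
    feasible: bool
    unassigned: list[int] = field(default_factory=list)

    @property
    def n_routes(self) -> int:
        return len(self.itineraries)

    @property
    def total_travel_min(self) -> float:
        return sum(it.travel_min for it in self.itineraries)

    @property
    def total_service_min(self) -> float:
        return sum(it.service_min for it in self.itineraries)


def fold_service_times(matrix, targets, horizon_min: float = 480.0,
                       n_units: int = 1) -> RoutingInstance:
    """Build a RoutingInstance from a travel-time matrix and visit targets.

    Every target must be a point of the matrix; the instance travel
    matrix is the submatrix over depot + targets (in target order), and
    service times ride along as the folded arc-destination component.
    """
    id_to_idx = {pid: k for k, pid in enumerate(matrix.point_ids)}
    for b in targets:
        if b.id not in id_to_idx:
            raise KeyError(f"target {b.id} not present in travel-time matrix")
        if b.service_min is None:
            raise ValueError(f"target {b.id} has no service time")
    rows = [0] + [id_to_idx[b.id] for b in targets]
    sub = matrix.minutes[np.ix_(rows, rows)]
    service = np.array([0.0] + [float(b.service_min) for b in targets])
    return RoutingInstance(
        travel_min=sub,
        service_min=service,
        horizon_min=horizon_min,
        n_units=n_units,
        target_ids=[b.id for b in targets],
        speed_kmh=matrix.speed_kmh,
    )


# ---------------------------------------------------------------------------
# heuristic solver
# ---------------------------------------------------------------------------

def _route_travel(route: list[int], t: np.ndarray) -> float:
    if not route:
        return 0.0
    tot = t[0, route[0]] + t[route[-1], 0]
    for a, b in zip(route, route[1:]):
        tot += t[a, b]
    return float(tot)


def _route_duration(route: list[int], t: np.ndarray, s: np.ndarray) -> float:
    return _route_travel(route, t) + float(s[route].sum()) if route else 0.0


def _cheapest_insertion(route: list[int], dur: float, unrouted: list[int],
                        t: np.ndarray, s: np.ndarray, horizon: float):
    """Best (target, position, delta) for inserting into one route.

    Delta is the duration increase (travel delta + service).  Ties break
    on lower target id, then lower position — guaranteed by the scan
    order of the flattened cost array.
    """
    if not unrouted:
        return None
    us = np.asarray(unrouted)           # ascending
    seq = [0] + route + [0]
    xs = np.asarray(seq[:-1])
    ys = np.asarray(seq[1:])
    # cost[ui, pos] = travel delta of inserting u into arc (xs[pos], ys[pos])
    cost = t[np.ix_(xs, us)].T + t[np.ix_(us, ys)] - t[xs, ys][None, :]
    delta = cost + s[us][:, None]
    feas = dur + delta <= horizon + _FEAS_EPS
    if not feas.any():
        return None
    masked = np.where(feas, delta, np.inf)
    flat = int(np.argmin(masked))       # row-major: lowest id first, then pos
    ui, pos = divmod(flat, masked.shape[1])
    return int(us[ui]), int(pos), float(masked[ui, pos])


def _construct(m: int, t: np.ndarray, s: np.ndarray, horizon: float,
               n_units: int, rng: np.random.Generator | None):
    """Sequential cheapest-insertion construction.

    Routes open one at a time; the seed of each new route is the
    farthest unrouted target from the depot (or, under restart
    perturbation, a random pick among the five farthest).
    """
    unrouted = list(range(1, m + 1))
    routes: list[list[int]] = []
    durs: list[float] = []
    while unrouted and len(routes) < n_units:
        by_dist = sorted(unrouted, key=lambda u: (-t[0, u], u))
        if rng is None:
            seed_t = by_dist[0]
        else:
            seed_t = by_dist[int(rng.integers(0, min(5, len(by_dist))))]
        route = [seed_t]
        unrouted.remove(seed_t)
        dur = _route_duration(route, t, s)
        if dur > horizon + _FEAS_EPS:
            # this target can never be served; keep going so the caller
            # can report it as unassigned
            unrouted.append(seed_t)
            unrouted.sort()
            break
        while True:
            best = _cheapest_insertion(route, dur, unrouted, t, s, horizon)
            if best is None:
                break
            u, pos, delta = best
            route.insert(pos, u)
            unrouted.remove(u)
            dur += delta
        routes.append(route)
        durs.append(dur)
    return routes, durs, unrouted


def _local_search(routes: list[list[int]], durs: list[float], t: np.ndarray,
                  s: np.ndarray, horizon: float, max_moves: int = 100_000) -> None:
    """Best-improvement local search, in place.

    Move families: relocate (intra- and inter-route), inter-route
    exchange, intra-route 2-opt.  Each pass evaluates every move
    (vectorized), applies the single best improving one, and repeats
    until no move improves the total duration.
    """
    for _ in range(max_moves):
        m_total = sum(len(r) for r in routes)
        if m_total < 2:
            return
        # flat target bookkeeping
        node_route = {}
        prev = {}
        nxt = {}
        for ri, r in enumerate(routes):
            seq = [0] + r + [0]
            for k in range(1, len(seq) - 1):
                node_route[seq[k]] = ri
                prev[seq[k]] = seq[k - 1]
                nxt[seq[k]] = seq[k + 1]
        nodes = np.asarray(sorted(node_route))
        p = np.asarray([prev[u] for u in nodes])
        q = np.asarray([nxt[u] for u in nodes])
        r_of = np.asarray([node_route[u] for u in nodes])
        D = np.asarray(durs)
        gain = t[p, nodes] + t[nodes, q] - t[p, q]      # travel saved by removal

        best_delta = -1e-9
        best_move = None

        # --- relocate ---------------------------------------------------
        arcs_x, arcs_y, arc_route = [], [], []
        for ri, r in enumerate(routes):
            seq = [0] + r + [0]
            arcs_x.extend(seq[:-1])
            arcs_y.extend(seq[1:])
            arc_route.extend([ri] * (len(seq) - 1))
        ax = np.asarray(arcs_x)
        ay = np.asarray(arcs_y)
        ar = np.asarray(arc_route)
        # ci[u, a]: travel cost of inserting u into arc a
        ci = t[np.ix_(ax, nodes)].T + t[np.ix_(nodes, ay)] - t[ax, ay][None, :]
        delta = ci - gain[:, None]
        same = r_of[:, None] == ar[None, :]
        adj = (ax[None, :] == nodes[:, None]) | (ay[None, :] == nodes[:, None])
        new_inter = D[ar][None, :] + ci + s[nodes][:, None]
        new_intra = D[r_of][:, None] - gain[:, None] + ci
        feas = np.where(same, new_intra, new_inter) <= horizon + _FEAS_EPS
        ok = feas & ~adj & (delta < best_delta)
        if ok.any():
            masked = np.where(ok, delta, np.inf)
            flat = int(np.argmin(masked))
            ui, a = divmod(flat, masked.shape[1])
            best_delta = float(masked[ui, a])
            best_move = ("relocate", int(nodes[ui]), int(a))

        # --- inter-route exchange ---------------------------------------
        # E[u, v]: travel delta on u's route when v replaces u
        const = t[p, nodes] + t[nodes, q]
        E = t[np.ix_(p, nodes)] + t[np.ix_(nodes, q)].T - const[:, None]
        dd = E + E.T
        feas_u = D[r_of][:, None] + E + (s[nodes][None, :] - s[nodes][:, None]) \
            <= horizon + _FEAS_EPS
        diff_route = r_of[:, None] != r_of[None, :]
        upper = np.triu(np.ones_like(dd, dtype=bool), k=1)
        ok = diff_route & upper & feas_u & feas_u.T & (dd < best_delta)
        if ok.any():
            masked = np.where(ok, dd, np.inf)
            flat = int(np.argmin(masked))
            ui, vi = divmod(flat, masked.shape[1])
            if float(masked[ui, vi]) < best_delta:
                best_delta = float(masked[ui, vi])
                best_move = ("exchange", int(nodes[ui]), int(nodes[vi]))

        # --- intra-route 2-opt (travel is symmetric) --------------------
        for ri, r in enumerate(routes):
            L = len(r)
            if L < 2:
                continue
            seq = np.asarray([0] + r + [0])
            # d2[i-1, j-1] = delta of reversing r[i-1 .. j-1], 1 <= i < j <= L
            A = t[np.ix_(seq[0:L], seq[1:L + 1])]
            B = t[np.ix_(seq[1:L + 1], seq[2:L + 2])]
            d2 = A + B - np.diag(A)[:, None] - np.diag(B)[None, :]
            d2 = np.where(np.triu(np.ones((L, L), dtype=bool), k=1), d2, np.inf)
            flat = int(np.argmin(d2))
            i0, j0 = divmod(flat, L)
            if d2[i0, j0] < best_delta:
                best_delta = float(d2[i0, j0])
                best_move = ("2opt", ri, i0, j0)

        if best_move is None:
            return

        kind = best_move[0]
        if kind == "relocate":
            _, u, a = best_move
            ra = node_route[u]
            routes[ra].remove(u)
            # re-derive insertion slot from the arc endpoints
            rb = int(ar[a])
            x = int(ax[a])
            pos = 0 if x == 0 else routes[rb].index(x) + 1
            routes[rb].insert(pos, u)
            durs[ra] = _route_duration(routes[ra], t, s)
            durs[rb] = _route_duration(routes[rb], t, s)
        elif kind == "exchange":
            _, u, v = best_move
            ra, rb = node_route[u], node_route[v]
            iu, iv = routes[ra].index(u), routes[rb].index(v)
            routes[ra][iu], routes[rb][iv] = v, u
            durs[ra] = _route_duration(routes[ra], t, s)
            durs[rb] = _route_duration(routes[rb], t, s)
        else:  # 2-opt
            _, ri, i, j = best_move
            routes[ri][i:j + 1] = routes[ri][i:j + 1][::-1]
            durs[ri] = _route_duration(routes[ri], t, s)


def _insert_one(routes, durs, unrouted, t, s, horizon) -> bool:
    """Insert the single cheapest-to-place leftover target, if any fits."""
    best = None
    for u in sorted(unrouted):
        for ri, r in enumerate(routes):
            got = _cheapest_insertion(r, durs[ri], [u], t, s, horizon)
            if got is not None and (best is None or got[2] < best[3]):
                best = (u, ri, got[1], got[2])
    if best is None:
        return False
    u, ri, pos, delta = best
    routes[ri].insert(pos, u)
    durs[ri] += delta
    unrouted.remove(u)
    return True


def _try_repair(routes, durs, unrouted, t, s, horizon) -> None:
    """Insert leftover targets wherever they fit, compacting in between."""
    while unrouted:
        if _insert_one(routes, durs, unrouted, t, s, horizon):
            continue
        _local_search(routes, durs, t, s, horizon)
        if not _insert_one(routes, durs, unrouted, t, s, horizon):
            return


def _build_solution(routes: list[list[int]], t: np.ndarray, s: np.ndarray,
                    target_ids: list[int], unassigned: list[int]) -> Solution:
    its = []
    total = 0.0
    for k, route in enumerate(r for r in routes if r):
        arr, dep = [], []
        clock = 0.0
        travel = 0.0
        prev = 0
        for u in route:
            leg = float(t[prev, u])
            travel += leg
            clock += leg
            arr.append(clock)
            clock += float(s[u])
            dep.append(clock)
            prev = u
        leg = float(t[prev, 0])
        travel += leg
        service = float(s[route].sum())
        its.append(Itinerary(
            unit_index=k,
            visit_order=[target_ids[u - 1] for u in route],
            arrivals_min=arr,
            departures_min=dep,
            travel_min=travel,
            service_min=service,
        ))
        total += travel + service
    feasible = not unassigned
    return Solution(
        itineraries=its,
        objective_min=total if feasible else math.inf,
        feasible=feasible,
        unassigned=[target_ids[u - 1] for u in sorted(unassigned)],
    )


def solve(instance: RoutingInstance, rng: np.random.Generator | int | None = None,
          n_restarts: int = 3) -> Solution:
    """Heuristic VRPTW solve; deterministic for a fixed seed.

    Restart 0 uses the deterministic farthest-seed construction; later
    restarts randomize the route seeds.  The best feasible solution
    across restarts wins; if none is feasible the best-coverage attempt
    is returned with ``feasible=False``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    t = instance.travel_min
    s = instance.service_min
    m = instance.n_targets
    horizon = instance.horizon_min
    if m == 0:
        return Solution(itineraries=[], objective_min=0.0, feasible=True)

    best: tuple[int, float, list[list[int]], list[int]] | None = None
    for restart in range(max(1, n_restarts)):
        routes, durs, unrouted = _construct(
            m, t, s, horizon, instance.n_units, rng if restart else None)
        if unrouted:
            _try_repair(routes, durs, unrouted, t, s, horizon)
        _local_search(routes, durs, t, s, horizon)
        if unrouted:
            _try_repair(routes, durs, unrouted, t, s, horizon)
        key = (len(unrouted), sum(durs))
        if best is None or key < (best[0], best[1]):
            best = (len(unrouted), key[1], [list(r) for r in routes], list(unrouted))
    _, _, routes, unrouted = best
    return _build_solution(routes, t, s, instance.target_ids, unrouted)


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------

def brute_force_solve(instance: RoutingInstance) -> Solution:
    """Provably optimal solution by exhaustive search (small instances).

    Held–Karp gives the optimal visiting order for every target subset;
    a set-partition DP then splits the targets into at most ``n_units``
    feasible routes minimizing total duration.  Limited to <= 9 targets.
    """
    m = instance.n_targets
    if m > 9:
        raise ValueError(f"brute_force_solve limited to 9 targets, got {m}")
    if m == 0:
        return Solution(itineraries=[], objective_min=0.0, feasible=True)
    t = instance.travel_min
    s = instance.service_min
    horizon = instance.horizon_min
    full = (1 << m) - 1

    # Held-Karp over subsets; hk[mask][last] = min travel depot -> ... -> last
    hk = [dict() for _ in range(1 << m)]
    parent = [dict() for _ in range(1 << m)]
    for u in range(m):
        hk[1 << u][u] = float(t[0, u + 1])
        parent[1 << u][u] = None
    for mask in range(1, full + 1):
        if not hk[mask]:
            continue
        for last, cost in list(hk[mask].items()):
            for v in range(m):
                if mask & (1 << v):
                    continue
                nm = mask | (1 << v)
                nc = cost + float(t[last + 1, v + 1])
                if v not in hk[nm] or nc < hk[nm][v] - _EPS:
                    hk[nm][v] = nc
                    parent[nm][v] = last

    svc = np.zeros(1 << m)
    for mask in range(1, full + 1):
        lsb = mask & -mask
        svc[mask] = svc[mask ^ lsb] + float(s[lsb.bit_length()])  # target i -> row i

    route_dur = np.full(1 << m, math.inf)
    route_last = np.full(1 << m, -1, dtype=int)
    for mask in range(1, full + 1):
        best_d, best_l = math.inf, -1
        for last, cost in hk[mask].items():
            d = cost + float(t[last + 1, 0]) + svc[mask]
            if d < best_d - _EPS or (abs(d - best_d) <= _EPS and last < best_l):
                best_d, best_l = d, last
        route_dur[mask] = best_d
        route_last[mask] = best_l
    feas_route = route_dur <= horizon + 1e-6

    # partition DP: G[k][mask] = min total duration splitting mask into
    # at most k feasible routes
    kmax = min(instance.n_units, m)
    G = [np.full(1 << m, math.inf)]
    G[0][0] = 0.0
    choice: list[dict[int, int]] = [dict()]
    for k in range(1, kmax + 1):
        g = G[k - 1].copy()
        ch: dict[int, int] = {}
        for mask in range(1, full + 1):
            sub = mask
            while sub:
                if feas_route[sub]:
                    cand = G[k - 1][mask ^ sub] + route_dur[sub]
                    if cand < g[mask] - _EPS:
                        g[mask] = cand
                        ch[mask] = sub
                sub = (sub - 1) & mask
        G.append(g)
        choice.append(ch)
    if not math.isfinite(G[kmax][full]):
        return Solution(itineraries=[], objective_min=math.inf, feasible=False,
                        unassigned=list(instance.target_ids))

    # reconstruct subsets
    subsets = []
    mask, k = full, kmax
    while mask:
        if k > 1 and G[k - 1][mask] <= G[k][mask] + _EPS:
            k -= 1
            continue
        sub = choice[k][mask]
        subsets.append(sub)
        mask ^= sub
        k -= 1

    routes = []
    for sub in subsets:
        order = []
        msk, last = sub, int(route_last[sub])
        while last is not None and msk:
            order.append(last + 1)
            nlast = parent[msk][last]
            msk ^= 1 << last
            last = nlast
        order.reverse()
        routes.append(order)
    return _build_solution(routes, t, s, instance.target_ids, [])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def check_solution(instance: RoutingInstance, solution: Solution,
                   tol: float = 1e-6) -> list[str]:
    """Return the list of invariant violations (empty iff valid).

    Checks: every target serviced exactly once; every route within the
    horizon; arrival/departure bookkeeping consistent with the travel
    and service matrices to ``tol`` minutes; depot start/end implied by
    the first/last travel legs.
    """
    violations: list[str] = []
    t = instance.travel_min
    s = instance.service_min
    idx = {pid: k + 1 for k, pid in enumerate(instance.target_ids)}

    seen: dict[int, int] = {}
    for it in solution.itineraries:
        for pid in it.visit_order:
            seen[pid] = seen.get(pid, 0) + 1
    for pid in instance.target_ids:
        c = seen.get(pid, 0)
        if c == 0:
            violations.append(f"target {pid} not visited")
        elif c > 1:
            violations.append(f"target {pid} visited {c} times")
    for pid in seen:
        if pid not in idx:
            violations.append(f"unknown target {pid} in solution")

    total = 0.0
    for it in solution.itineraries:
        rows = [idx[pid] for pid in it.visit_order if pid in idx]
        if len(rows) != len(it.visit_order):
            continue
        travel = _route_travel(rows, t)
        service = float(s[rows].sum()) if rows else 0.0
        if abs(travel - it.travel_min) > tol:
            violations.append(
                f"unit {it.unit_index}: travel bookkeeping off by "
                f"{abs(travel - it.travel_min):.3g} min")
        if abs(service - it.service_min) > tol:
            violations.append(
                f"unit {it.unit_index}: service bookkeeping off by "
                f"{abs(service - it.service_min):.3g} min")
        if it.total_min > instance.horizon_min + tol:
            violations.append(
                f"unit {it.unit_index}: horizon exceeded "
                f"({it.total_min:.1f} > {instance.horizon_min} min)")
        clock = 0.0
        prev = 0
        last_arr = -math.inf
        for k, u in enumerate(rows):
            clock += float(t[prev, u])
            if abs(clock - it.arrivals_min[k]) > tol:
                violations.append(
                    f"unit {it.unit_index}: arrival time at stop {k} inconsistent")
                break
            if it.arrivals_min[k] <= last_arr:
                violations.append(
                    f"unit {it.unit_index}: arrival times not strictly increasing")
                break
            last_arr = it.arrivals_min[k]
            clock += float(s[u])
            if abs(clock - it.departures_min[k]) > tol:
                violations.append(
                    f"unit {it.unit_index}: departure time at stop {k} inconsistent")
                break
            prev = u
        total += it.total_min
    if solution.feasible and abs(total - solution.objective_min) > max(tol, 1e-6 * max(1.0, total)):
        violations.append("objective does not equal the sum of route durations")
    return violations
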