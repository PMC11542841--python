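"""Two-step workforce sizing for a catchment.

Step 1 estimates the work as a single unconstrained grand tour over all
targets (one walker, no workday limit) and seeds the fleet size with
ceil(grand-tour duration / workday).  Step 2 solves the time-windowed
routing problem with that many units, incrementing by one until a
feasible plan is found.  The resulting count is read equally as "days
for one CHW" or "CHWs to finish in one day" — a person-day count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .vrptw import RoutingInstance, Solution, check_solution, solve

__all__ = [
    "FleetPlan",
    "UnreachableTargetError",
    "FleetSizingError",
    "unconstrained_total",
    "size_fleet",
]


class UnreachableTargetError(ValueError):
    """A target cannot be served within the workday even on its own."""


class FleetSizingError(RuntimeError):
    """The incremental fleet search exceeded its cap without a solution."""


@dataclass
class FleetPlan:
    """A sized plan: the routing solution plus aggregate resource totals."""

    person_days: int
    solution: Solution
    total_travel_min: float
    total_service_min: float
    total_travel_km: float | None

    @property
    def total_work_min(self) -> float:
        return self.total_travel_min + self.total_service_min


def unconstrained_total(instance: RoutingInstance,
                        rng: np.random.Generator | int | None = None) -> float:
    """Duration (travel + service, minutes) of a single grand tour.

    One walker serves every target with no workday limit, returning to
    the depot at the end — the quantity that seeds fleet sizing.
    """
    relaxed = instance.replace(n_units=1, horizon_min=math.inf)
    sol = solve(relaxed, rng=rng)
    if not sol.feasible:  # cannot happen with an infinite horizon
        raise RuntimeError("grand tour unexpectedly infeasible")
    return sol.objective_min


def size_fleet(instance: RoutingInstance,
               rng: np.random.Generator | int | None = None,
               cap: int | None = None) -> FleetPlan:
    """Minimum person-days to cover the instance, by incremental search.

    Starts at m0 = ceil(grand-tour duration / horizon) units and
    increments until the heuristic finds a feasible solution.  Raises
    ``UnreachableTargetError`` if some target's round trip plus service
    alone exceeds the horizon, and ``FleetSizingError`` if the search
    passes its cap (default: the number of targets).
    """
    m = instance.n_targets
    t = instance.travel_min
    s = instance.service_min
    horizon = instance.horizon_min
    for k in range(1, m + 1):
        solo = t[0, k] + t[k, 0] + s[k]
        if solo > horizon + 1e-9:
            raise UnreachableTargetError(
                f"target {instance.target_ids[k - 1]} needs {solo:.1f} min "
                f"round trip, exceeding the {horizon:.0f} min workday")
    if m == 0:
        return FleetPlan(0, Solution([], 0.0, True), 0.0, 0.0,
                         0.0 if instance.speed_kmh else None)

    if cap is None:
        cap = m
    total = unconstrained_total(instance, rng=rng)
    m0 = max(1, math.ceil(total / horizon - 1e-9))
    for n_units in range(m0, cap + 1):
        sol = solve(instance.replace(n_units=n_units), rng=rng)
        if sol.feasible:
            bad = check_solution(instance.replace(n_units=n_units), sol)
            if bad:
                raise AssertionError(f"solver produced invalid solution: {bad}")
            travel = sol.total_travel_min
            service = sol.total_service_min
            km = travel / 60.0 * instance.speed_kmh if instance.speed_kmh else None
            return FleetPlan(
                person_days=sol.n_routes,
                solution=sol,
                total_travel_min=travel,
                total_service_min=service,
                total_travel_km=km,
            )
    raise FleetSizingError(
        f"no feasible plan found with up to {cap} units")
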