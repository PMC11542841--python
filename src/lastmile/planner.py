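"""Catchment-level planning, district aggregation, and sensitivity sweeps.

This module strings the pipeline together — scenario draw, travel-time
matrix, routing, fleet sizing — and layers on the program-level
arithmetic: monthly scaling by visit frequency, CHW head-count
conversion against the 20-workday month, stratified district tables,
the visit-time x frequency sensitivity grid, and the occupancy
randomization robustness analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fleet_sizing import FleetPlan, size_fleet
from .network import TravelTimeMatrix, path_length_km, travel_time_matrix
from .scenario import ScenarioConfig, assign_status, visit_targets
from .vrptw import fold_service_times

__all__ = [
    "CatchmentPlan",
    "MonthlyRequirement",
    "plan_catchment",
    "aggregate",
    "monthly_requirement",
    "sensitivity_grid",
    "occupancy_resampling",
    "DEFAULT_PATIENT_MINUTES",
    "DEFAULT_NONPATIENT_MINUTES",
    "DEFAULT_FREQUENCIES",
]

#: Sensitivity-grid defaults: patient visits 10..120 min by 10,
#: non-patient visits 5..60 min by 5, four monthly frequencies --
#: 12 x 12 x 4 = 576 scenarios per catchment.
DEFAULT_PATIENT_MINUTES = tuple(range(10, 121, 10))
DEFAULT_NONPATIENT_MINUTES = tuple(range(5, 61, 5))
DEFAULT_FREQUENCIES = (1, 2, 3, 4)

_SOLVER_SEED_MOD = 2**31 - 1


@dataclass
class CatchmentPlan:
    """Per-catchment resource summary of a sized routing plan."""

    catchment_id: str
    n_targets: int
    person_days: int
    travel_km: float
    travel_h: float
    work_h: float
    fleet: FleetPlan

    @property
    def service_h(self) -> float:
        return self.work_h - self.travel_h

    @property
    def travel_share(self) -> float:
        """Travel time as a fraction of total work time."""
        return self.travel_h / self.work_h if self.work_h > 0 else 0.0


@dataclass
class MonthlyRequirement:
    """Monthly person-days and CHW head count at a visit frequency."""

    visits_per_month: int
    monthly_person_days: int
    chw_count: int


def _itinerary_travel_km(plan: FleetPlan, matrix: TravelTimeMatrix) -> float:
    """Total route length recovered from reconstructed path geometries."""
    pos = {pid: k for k, pid in enumerate(matrix.point_ids)}
    km = 0.0
    for it in plan.solution.itineraries:
        seq = [0] + [pos[pid] for pid in it.visit_order] + [0]
        for a, b in zip(seq, seq[1:]):
            km += path_length_km(matrix, a, b)
    return km


def plan_catchment(catchment, config: ScenarioConfig,
                   catchment_id: str = "catchment",
                   matrix: TravelTimeMatrix | None = None) -> CatchmentPlan:
    """Plan one catchment end to end; deterministic for a fixed seed.

    Draws building statuses, selects targets, builds the walking
    travel-time matrix, folds service times, sizes the fleet and
    recovers travel distance from the route geometries.
    """
    rng = np.random.default_rng(config.seed)
    buildings = assign_status(catchment.buildings, config, rng)
    targets = visit_targets(buildings, config)
    if matrix is None:
        matrix = travel_time_matrix(catchment, config.speed_kmh)
    instance = fold_service_times(matrix, targets, horizon_min=config.workday_min)
    fleet = size_fleet(instance, rng=config.seed % _SOLVER_SEED_MOD)
    travel_km = _itinerary_travel_km(fleet, matrix)
    return CatchmentPlan(
        catchment_id=catchment_id,
        n_targets=len(targets),
        person_days=fleet.person_days,
        travel_km=travel_km,
        travel_h=fleet.total_travel_min / 60.0,
        work_h=fleet.total_work_min / 60.0,
        fleet=fleet,
    )


def plans_to_frame(plans) -> pd.DataFrame:
    rows = [
        {
            "catchment_id": p.catchment_id,
            "n_targets": p.n_targets,
            "person_days": p.person_days,
            "travel_km": p.travel_km,
            "travel_h": p.travel_h,
            "work_h": p.work_h,
            "travel_share": p.travel_share,
        }
        for p in plans
    ]
    return pd.DataFrame(rows)


def aggregate(plans, strata_bounds=(0, 15, 30, 45, 60)) -> pd.DataFrame:
    """Stratified summary table plus a grand-total row.

    Catchments are binned by person-days into half-open strata as
    printed in program tables: the first stratum includes its lower
    bound ("[0,15]"), subsequent ones are lower-exclusive /
    upper-inclusive ("(15,30]"), and everything beyond the last bound
    lands in "> last".
    """
    plans = list(plans)
    if not plans:
        raise ValueError("no plans to aggregate")
    bounds = list(strata_bounds)
    if sorted(set(bounds)) != bounds:
        raise ValueError("strata bounds must be strictly increasing")

    labels = [f"[{bounds[0]},{bounds[1]}]"]
    labels += [f"({lo},{hi}]" for lo, hi in zip(bounds[1:], bounds[2:])]
    labels.append(f"> {bounds[-1]}")

    def stratum(pd_count: float) -> str:
        if bounds[0] <= pd_count <= bounds[1]:
            return labels[0]
        for k, (lo, hi) in enumerate(zip(bounds[1:], bounds[2:]), start=1):
            if lo < pd_count <= hi:
                return labels[k]
        return labels[-1]

    df = plans_to_frame(plans)
    df["stratum"] = [stratum(v) for v in df["person_days"]]
    n = len(df)
    rows = []
    for lab in labels:
        sub = df[df["stratum"] == lab]
        if sub.empty:
            continue
        rows.append({
            "stratum": lab,
            "n_catchments": len(sub),
            "share_pct": 100.0 * len(sub) / n,
            "mean_targets": sub["n_targets"].mean(),
            "mean_travel_km": sub["travel_km"].mean(),
            "mean_travel_h": sub["travel_h"].mean(),
            "mean_work_h": sub["work_h"].mean(),
            "mean_person_days": sub["person_days"].mean(),
        })
    rows.append({
        "stratum": "total",
        "n_catchments": n,
        "share_pct": 100.0,
        "mean_targets": df["n_targets"].sum(),
        "mean_travel_km": df["travel_km"].sum(),
        "mean_travel_h": df["travel_h"].sum(),
        "mean_work_h": df["work_h"].sum(),
        "mean_person_days": df["person_days"].sum(),
    })
    # the "total" row carries district sums in the mean_* columns, the
    # same layout program tables print (stratum averages, district totals)
    return pd.DataFrame(rows)


def monthly_requirement(plan: CatchmentPlan | int,
                        config: ScenarioConfig,
                        _warn: bool = True) -> MonthlyRequirement:
    """Scale a one-round plan to a monthly schedule and a CHW head count.

    Monthly person-days are the one-round person-days times the visit
    frequency (visits are identical rounds); the CHW count divides by
    the workdays available per month, rounded up.
    """
    person_days = plan if isinstance(plan, int) else plan.person_days
    v = config.visits_per_month
    if _warn and v not in (1, 2, 4):
        warnings.warn(
            f"visits_per_month={v} is outside the standard set {{1, 2, 4}}",
            stacklevel=2)
    monthly = person_days * v
    chw = math.ceil(monthly / config.workdays_per_month)
    if person_days > 0:
        chw = max(1, chw)
    return MonthlyRequirement(
        visits_per_month=v,
        monthly_person_days=monthly,
        chw_count=chw,
    )


def sensitivity_grid(
    catchments: dict,
    config: ScenarioConfig | None = None,
    patient_minutes=DEFAULT_PATIENT_MINUTES,
    nonpatient_minutes=DEFAULT_NONPATIENT_MINUTES,
    frequencies=DEFAULT_FREQUENCIES,
) -> pd.DataFrame:
    """Person-days and CHW counts across a visit-time x frequency grid.

    One long-format row per (patient_min, nonpatient_min, frequency,
    catchment).  Statuses are drawn once per catchment at the config
    seed and held fixed across the whole grid; only service times and
    frequency vary.  Defaults yield 12 x 12 x 4 = 576 rows per
    catchment.
    """
    if config is None:
        config = ScenarioConfig(intervention="proccm")
    if not patient_minutes or not nonpatient_minutes or not frequencies:
        raise ValueError("sensitivity ranges must be nonempty")
    rows = []
    for cid, catchment in catchments.items():
        base = config.with_overrides(intervention="proccm")
        matrix = travel_time_matrix(catchment, base.speed_kmh)
        rng = np.random.default_rng(base.seed)
        buildings = assign_status(catchment.buildings, base, rng)
        for p_min in patient_minutes:
            for np_min in nonpatient_minutes:
                cfg = base.with_overrides(
                    visit_min_occupied=float(p_min),
                    visit_min_unoccupied=float(np_min))
                targets = visit_targets(buildings, cfg)
                inst = fold_service_times(matrix, targets,
                                          horizon_min=cfg.workday_min)
                fleet = size_fleet(inst, rng=cfg.seed % _SOLVER_SEED_MOD)
                for freq in frequencies:
                    req = monthly_requirement(
                        fleet.person_days,
                        cfg.with_overrides(visits_per_month=int(freq)),
                        _warn=False)
                    rows.append({
                        "catchment_id": cid,
                        "patient_min": p_min,
                        "nonpatient_min": np_min,
                        "visits_per_month": freq,
                        "person_days": fleet.person_days,
                        "monthly_person_days": req.monthly_person_days,
                        "chw_count": req.chw_count,
                    })
    return pd.DataFrame(rows)


def occupancy_resampling(
    catchments: dict,
    config: ScenarioConfig,
    n_resamples: int,
    master_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Robustness of person-day estimates to the occupancy randomization.

    Re-draws which buildings are occupied ``n_resamples`` times (seed of
    resample i = master_seed + i; master defaults to the config seed, so
    resample 0 reproduces the initial estimate exactly) and re-plans
    every catchment.  Returns a per-(resample, catchment) table of
    person-days and differences vs the initial estimate, and a
    per-resample aggregate table of district totals.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if master_seed is None:
        master_seed = config.seed
    matrices = {
        cid: travel_time_matrix(c, config.speed_kmh)
        for cid, c in catchments.items()
    }
    initial = {
        cid: plan_catchment(c, config, catchment_id=cid, matrix=matrices[cid])
        for cid, c in catchments.items()
    }
    rows = []
    for i in range(n_resamples):
        cfg = config.with_overrides(seed=master_seed + i)
        for cid, c in catchments.items():
            p = plan_catchment(c, cfg, catchment_id=cid, matrix=matrices[cid])
            rows.append({
                "resample": i,
                "seed": cfg.seed,
                "catchment_id": cid,
                "person_days": p.person_days,
                "initial_person_days": initial[cid].person_days,
                "diff_person_days": p.person_days - initial[cid].person_days,
            })
    per_catchment = pd.DataFrame(rows)
    agg = (
        per_catchment.groupby("resample", as_index=False)
        .agg(total_person_days=("person_days", "sum"),
             total_abs_diff=("diff_person_days", lambda s: s.abs().sum()))
    )
    agg["initial_total"] = sum(p.person_days for p in initial.values())
    agg["diff_total"] = agg["total_person_days"] - agg["initial_total"]
    return per_catchment, agg
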