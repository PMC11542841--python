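"""Intervention scenarios: household statuses, service times, visit targets.

A scenario fixes the workday (8 h), the workdays per month (20), the
walking speed (5 km/h), the fraction of buildings that are occupied
households (40%), the fraction of occupied households with a patient
(20%), and per-status visit durations (30 min long, 5 min short).  Two
intervention types are built in:

* ``mass_distribution`` — every building is visited, occupied or not;
  occupied households take the long visit, other buildings the short one.
* ``proccm`` — proactive community case management: only occupied
  households are visited; those with a patient take the long visit.

Statuses are assigned by exact-count sampling without replacement, so a
fixed configuration always produces the same *number* of occupied and
patient households, with no spatial correlation by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Building",
    "ScenarioConfig",
    "assign_status",
    "visit_targets",
    "round_half_up",
]

UNOCCUPIED = "unoccupied"
OCCUPIED_NO_PATIENT = "occupied_no_patient"
OCCUPIED_PATIENT = "occupied_patient"

_STATUSES = (UNOCCUPIED, OCCUPIED_NO_PATIENT, OCCUPIED_PATIENT)

_INTERVENTIONS = ("mass_distribution", "proccm", "custom")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass
class Building:
    """A point to visit, with an occupancy status and a service time."""

    id: int
    coordinates: tuple[float, float]
    status: str | None = None
    service_min: float | None = None

    def __post_init__(self) -> None:
        if self.status is not None and self.status not in _STATUSES:
            raise ValueError(f"unknown building status: {self.status!r}")

    @property
    def occupied(self) -> bool:
        return self.status in (OCCUPIED_NO_PATIENT, OCCUPIED_PATIENT)


@dataclass
class ScenarioConfig:
    """All scenario parameters plus the RNG seed; fully determines a run.

    ``visit_min_occupied`` is the long visit (occupied households in a
    mass campaign, patient households in proCCM); ``visit_min_unoccupied``
    is the short one (unoccupied buildings, resp. non-patient households).
    """

    intervention: str = "mass_distribution"
    occupied_fraction: float = 0.40
    patient_fraction: float = 0.20
    visit_min_occupied: float = 30.0
    visit_min_unoccupied: float = 5.0
    visits_per_month: int = 1
    workday_min: float = 480.0
    workdays_per_month: int = 20
    speed_kmh: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intervention not in _INTERVENTIONS:
            raise ValueError(f"unknown intervention: {self.intervention!r}")
        for name in ("occupied_fraction", "patient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("visit_min_occupied", "visit_min_unoccupied", "workday_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.workdays_per_month < 1:
            raise ValueError("workdays_per_month must be >= 1")
        if not self.speed_kmh > 0:
            raise ValueError("speed_kmh must be positive")

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        """Read a YAML (or JSON, a YAML subset) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def assign_status(
    buildings: Sequence[Building],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[Building]:
    """Assign occupancy/patient statuses by exact-count uniform sampling.

    Exactly ``round(occupied_fraction * n)`` buildings become occupied
    (round half up), chosen uniformly without replacement; of those,
    exactly ``round(patient_fraction * n_occupied)`` get a patient.
    Deterministic for a fixed seed, with no spatial correlation.
    """
    if not buildings:
        raise ValueError("no buildings to assign statuses to")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(buildings)
    ids = sorted(b.id for b in buildings)
    n_occ = round_half_up(config.occupied_fraction * n)
    occupied = set(rng.choice(ids, size=n_occ, replace=False).tolist()) if n_occ else set()
    occ_ids = sorted(occupied)
    n_pat = round_half_up(config.patient_fraction * n_occ)
    patients = set(rng.choice(occ_ids, size=n_pat, replace=False).tolist()) if n_pat else set()
    out = []
    for b in sorted(buildings, key=lambda b: b.id):
        if b.id in patients:
            status = OCCUPIED_PATIENT
        elif b.id in occupied:
            status = OCCUPIED_NO_PATIENT
        else:
            status = UNOCCUPIED
        out.append(replace(b, status=status, service_min=None))
    return out


def visit_targets(
    buildings: Sequence[Building],
    config: ScenarioConfig,
    custom_ids: Iterable[int] | None = None,
    custom_service_min: Mapping[int, float] | float | None = None,
) -> list[Building]:
    """Select the buildings to visit and attach per-status service times.

    mass_distribution: all buildings; occupied households take the long
    visit, other buildings the short one.  proccm: occupied households
    only; patient households take the long visit.  custom: the caller
    supplies the subset (and optionally times).  Targets come back in
    ascending id order.
    """
    long_min = config.visit_min_occupied
    short_min = config.visit_min_unoccupied
    by_id = {b.id: b for b in buildings}

    if config.intervention == "custom":
        if custom_ids is None:
            raise ValueError("custom intervention requires an explicit target subset")
        chosen = sorted(set(custom_ids))
        if not chosen:
            raise ValueError("custom target subset is empty")
        missing = [i for i in chosen if i not in by_id]
        if missing:
            raise KeyError(f"custom targets not in catchment: {missing}")
        out = []
        for i in chosen:
            if custom_service_min is None:
                svc = long_min
            elif isinstance(custom_service_min, Mapping):
                svc = float(custom_service_min[i])
            else:
                svc = float(custom_service_min)
            out.append(replace(by_id[i], service_min=svc))
        return out

    for b in buildings:
        if b.status is None:
            raise ValueError(f"building {b.id} has no status; run assign_status first")

    out = []
    for b in sorted(buildings, key=lambda b: b.id):
        if config.intervention == "mass_distribution":
            svc = long_min if b.occupied else short_min
            out.append(replace(b, service_min=svc))
        else:  # proccm
            if not b.occupied:
                continue
            svc = long_min if b.status == OCCUPIED_PATIENT else short_min
            out.append(replace(b, service_min=svc))
    return out
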