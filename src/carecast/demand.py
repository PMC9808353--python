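"""Nursing-staff demand via the population-ratio method.

Demand per state is simply ``population x staff-per-elder ratio``. Two
default schedules bracket typical institutional staffing standards; both
are configuration, not model output, and can be replaced from a JSON/YAML
file. Reported figures are in millions; the default policy rounds each
state's demand to two decimals before summing, which is how the published
totals were assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CarecastError, ConfigurationError
from .states import HealthState, LIVING_LABELS

__all__ = [
    "StaffingSchedule",
    "DemandForecast",
    "demand_by_state",
    "total_demand",
    "DEFAULT_SCHEDULES",
]


@dataclass(frozen=True)
class StaffingSchedule:
    """Staff-per-elder ratios for each living state.

    Ratios are dimensionless (1 staff per k elders => ratio 1/k), must be
    strictly positive and must not decrease with disability severity.
    """

    name: str
    ratios: dict[str, float]

    def __post_init__(self) -> None:
        missing = [s for s in LIVING_LABELS if s not in self.ratios]
        if missing:
            raise ConfigurationError(
                f"schedule {self.name!r} is missing ratios for {missing}"
            )
        ordered = [float(self.ratios[s]) for s in LIVING_LABELS]
        if any(r <= 0 or r > 1 for r in ordered):
            raise ConfigurationError(
                f"schedule {self.name!r}: ratios must lie in (0, 1]"
            )
        if any(b < a - 1e-12 for a, b in zip(ordered, ordered[1:])):
            raise ConfigurationError(
                f"schedule {self.name!r}: ratios must not decrease with severity"
            )

    def ratio_vector(self) -> np.ndarray:
        return np.array([self.ratios[s] for s in LIVING_LABELS], dtype=float)


#: Low standard: 1 staff per 10/8/6/4 elders; high: 1 per 5/4/2.5/1.5.
DEFAULT_SCHEDULES: dict[str, StaffingSchedule] = {
    "low": StaffingSchedule(
        "low",
        {"HEALTHY": 1 / 10, "MILD": 1 / 8, "MODERATE": 1 / 6, "SEVERE": 1 / 4},
    ),
    "high": StaffingSchedule(
        "high",
        {"HEALTHY": 1 / 5, "MILD": 1 / 4, "MODERATE": 1 / 2.5, "SEVERE": 1 / 1.5},
    ),
}


@dataclass
class DemandForecast:
    """Per-state staff demand in persons, plus the schedule that produced it."""

    schedule: StaffingSchedule
    populations: dict[str, float]  # persons per living state
    demand: dict[str, float] = field(init=False)  # persons, unrounded

    def __post_init__(self) -> None:
        self.demand = {
            s: self.populations[s] * self.schedule.ratios[s] for s in LIVING_LABELS
        }

    def demand_millions(self, ndigits: int = 2) -> dict[str, float]:
        return {s: round(d / 1e6, ndigits) for s, d in self.demand.items()}


def demand_by_state(
    populations: dict[str, float] | dict[HealthState, float] | np.ndarray,
    schedule: StaffingSchedule,
) -> DemandForecast:
    """Apply a staffing schedule to per-state population totals (persons)."""
    if isinstance(populations, dict):
        pops = {
            (k.name if isinstance(k, HealthState) else str(k).upper()): float(v)
            for k, v in populations.items()
        }
    else:
        arr = np.asarray(populations, dtype=float)
        if arr.shape != (len(LIVING_LABELS),):
            raise CarecastError(
                f"expected one population per living state, got shape {arr.shape}"
            )
        pops = dict(zip(LIVING_LABELS, arr.tolist()))
    missing = [s for s in LIVING_LABELS if s not in pops]
    if missing:
        raise ConfigurationError(f"missing populations for states {missing}")
    if any(v < 0 for v in pops.values()):
        raise CarecastError("populations must be non-negative")
    return DemandForecast(schedule=schedule, populations=pops)


def total_demand(
    forecast: DemandForecast,
    policy: str = "round-then-sum",
    ndigits: int = 2,
) -> float:
    """Total demand in millions under a stated rounding policy.

    ``round-then-sum`` rounds each state's demand to ``ndigits`` decimals
    in millions first (this reproduces published table totals);
    ``sum-then-round`` rounds the full-precision sum last. The two differ
    by at most 4 x half an ulp of the rounding grid.
    """
    if policy == "round-then-sum":
        return round(sum(forecast.demand_millions(ndigits).values()), ndigits)
    if policy == "sum-then-round":
        return round(sum(forecast.demand.values()) / 1e6, ndigits)
    raise CarecastError(f"unknown rounding policy {policy!r}")
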