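"""Goodness-of-fit validation and projection uncertainty.

Three tools:

* a chi-square test comparing an observed categorical distribution with
  the distribution a projection predicts;
* scenario bounds from pushing every transition probability to a
  confidence limit (deterioration entries one way, recovery/survival
  entries the other) with proportional row renormalization — labelled a
  scenario bound, not a calibrated interval, because the directional
  perturbation is deliberately extreme;
* a Monte Carlo interval from row-wise Dirichlet(counts + 1) posterior
  resampling of the transition matrix, the conjugate update for
  row-multinomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import CarecastError, EstimationError
from .estimation import (
    IntervalMatrixSet,
    TransitionCounts,
    empirical_matrix,
)
from .matrices import N_STATES, TransitionMatrixSet, absorbing_death_row
from .projection import project, totals_by_state
from .states import HealthState, LIVING_LABELS
from .synthetic import PopulationTable
from .demand import StaffingSchedule, demand_by_state

__all__ = [
    "FitTestResult",
    "PredictionInterval",
    "chi_square_fit",
    "perturb_matrices",
    "perturbation_interval",
    "monte_carlo_interval",
]

N_LIVING = len(LIVING_LABELS)


@dataclass
class FitTestResult:
    """Chi-square goodness-of-fit summary."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    categories: tuple[str, ...]

    @property
    def rejects(self) -> bool:
        return self.p_value < 0.05


def chi_square_fit(
    observed,
    expected,
    categories: tuple[str, ...] | None = None,
) -> FitTestResult:
    """Chi-square test of observed counts against expected proportions.

    ``expected`` may be counts or proportions on any scale; it is rescaled
    to the observed total, so the test is invariant to uniform scaling.
    ``df = k - 1``.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise CarecastError("observed and expected must be 1-d and the same length")
    if (exp <= 0).any():
        raise EstimationError(
            "expected count of zero; pool that category with a neighbour "
            "before testing"
        )
    total = obs.sum()
    if total <= 0:
        raise CarecastError("observed total must be positive")
    exp = exp * (total / exp.sum())
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(scipy.stats.chi2.sf(statistic, df))
    return FitTestResult(
        statistic=statistic,
        df=df,
        p_value=p,
        observed=obs,
        expected=exp,
        categories=categories or tuple(f"cat{i}" for i in range(obs.size)),
    )


@dataclass
class PredictionInterval:
    """Bounds around a projected quantity (population or staff demand)."""

    point: float
    lower: float
    upper: float
    method: str
    level: float
    units: str = "persons"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise CarecastError(
                "prediction interval must satisfy lower <= point <= upper "
                f"(got {self.lower}, {self.point}, {self.upper})"
            )


def _quantity(
    baseline: PopulationTable,
    matrices: TransitionMatrixSet,
    n_steps: int,
    step_years: float,
    age_threshold: float,
    schedule: StaffingSchedule | None,
) -> float:
    """Projected total living population, or total staff demand if a
    schedule is given. Persons, unrounded."""
    result = project(
        baseline, matrices, n_steps, step_years=step_years, age_threshold=age_threshold
    )
    totals = totals_by_state(result)
    if schedule is None:
        return float(sum(totals.values()))
    return float(sum(demand_by_state(totals, schedule).demand.values()))


def perturb_matrices(
    limits: IntervalMatrixSet, direction: str
) -> TransitionMatrixSet:
    """Push every living-row probability to a confidence limit.

    ``direction='pessimistic'`` sets deterioration entries (any move to a
    worse state, death included) to their upper limits and same-or-better
    entries to their lower limits; ``'optimistic'`` is the reverse. Each
    living row is then rescaled proportionally to sum to one.
    """
    if direction not in ("pessimistic", "optimistic"):
        raise CarecastError("direction must be 'pessimistic' or 'optimistic'")
    lower = limits.lower.probs
    upper = limits.upper.probs
    worse = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i in range(N_LIVING):
        worse[i, i + 1 :] = True
    pick_upper = worse if direction == "pessimistic" else ~worse
    probs = np.where(pick_upper, upper, lower)
    sums = probs[:, :N_LIVING, :].sum(axis=2)
    if (sums <= 0).any():
        raise CarecastError(
            "perturbed row has zero total mass; cannot renormalize"
        )
    probs[:, :N_LIVING, :] /= sums[:, :, None]
    probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
    out = TransitionMatrixSet(probs, age_groups=limits.point.age_groups)
    out.validate(atol=1e-9)
    return out


def perturbation_interval(
    baseline: PopulationTable,
    limits: IntervalMatrixSet,
    n_steps: int,
    step_years: float = 3.0,
    age_threshold: float = 80.0,
    schedule: StaffingSchedule | None = None,
) -> PredictionInterval:
    """Scenario bounds from projecting the two directional perturbations.

    The pessimistic matrix gives the lower living-population (or demand)
    bound, the optimistic matrix the upper; the point comes from the
    unperturbed point-estimate matrices (renormalized for safety).
    """
    args = (n_steps, step_years, age_threshold, schedule)
    point = _quantity(baseline, limits.point.normalized(), *args)
    lo = _quantity(baseline, perturb_matrices(limits, "pessimistic"), *args)
    hi = _quantity(baseline, perturb_matrices(limits, "optimistic"), *args)
    lo, hi = min(lo, hi), max(lo, hi)
    return PredictionInterval(
        point=point,
        lower=min(lo, point),
        upper=max(hi, point),
        method="bound-perturbation",
        level=limits.level,
        units="persons" if schedule is None else "staff",
    )


def monte_carlo_interval(
    counts: TransitionCounts,
    baseline: PopulationTable,
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
    n_steps: int = 5,
    step_years: float = 3.0,
    age_threshold: float = 80.0,
    schedule: StaffingSchedule | None = None,
) -> PredictionInterval:
    """Percentile interval from Dirichlet(counts + 1) matrix resampling.

    Each replicate draws every living row of every age band from its
    posterior, projects the baseline, and records the total quantity.
    """
    if B < 100:
        raise CarecastError("monte_carlo_interval requires B >= 100")
    if not 0 < level < 1:
        raise CarecastError("confidence level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_bands = counts.n.shape[0]

    draws = np.empty(B)
    probs = np.zeros((n_bands, N_STATES, N_STATES))
    probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
    for b in range(B):
        for a in range(n_bands):
            for i in range(N_LIVING):
                probs[a, i] = rng.dirichlet(counts.n[a, i] + 1.0)
        mset = TransitionMatrixSet(probs.copy(), age_groups=counts.age_groups)
        draws[b] = _quantity(
            baseline, mset, n_steps, step_years, age_threshold, schedule
        )

    point_matrices = empirical_matrix(counts, smoothing=0.5).normalized()
    point = _quantity(
        baseline, point_matrices, n_steps, step_years, age_threshold, schedule
    )
    lo, hi = np.quantile(draws, [(1 - level) / 2, 0.5 + level / 2])
    return PredictionInterval(
        point=point,
        lower=min(float(lo), point),
        upper=max(float(hi), point),
        method="monte-carlo",
        level=level,
        units="persons" if schedule is None else "staff",
    )
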