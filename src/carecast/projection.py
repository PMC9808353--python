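"""Discrete-step Markov projection of a baseline population.

Every (age band, living state) cell of the baseline becomes a cohort that
carries its band midpoint age. At each step the cohort's five-state mass
vector is multiplied by the transition matrix of the band containing its
current age, and the age advances by the step length. Matrices are applied
as per-step probabilities (no annualization), populations are real-valued
masses rounded only at reporting, and transition probabilities are assumed
stationary over the projection horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CarecastError, ConfigurationError
from .matrices import N_STATES, TransitionMatrixSet
from .states import (
    AgeGroup,
    HealthState,
    LIVING_LABELS,
    STATE_LABELS,
)
from .synthetic import PopulationTable

__all__ = [
    "CohortTrajectory",
    "ProjectionResult",
    "advance_step",
    "project",
    "totals_by_state",
]

N_LIVING = len(LIVING_LABELS)
DEATH = HealthState.DEATH.index


def advance_step(
    state_vector: np.ndarray,
    matrices: TransitionMatrixSet,
    current_age: float,
) -> np.ndarray:
    """One Markov step: ``state_vector @ M(band(current_age))``.

    Ages at or past the open band's lower bound use the open-band matrix;
    ages below the youngest band raise a :class:`ConfigurationError`.
    """
    vec = np.asarray(state_vector, dtype=float)
    if vec.shape != (N_STATES,):
        raise CarecastError(f"state vector must have {N_STATES} entries")
    if (vec < 0).any():
        raise CarecastError("state vector must be non-negative")
    return vec @ matrices.matrix_for_age(current_age)


@dataclass
class CohortTrajectory:
    """Evolution of one baseline cell through the projection steps."""

    origin_age_group: AgeGroup
    origin_state: HealthState
    initial_count: float
    #: step-indexed history; ``states[0]`` is the baseline vector
    states: np.ndarray  # (n_steps + 1, 5)
    ages: np.ndarray  # (n_steps + 1,) midpoint age at each step

    @property
    def final_states(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_age(self) -> float:
        return float(self.ages[-1])


@dataclass
class ProjectionResult:
    """All cohort trajectories plus the target-year aggregate."""

    trajectories: list[CohortTrajectory]
    target_table: PopulationTable
    death_total: float
    baseline_total: float
    target_year: int
    age_threshold: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format endpoint table: one row per (origin cell, target state)."""
        rows = []
        for traj in self.trajectories:
            for j, label in enumerate(STATE_LABELS):
                rows.append(
                    {
                        "origin_age_group": traj.origin_age_group.label,
                        "origin_state": traj.origin_state.name,
                        "target_state": label,
                        "persons": traj.final_states[j],
                    }
                )
        return pd.DataFrame(rows)


def project(
    baseline: PopulationTable,
    matrices: TransitionMatrixSet,
    n_steps: int,
    step_years: float = 3.0,
    age_threshold: float = 80.0,
) -> ProjectionResult:
    """Advance every baseline cohort ``n_steps`` steps.

    The target table aggregates living-state masses of cohorts whose final
    midpoint age is at least ``age_threshold`` (default 80: a 2010 baseline
    of 65+ cohorts projected five 3-year steps is entirely 80+ in 2025).
    Rows of the target table are indexed by the cohort's *origin* age band.
    """
    if n_steps < 1:
        raise CarecastError("n_steps must be >= 1")
    if step_years <= 0:
        raise CarecastError("step_years must be positive")
    if len(matrices.age_groups) != len(baseline.age_groups) or any(
        m.label != b.label for m, b in zip(matrices.age_groups, baseline.age_groups)
    ):
        raise ConfigurationError(
            "transition matrices do not cover the baseline's age bands"
        )

    trajectories: list[CohortTrajectory] = []
    target_counts = np.zeros_like(baseline.counts)
    death_total = 0.0
    for a, group in enumerate(baseline.age_groups):
        for i, state in enumerate(HealthState):
            if not state.is_living:
                continue
            count = float(baseline.counts[a, i])
            states = np.zeros((n_steps + 1, N_STATES))
            states[0, i] = count
            ages = group.midpoint + step_years * np.arange(n_steps + 1)
            for step in range(n_steps):
                states[step + 1] = advance_step(
                    states[step], matrices, float(ages[step])
                )
            traj = CohortTrajectory(
                origin_age_group=group,
                origin_state=state,
                initial_count=count,
                states=states,
                ages=ages,
            )
            trajectories.append(traj)
            death_total += traj.final_states[DEATH]
            if traj.final_age >= age_threshold:
                target_counts[a] += traj.final_states[:N_LIVING]

    target_year = int(round(baseline.year + n_steps * step_years))
    return ProjectionResult(
        trajectories=trajectories,
        target_table=PopulationTable(
            target_counts, age_groups=baseline.age_groups, year=target_year
        ),
        death_total=death_total,
        baseline_total=baseline.total(),
        target_year=target_year,
        age_threshold=age_threshold,
    )


def totals_by_state(result: ProjectionResult) -> dict[str, float]:
    """Target-year persons per living state, summed over cohorts."""
    totals = result.target_table.state_totals()
    return dict(zip(LIVING_LABELS, totals.tolist()))
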