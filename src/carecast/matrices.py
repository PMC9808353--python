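"""Row-stochastic transition-matrix container.

A :class:`TransitionMatrixSet` holds one 5x5 matrix per age band. Rows are
the state at the start of a step, columns the state one step (default three
years) later. Every valid set satisfies:

* entries in [0, 1],
* rows summing to one,
* an absorbing death row ``(0, 0, 0, 0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IntegrityError
from .states import (
    AgeGroup,
    HealthState,
    STATE_LABELS,
    default_age_groups,
    group_index_for_age,
)

__all__ = ["TransitionMatrixSet", "absorbing_death_row", "N_STATES"]

N_STATES = len(STATE_LABELS)


def absorbing_death_row() -> np.ndarray:
    row = np.zeros(N_STATES)
    row[HealthState.DEATH.index] = 1.0
    return row


@dataclass
class TransitionMatrixSet:
    """Per-age-band 5x5 transition probabilities.

    Parameters
    ----------
    probs : ndarray of shape (n_bands, 5, 5)
        ``probs[a, i, j]`` is the probability of moving from state ``i+1``
        to state ``j+1`` over one step for age band ``a``.
    age_groups : tuple of AgeGroup
        Band definitions aligned with the first axis of ``probs``.
    step_years : float
        Length of one step; matrices estimated from a 2008->2011 panel use
        the default of 3 years.
    """

    probs: np.ndarray
    age_groups: tuple[AgeGroup, ...] = field(default_factory=default_age_groups)
    step_years: float = 3.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.age_groups), N_STATES, N_STATES):
            raise IntegrityError(
                f"expected probs of shape {(len(self.age_groups), N_STATES, N_STATES)},"
                f" got {self.probs.shape}"
            )

    @property
    def age_labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.age_groups)

    def validate(self, atol: float = 1e-9) -> None:
        """Raise :class:`IntegrityError` naming the first offending row."""
        death = HealthState.DEATH.index
        for a, group in enumerate(self.age_groups):
            mat = self.probs[a]
            if (mat < -atol).any() or (mat > 1 + atol).any():
                raise IntegrityError(
                    f"entry outside [0, 1] in age band {group.label}"
                )
            sums = mat.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > atol)
            if bad.size:
                i = int(bad[0])
                raise IntegrityError(
                    f"row ({STATE_LABELS[i]}, {group.label}) sums to "
                    f"{sums[i]:.6f}, deviating from 1 by more than {atol:g}"
                )
            if not np.allclose(mat[death], absorbing_death_row(), atol=atol):
                raise IntegrityError(
                    f"death row of age band {group.label} is not absorbing"
                )

    def normalized(self) -> "TransitionMatrixSet":
        """Return a copy with every row rescaled to sum exactly to one.

        Used to repair rounding in tabulated fixtures before the matrices
        are fed to samplers or long projections that assume exact
        stochasticity.
        """
        probs = self.probs.copy()
        probs /= probs.sum(axis=2, keepdims=True)
        probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
        return replace(self, probs=probs)

    def copy(self) -> "TransitionMatrixSet":
        return replace(self, probs=self.probs.copy())

    def matrix_for_age(self, age: float) -> np.ndarray:
        """The matrix of the band containing ``age`` (85+ past the bands)."""
        return self.probs[group_index_for_age(age, self.age_groups)]

    def row(self, age_label: str, state: HealthState) -> np.ndarray:
        a = self.age_labels.index(age_label)
        return self.probs[a, state.index]
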