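"""Synthetic two-wave panels and census baselines.

Generators producing data with the statistical structure the estimation
and projection stages assume: individual follow-up states are independent
multinomial draws from the transition row of the individual's (age band,
baseline state) cell, and census tables spread state totals over age bands
with exact integer conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CarecastError, IntegrityError
from .matrices import TransitionMatrixSet
from .states import (
    AGE_LABELS,
    AgeGroup,
    HealthState,
    LIVING_LABELS,
    STATE_LABELS,
    default_age_groups,
)

__all__ = [
    "PanelDataset",
    "PopulationTable",
    "simulate_panel",
    "simulate_census",
    "default_cohort_sizes",
    "marginal_panel",
]

PANEL_COLUMNS = ("id", "age_group", "state_baseline", "state_followup")


@dataclass
class PanelDataset:
    """Individual two-wave records.

    ``records`` has columns ``id``, ``age_group``, ``state_baseline``,
    ``state_followup`` (labels), plus optional extra columns such as
    ``sex``. Baseline states are living states only; follow-up may be any
    of the five states. ``wave_gap_years`` is the time between waves.
    """

    records: pd.DataFrame
    wave_gap_years: float = 3.0

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.records.columns]
        if missing:
            raise IntegrityError(f"panel is missing columns {missing}")
        if self.wave_gap_years <= 0:
            raise IntegrityError("wave gap must be positive")
        if len(self.records):
            if self.records["id"].duplicated().any():
                raise IntegrityError("panel ids are not unique")
            if (self.records["state_baseline"] == HealthState.DEATH.name).any():
                raise IntegrityError("baseline state DEATH is not allowed")
            bad = set(self.records["state_baseline"]) - set(LIVING_LABELS)
            bad |= set(self.records["state_followup"]) - set(STATE_LABELS)
            bad |= set(self.records["age_group"]) - set(AGE_LABELS)
            if bad:
                raise IntegrityError(f"unknown labels in panel: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PopulationTable:
    """Person counts by (age band, living state) at a reference year."""

    counts: np.ndarray  # (n_bands, 4), living states only
    age_groups: tuple[AgeGroup, ...] = field(default_factory=default_age_groups)
    year: int = 2010

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.age_groups), len(LIVING_LABELS)):
            raise IntegrityError(
                f"expected counts of shape {(len(self.age_groups), len(LIVING_LABELS))},"
                f" got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise IntegrityError("population counts must be non-negative")

    def state_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "age_group": g.label,
                "state": s,
                "count": self.counts[a, j],
                "year": self.year,
            }
            for a, g in enumerate(self.age_groups)
            for j, s in enumerate(LIVING_LABELS)
        ]
        return pd.DataFrame(rows)


def simulate_panel(
    matrices: TransitionMatrixSet,
    cohort_sizes: np.ndarray | dict[tuple[str, str], int],
    seed: int | np.random.Generator,
) -> PanelDataset:
    """Draw a synthetic two-wave panel from a transition-matrix set.

    Each individual in cell (age band ``a``, baseline state ``i``) gets a
    follow-up state drawn independently from row ``i`` of the band-``a``
    matrix. ``cohort_sizes`` is either an ``(n_bands, 4)`` integer array or
    a ``{(age_label, state_label): n}`` mapping; missing cells are empty.
    """
    rng = np.random.default_rng(seed)
    n_bands = len(matrices.age_groups)
    if isinstance(cohort_sizes, dict):
        sizes = np.zeros((n_bands, len(LIVING_LABELS)), dtype=int)
        for (age_label, state_label), n in cohort_sizes.items():
            a = matrices.age_labels.index(age_label)
            i = HealthState.from_label(state_label).index
            sizes[a, i] = n
    else:
        sizes = np.asarray(cohort_sizes, dtype=int)
        if sizes.shape != (n_bands, len(LIVING_LABELS)):
            raise CarecastError(
                f"cohort_sizes must have shape {(n_bands, len(LIVING_LABELS))}"
            )
    if (sizes < 0).any():
        raise CarecastError("cohort sizes must be non-negative")

    probs = matrices.normalized().probs
    age_col: list[str] = []
    base_col: list[str] = []
    follow_col: list[str] = []
    for a, group in enumerate(matrices.age_groups):
        for i, state_label in enumerate(LIVING_LABELS):
            n = int(sizes[a, i])
            if n == 0:
                continue
            outcome_counts = rng.multinomial(n, probs[a, i])
            age_col.extend([group.label] * n)
            base_col.extend([state_label] * n)
            follow_col.extend(np.repeat(STATE_LABELS, outcome_counts))
    records = pd.DataFrame(
        {
            "id": np.arange(1, len(age_col) + 1),
            "age_group": age_col,
            "state_baseline": base_col,
            "state_followup": follow_col,
        }
    )
    return PanelDataset(records, wave_gap_years=matrices.step_years)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` over ``weights`` (summing to 1) as integers."""
    raw = total * weights
    base = np.floor(raw).astype(np.int64)
    short = int(round(total - base.sum()))
    if short:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_census(
    state_totals: dict[HealthState, int] | np.ndarray,
    age_weights: np.ndarray | dict[str, float],
    year: int = 2010,
    age_groups: tuple[AgeGroup, ...] | None = None,
) -> PopulationTable:
    """Spread per-state totals over age bands, conserving totals exactly.

    Cell ``(a, s)`` is ``state_total(s) * age_weight(a)`` rounded with
    largest-remainder correction, so each state column sums exactly to its
    input total.
    """
    groups = age_groups or default_age_groups()
    if isinstance(age_weights, dict):
        weights = np.array([age_weights[g.label] for g in groups], dtype=float)
    else:
        weights = np.asarray(age_weights, dtype=float)
    if weights.shape != (len(groups),):
        raise CarecastError(f"need one age weight per band, got {weights.shape}")
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise CarecastError("age weights must be non-negative and sum to 1")
    if isinstance(state_totals, dict):
        totals = np.array(
            [state_totals[s] for s in HealthState if s.is_living], dtype=float
        )
    else:
        totals = np.asarray(state_totals, dtype=float)
    if (totals < 0).any():
        raise CarecastError("state totals must be non-negative")

    counts = np.column_stack(
        [_largest_remainder(int(round(t)), weights) for t in totals]
    )
    return PopulationTable(counts, age_groups=groups, year=year)


def default_cohort_sizes(
    marginals: dict[str, dict[str, int]] | None = None,
) -> np.ndarray:
    """An (age band x baseline state) cohort-size grid matching the
    reference panel marginals (n = 13,269; baseline split about
    78.4/11.0/5.2/5.4%), apportioned under independence with
    largest-remainder rounding."""
    from .reference import PANEL_MARGINALS

    marg = marginals or PANEL_MARGINALS
    age = np.array([marg["age_group"][lab] for lab in AGE_LABELS], dtype=float)
    state = np.array([marg["state_baseline"][lab] for lab in LIVING_LABELS], dtype=float)
    total = int(age.sum())
    weights = np.outer(age / age.sum(), state / state.sum()).ravel()
    return _largest_remainder(total, weights / weights.sum()).reshape(
        len(AGE_LABELS), len(LIVING_LABELS)
    )


def marginal_panel(
    marginals: dict[str, dict[str, int]] | None = None,
    seed: int | np.random.Generator = 0,
    wave_gap_years: float = 3.0,
) -> PanelDataset:
    """A panel whose column marginals equal the given counts exactly.

    Each column (sex, age band, baseline state, follow-up state) is an
    independent seeded shuffle of a label vector with exactly the requested
    counts, so marginal summaries are reproduced to the person while the
    joint distribution is uninformative. Intended for descriptive-summary
    tests; use :func:`simulate_panel` when transition structure matters.
    """
    from .reference import PANEL_MARGINALS

    marg = marginals or PANEL_MARGINALS
    rng = np.random.default_rng(seed)
    n = sum(marg["state_baseline"].values())

    def column(counts: dict[str, int]) -> np.ndarray:
        if sum(counts.values()) != n:
            raise CarecastError(
                f"marginal counts sum to {sum(counts.values())}, expected {n}"
            )
        labels = np.repeat(list(counts), list(counts.values()))
        return rng.permutation(labels)

    data = {
        "id": np.arange(1, n + 1),
        "age_group": column(marg["age_group"]),
        "state_baseline": column(marg["state_baseline"]),
        "state_followup": column(marg["state_followup"]),
    }
    if "sex" in marg:
        data["sex"] = column(marg["sex"])
    return PanelDataset(pd.DataFrame(data), wave_gap_years=wave_gap_years)
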