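"""Transition-matrix estimation from a two-wave panel.

Two estimation routes are provided and kept deliberately independent so
each can check the other:

* the empirical (count) estimator, optionally add-alpha smoothed;
* a multinomial logit model fitted by maximum likelihood, with the
  healthy state as the reference outcome. With the ``saturated`` design
  (one parameter per (age band, baseline state) cell) its predicted
  probabilities coincide with the empirical proportions; the ``additive``
  design (age and state main effects only) yields a smoothed matrix.

Pointwise confidence limits for each probability come from either the
binomial Wald approximation or a row-wise multinomial bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from .errors import CarecastError, EstimationError
from .matrices import N_STATES, TransitionMatrixSet, absorbing_death_row
from .states import (
    AgeGroup,
    HealthState,
    LIVING_LABELS,
    STATE_LABELS,
    default_age_groups,
)
from .synthetic import PanelDataset

__all__ = [
    "TransitionCounts",
    "LogitCoefficients",
    "IntervalMatrixSet",
    "count_transitions",
    "empirical_matrix",
    "fit_multinomial_logit",
    "predict_matrix",
    "probability_limits",
]

N_LIVING = len(LIVING_LABELS)

#: Cells flagged as unstable: row total below this and a probability of
#: exactly 0 or 1.
SPARSE_ROW_THRESHOLD = 20

#: Cap applied to logit coefficients under (quasi-)complete separation.
COEF_CAP = 30.0


@dataclass
class TransitionCounts:
    """Integer flow counts ``n[a, i, j]`` from living state ``i`` to state
    ``j`` between waves, per age band ``a``."""

    n: np.ndarray  # (n_bands, 4, 5)
    age_groups: tuple[AgeGroup, ...] = field(default_factory=default_age_groups)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        expected = (len(self.age_groups), N_LIVING, N_STATES)
        if self.n.shape != expected:
            raise CarecastError(f"expected counts of shape {expected}, got {self.n.shape}")
        if (self.n < 0).any():
            raise CarecastError("transition counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.n.sum(axis=2)

    def total(self) -> int:
        return int(self.n.sum())


def count_transitions(
    panel: PanelDataset, age_groups: tuple[AgeGroup, ...] | None = None
) -> TransitionCounts:
    """Cross-tabulate a panel into (age band, from-state, to-state) counts."""
    groups = age_groups or default_age_groups()
    age_labels = [g.label for g in groups]
    n = np.zeros((len(groups), N_LIVING, N_STATES), dtype=np.int64)
    if len(panel):
        grouped = panel.records.groupby(
            ["age_group", "state_baseline", "state_followup"], observed=True
        ).size()
        for (age, base, follow), count in grouped.items():
            a = age_labels.index(age)
            i = HealthState.from_label(base).index
            j = HealthState.from_label(follow).index
            n[a, i, j] = count
    return TransitionCounts(n, age_groups=groups)


def empirical_matrix(
    counts: TransitionCounts, smoothing: float = 0.0
) -> TransitionMatrixSet:
    """Row-proportion estimator with optional add-alpha smoothing.

    ``P[a, i, j] = (n[a, i, j] + alpha) / (n[a, i, .] + 5 alpha)``; the
    death row is set absorbing. With ``smoothing=0`` every living row must
    have at least one observation.
    """
    if smoothing < 0:
        raise CarecastError("smoothing alpha must be >= 0")
    totals = counts.row_totals
    if smoothing == 0.0:
        empty = np.argwhere(totals == 0)
        if empty.size:
            a, i = empty[0]
            raise EstimationError(
                "no observations for cell "
                f"({counts.age_groups[a].label}, {LIVING_LABELS[i]}); "
                "use smoothing > 0 or merge cells"
            )
    probs = np.zeros((len(counts.age_groups), N_STATES, N_STATES))
    probs[:, :N_LIVING, :] = (counts.n + smoothing) / (
        totals + N_STATES * smoothing
    )[:, :, None]
    probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
    return TransitionMatrixSet(probs, age_groups=counts.age_groups)


def flag_sparse_cells(
    counts: TransitionCounts, threshold: int = SPARSE_ROW_THRESHOLD
) -> list[dict]:
    """Cells with a small row total and a degenerate (0 or 1) estimate.

    These are the rows whose raw proportions are least trustworthy; callers
    may re-estimate with ``smoothing=0.5``.
    """
    flags = []
    totals = counts.row_totals
    for a, group in enumerate(counts.age_groups):
        for i in range(N_LIVING):
            tot = totals[a, i]
            if tot == 0 or tot >= threshold:
                continue
            p = counts.n[a, i] / tot
            if ((p == 0.0) | (p == 1.0)).any():
                flags.append(
                    {
                        "age_group": group.label,
                        "from_state": LIVING_LABELS[i],
                        "row_total": int(tot),
                    }
                )
    return flags


# ---------------------------------------------------------------------------
# multinomial logit


@dataclass
class LogitCoefficients:
    """Fitted multinomial-logit coefficients with their design description.

    ``coef`` has one column per non-reference outcome (MILD, MODERATE,
    SEVERE, DEATH); the reference outcome (HEALTHY) has an implicit
    all-zero column. The design description makes predictions
    self-contained.
    """

    design: str
    coef: np.ndarray  # (n_features, 4)
    feature_names: tuple[str, ...]
    age_groups: tuple[AgeGroup, ...]
    log_likelihood: float
    converged: bool
    n_iter: int
    cap: float = COEF_CAP
    capped: bool = False


def _cell_design(design: str, age_groups: tuple[AgeGroup, ...]):
    """Design matrix over the (age band x baseline state) covariate cells.

    Rows are ordered age-major: (band 0, HEALTHY), (band 0, MILD), ...
    """
    n_bands = len(age_groups)
    cells = [(a, i) for a in range(n_bands) for i in range(N_LIVING)]
    if design == "saturated":
        X = np.eye(len(cells))
        names = tuple(
            f"cell[{age_groups[a].label}|{LIVING_LABELS[i]}]" for a, i in cells
        )
    elif design == "additive":
        cols = [np.ones(len(cells))]
        names_list = ["intercept"]
        for a in range(1, n_bands):
            cols.append(np.array([float(ca == a) for ca, _ in cells]))
            names_list.append(f"age[{age_groups[a].label}]")
        for i in range(1, N_LIVING):
            cols.append(np.array([float(ci == i) for _, ci in cells]))
            names_list.append(f"state[{LIVING_LABELS[i]}]")
        X = np.column_stack(cols)
        names = tuple(names_list)
    else:
        raise CarecastError(f"unknown design {design!r}; use 'saturated' or 'additive'")
    return X, names


def _cell_probs(X: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Outcome probabilities per covariate cell; reference outcome first."""
    utilities = np.zeros((X.shape[0], N_STATES))
    utilities[:, 1:] = X @ coef
    return scipy.special.softmax(utilities, axis=1)


def fit_multinomial_logit(
    panel: PanelDataset | TransitionCounts,
    design: str = "saturated",
    cap: float = COEF_CAP,
    maxiter: int = 5000,
) -> LogitCoefficients:
    """Maximum-likelihood multinomial logit for the follow-up state.

    Accepts a panel or pre-tabulated counts (the likelihood depends on the
    data only through the cell counts). The healthy outcome is the
    reference. Coefficients are bounded at ``|beta| <= cap``; hitting the
    bound (complete separation, e.g. an empty cell under the saturated
    design) produces a warning, not a failure.
    """
    counts = panel if isinstance(panel, TransitionCounts) else count_transitions(panel)
    if counts.total() == 0:
        raise EstimationError("cannot fit a logit model on an empty panel")
    observed_levels = (counts.n.sum(axis=(0, 1)) > 0).sum()
    if observed_levels < 2:
        raise EstimationError("follow-up outcome has fewer than 2 observed levels")

    X, names = _cell_design(design, counts.age_groups)
    n = counts.n.reshape(-1, N_STATES).astype(float)  # cells x outcomes
    n_features = X.shape[1]

    def nll_grad(theta: np.ndarray):
        coef = theta.reshape(n_features, N_STATES - 1)
        p = _cell_probs(X, coef)
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        ll = float(np.sum(np.where(n > 0, n * logp, 0.0)))
        resid = n.sum(axis=1, keepdims=True) * p - n  # cells x outcomes
        grad = X.T @ resid[:, 1:]
        return -ll, grad.ravel()

    bounds = [(-cap, cap)] * (n_features * (N_STATES - 1))
    options = {"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-10}
    res = scipy.optimize.minimize(
        nll_grad,
        np.zeros(n_features * (N_STATES - 1)),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options=options,
    )
    # warm restart: resets the relative-reduction stopping rule and squeezes
    # out the last digits, which the saturated/empirical equivalence needs
    polish = scipy.optimize.minimize(
        nll_grad, res.x, jac=True, method="L-BFGS-B", bounds=bounds, options=options
    )
    if polish.fun <= res.fun:
        polish.nit += res.nit
        res = polish
    coef = res.x.reshape(n_features, N_STATES - 1)
    capped = bool(np.any(np.abs(coef) >= cap - 1e-8))
    if capped:
        warnings.warn(
            "some logit coefficients hit the separation cap "
            f"(|beta| = {cap:g}); the affected probabilities are pinned "
            "near 0 or 1",
            stacklevel=2,
        )
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise EstimationError(
            f"logit fit did not converge within {maxiter} iterations: {res.message}"
        )
    return LogitCoefficients(
        design=design,
        coef=coef,
        feature_names=names,
        age_groups=counts.age_groups,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        cap=cap,
        capped=capped,
    )


def predict_matrix(coefficients: LogitCoefficients) -> TransitionMatrixSet:
    """Evaluate the fitted logit at every (age band, baseline state) cell.

    Rows sum to one by construction of the softmax; the death row is
    absorbing.
    """
    X, names = _cell_design(coefficients.design, coefficients.age_groups)
    if names != tuple(coefficients.feature_names) or X.shape[1] != coefficients.coef.shape[0]:
        raise CarecastError("coefficient block does not match its declared design")
    p = _cell_probs(X, coefficients.coef)
    n_bands = len(coefficients.age_groups)
    probs = np.zeros((n_bands, N_STATES, N_STATES))
    probs[:, :N_LIVING, :] = p.reshape(n_bands, N_LIVING, N_STATES)
    probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
    return TransitionMatrixSet(probs, age_groups=coefficients.age_groups)


# ---------------------------------------------------------------------------
# confidence limits


@dataclass
class IntervalMatrixSet:
    """Pointwise confidence limits around a transition-matrix estimate."""

    point: TransitionMatrixSet
    lower: TransitionMatrixSet
    upper: TransitionMatrixSet
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (
            (self.lower.probs <= self.point.probs + 1e-12).all()
            and (self.point.probs <= self.upper.probs + 1e-12).all()
        ):
            raise CarecastError("interval limits must satisfy lower <= point <= upper")


def probability_limits(
    counts: TransitionCounts,
    level: float = 0.95,
    method: str = "wald",
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> IntervalMatrixSet:
    """Pointwise confidence limits for every transition probability.

    ``wald``: binomial normal approximation ``p +/- z sqrt(p(1-p)/n)`` per
    cell, clipped to [0, 1]. Cells observed at exactly 0 or 1 get
    degenerate Wald limits — a known weakness of the approximation that
    the caller may prefer the bootstrap for. ``bootstrap``: percentile
    limits over ``B`` multinomial resamples of each row.

    Rows with no observations get uninformative limits (0, 1) and a
    warning.
    """
    if not 0 < level < 1:
        raise CarecastError("confidence level must be in (0, 1)")
    totals = counts.row_totals.astype(float)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty transition row(s); their limits are (0, 1)",
            stacklevel=2,
        )
    safe_totals = np.where(empty, 1.0, totals)
    p = counts.n / safe_totals[:, :, None]

    if method == "wald":
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(p * (1 - p) / safe_totals[:, :, None])
        lower = np.clip(p - z * se, 0.0, 1.0)
        upper = np.clip(p + z * se, 0.0, 1.0)
    elif method == "bootstrap":
        if B < 100:
            raise CarecastError("bootstrap requires B >= 100")
        rng = np.random.default_rng(seed)
        qs = [(1 - level) / 2, 0.5 + level / 2]
        lower = np.zeros_like(p)
        upper = np.zeros_like(p)
        for a in range(p.shape[0]):
            for i in range(p.shape[1]):
                tot = int(totals[a, i])
                if tot == 0:
                    lower[a, i], upper[a, i] = 0.0, 1.0
                    continue
                draws = rng.multinomial(tot, p[a, i], size=B) / tot
                lo, hi = np.quantile(draws, qs, axis=0)
                lower[a, i], upper[a, i] = lo, hi
    else:
        raise CarecastError(f"unknown CI method {method!r}")

    lower[empty], upper[empty] = 0.0, 1.0

    def as_set(arr: np.ndarray) -> TransitionMatrixSet:
        probs = np.zeros((arr.shape[0], N_STATES, N_STATES))
        probs[:, :N_LIVING, :] = arr
        probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
        return TransitionMatrixSet(probs, age_groups=counts.age_groups)

    point_living = p.copy()
    point_living[empty] = 1.0 / N_STATES  # uninformative point for empty rows
    lower = np.minimum(lower, point_living)
    upper = np.maximum(upper, point_living)
    return IntervalMatrixSet(
        point=as_set(point_living),
        lower=as_set(lower),
        upper=as_set(upper),
        level=level,
        method=method,
    )
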