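"""End-to-end pipeline: estimate -> project -> demand -> validate -> report.

Every artifact carries a provenance header (package version, seed, config
hash), and a run is idempotent: two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .demand import DEFAULT_SCHEDULES, demand_by_state, total_demand
from .errors import ConfigurationError
from .estimation import (
    count_transitions,
    empirical_matrix,
    fit_multinomial_logit,
    flag_sparse_cells,
    predict_matrix,
    probability_limits,
)
from .io import (
    read_panel_csv,
    read_population_csv,
    read_schedules,
    write_matrices_csv,
    write_panel_csv,
    write_population_csv,
    write_report,
)
from .projection import project, totals_by_state
from .reference import CENSUS_STATE_TOTALS_2010, PANEL_MARGINALS, load_reference_matrices
from .states import AGE_LABELS, HealthState, LIVING_LABELS
from .summary import describe_panel
from .synthetic import default_cohort_sizes, simulate_census, simulate_panel
from .validation import chi_square_fit, perturbation_interval

logger = logging.getLogger("carecast")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; paths left ``None`` fall back to the
    bundled reference fixtures / synthetic generators."""

    out_dir: str = "carecast_out"
    panel_csv: str | None = None
    census_csv: str | None = None
    schedule_file: str | None = None
    baseline_year: int = 2010
    target_year: int = 2025
    step_years: float = 3.0
    age_threshold: float = 80.0
    design: str = "saturated"
    smoothing: float = 0.0
    ci_method: str = "wald"
    ci_level: float = 0.95
    rounding_policy: str = "round-then-sum"
    seed: int = 0
    validate_categories: int = 4

    def n_steps(self) -> int:
        span = self.target_year - self.baseline_year
        steps = span / self.step_years
        if span <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError(
                "target year minus baseline year must be a positive multiple "
                f"of the step length (got {span} / {self.step_years})"
            )
        return int(round(steps))

    def hash(self) -> str:
        # out_dir is where artifacts land, not what they contain: identical
        # settings + seed must hash identically wherever they are written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing artifacts under ``config.out_dir``.

    Returns the summary report dict. Raises on the first failing stage;
    partial outputs written before the failure stay on disk.
    """
    config.n_steps()  # validate early
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.hash(), "seed": config.seed}
    logger.info("run %s: seed=%d", config.hash(), config.seed)

    # --- inputs -----------------------------------------------------------
    if config.panel_csv:
        panel = read_panel_csv(config.panel_csv, wave_gap_years=config.step_years)
    else:
        logger.info("no panel supplied; simulating from the reference matrices")
        panel = simulate_panel(
            load_reference_matrices(normalize=True),
            default_cohort_sizes(),
            seed=config.seed,
        )
        write_panel_csv(panel, out / "panel.csv", provenance=prov)

    if config.census_csv:
        census = read_population_csv(config.census_csv)
    else:
        logger.info("no census supplied; emulating the 2010 baseline")
        weights = np.array(
            [PANEL_MARGINALS["age_group"][lab] for lab in AGE_LABELS], dtype=float
        )
        census = simulate_census(
            CENSUS_STATE_TOTALS_2010,
            weights / weights.sum(),
            year=config.baseline_year,
        )
        write_population_csv(census, out / "census.csv", provenance=prov)
    if census.year != config.baseline_year:
        raise ConfigurationError(
            f"census year {census.year} does not match baseline year "
            f"{config.baseline_year}"
        )

    schedules = (
        read_schedules(config.schedule_file)
        if config.schedule_file
        else dict(DEFAULT_SCHEDULES)
    )

    # --- estimate ---------------------------------------------------------
    summary = describe_panel(panel)
    counts = count_transitions(panel)
    coefs = fit_multinomial_logit(panel, design=config.design)
    matrices = predict_matrix(coefs)
    limits = probability_limits(
        counts, level=config.ci_level, method=config.ci_method, seed=config.seed
    )
    write_matrices_csv(matrices, out / "matrices.csv", limits=limits, provenance=prov)
    estimation_report = {
        "design": config.design,
        "log_likelihood": coefs.log_likelihood,
        "converged": coefs.converged,
        "n_iter": coefs.n_iter,
        "capped": coefs.capped,
        "flagged_cells": flag_sparse_cells(counts),
        "panel_n": summary.n,
    }
    write_report(estimation_report, out / "estimation.json", provenance=prov)

    # --- project ----------------------------------------------------------
    result = project(
        census,
        matrices.normalized(),
        n_steps=config.n_steps(),
        step_years=config.step_years,
        age_threshold=config.age_threshold,
    )
    with open(out / "projection.csv", "w") as fh:
        fh.write("".join(f"# {k}: {v}\n" for k, v in sorted(prov.items())))
        result.to_frame().to_csv(fh, index=False)
    totals = totals_by_state(result)

    # --- demand -----------------------------------------------------------
    demand_report: dict = {"target_year": config.target_year, "totals_persons": totals}
    for name, schedule in schedules.items():
        forecast = demand_by_state(totals, schedule)
        demand_report[name] = {
            "per_state_millions": forecast.demand_millions(),
            "total_millions": total_demand(forecast, policy=config.rounding_policy),
            "rounding_policy": config.rounding_policy,
        }
    write_report(demand_report, out / "demand.json", provenance=prov)

    # --- validate ---------------------------------------------------------
    # one-step check: observed follow-up distribution vs what the fitted
    # matrices predict from the baseline composition
    base_counts = counts.n.sum(axis=2)  # bands x living
    predicted = np.zeros(5)
    for a in range(base_counts.shape[0]):
        for i in range(base_counts.shape[1]):
            predicted += base_counts[a, i] * matrices.normalized().probs[a, i]
    observed = counts.n.sum(axis=(0, 1)).astype(float)
    if config.validate_categories == 4:
        fit = chi_square_fit(
            observed[:4], predicted[:4], categories=tuple(LIVING_LABELS)
        )
    else:
        fit = chi_square_fit(
            observed,
            predicted,
            categories=tuple(s.name for s in HealthState),
        )
    validation_report = {
        "statistic": fit.statistic,
        "df": fit.df,
        "p_value": fit.p_value,
        "observed": fit.observed.tolist(),
        "expected": fit.expected.tolist(),
        "categories": list(fit.categories),
    }

    interval = perturbation_interval(
        census,
        limits,
        n_steps=config.n_steps(),
        step_years=config.step_years,
        age_threshold=config.age_threshold,
    )
    validation_report["population_interval"] = {
        "point_millions": round(interval.point / 1e6, 2),
        "lower_millions": round(interval.lower / 1e6, 2),
        "upper_millions": round(interval.upper / 1e6, 2),
        "method": interval.method,
        "level": interval.level,
    }
    write_report(validation_report, out / "validation.json", provenance=prov)

    report = {
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "panel_n": summary.n,
        "totals_persons": totals,
        "demand": {k: v for k, v in demand_report.items() if k in schedules},
        "validation": {"statistic": fit.statistic, "p_value": fit.p_value},
    }
    write_report(report, out / "report.json", provenance=prov)
    return report
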