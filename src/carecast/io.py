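"""File I/O: panels, census tables, matrices, schedules, reports.

All tabular artifacts are plain CSV. Writers prepend ``#``-prefixed
provenance comment lines (version, seed, config hash) that readers skip,
so write->read round-trips are lossless. Malformed labels are reported
with their 1-based line number in the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParseError
from .estimation import IntervalMatrixSet
from .matrices import TransitionMatrixSet, absorbing_death_row
from .states import (
    AGE_LABELS,
    HealthState,
    LIVING_LABELS,
    STATE_LABELS,
    default_age_groups,
    normalize_age_label,
)
from .demand import StaffingSchedule
from .synthetic import PanelDataset, PopulationTable
from .errors import ConfigurationError

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_population_csv",
    "write_population_csv",
    "read_matrices_csv",
    "write_matrices_csv",
    "read_schedules",
    "write_report",
]


def _provenance_lines(provenance: dict | None) -> str:
    fields = {"generator": f"carecast {__version__}"}
    if provenance:
        fields.update(provenance)
    return "".join(f"# {k}: {v}\n" for k, v in sorted(fields.items()))


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def _line_lookup(path: str | Path) -> list[int]:
    """Map dataframe row index -> 1-based physical line, skipping comments."""
    lines = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            lines.append(lineno)
    return lines


def read_panel_csv(path: str | Path, wave_gap_years: float = 3.0) -> PanelDataset:
    """Read a two-wave panel (``id, age_group, state_baseline,
    state_followup`` plus optional extra columns)."""
    df = _read_csv(path)
    lines = _line_lookup(path)
    for col in ("id", "age_group", "state_baseline", "state_followup"):
        if col not in df.columns:
            raise ParseError(f"panel file {path} is missing column {col!r}")
    for idx, rec in df.iterrows():
        line = lines[idx] if idx < len(lines) else None
        try:
            df.at[idx, "age_group"] = normalize_age_label(rec["age_group"])
            base = HealthState.from_label(rec["state_baseline"])
            HealthState.from_label(rec["state_followup"])
        except ConfigurationError as exc:
            raise ParseError(str(exc), line=line) from None
        if base is HealthState.DEATH:
            raise ParseError("baseline state DEATH is not allowed", line=line)
    return PanelDataset(df, wave_gap_years=wave_gap_years)


def write_panel_csv(
    panel: PanelDataset, path: str | Path, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        panel.records.to_csv(fh, index=False)


def read_population_csv(path: str | Path) -> PopulationTable:
    """Read a census table (``age_group, state, count, year``)."""
    df = _read_csv(path)
    lines = _line_lookup(path)
    for col in ("age_group", "state", "count", "year"):
        if col not in df.columns:
            raise ParseError(f"census file {path} is missing column {col!r}")
    groups = default_age_groups()
    counts = np.zeros((len(groups), len(LIVING_LABELS)))
    years = set()
    for idx, rec in df.iterrows():
        line = lines[idx] if idx < len(lines) else None
        try:
            age = normalize_age_label(rec["age_group"])
            state = HealthState.from_label(rec["state"])
        except ConfigurationError as exc:
            raise ParseError(str(exc), line=line) from None
        if state is HealthState.DEATH:
            raise ParseError("census rows must be living states", line=line)
        if rec["count"] < 0:
            raise ParseError("negative count", line=line)
        counts[AGE_LABELS.index(age), state.index] += float(rec["count"])
        years.add(int(rec["year"]))
    if len(years) > 1:
        raise ParseError(f"census file mixes reference years {sorted(years)}")
    return PopulationTable(counts, age_groups=groups, year=years.pop() if years else 0)


def write_population_csv(
    table: PopulationTable, path: str | Path, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        table.to_frame().to_csv(fh, index=False)


def write_matrices_csv(
    matrices: TransitionMatrixSet,
    path: str | Path,
    limits: IntervalMatrixSet | None = None,
    provenance: dict | None = None,
) -> None:
    """Write matrices in long format: ``age_group, from_state, to_state, p``
    plus ``lower, upper`` columns when limits are supplied."""
    rows = []
    for a, group in enumerate(matrices.age_groups):
        for i, from_state in enumerate(STATE_LABELS):
            for j, to_state in enumerate(STATE_LABELS):
                row = {
                    "age_group": group.label,
                    "from_state": from_state,
                    "to_state": to_state,
                    "p": matrices.probs[a, i, j],
                }
                if limits is not None:
                    row["lower"] = limits.lower.probs[a, i, j]
                    row["upper"] = limits.upper.probs[a, i, j]
                rows.append(row)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_matrices_csv(path: str | Path) -> TransitionMatrixSet:
    df = _read_csv(path)
    groups = default_age_groups()
    probs = np.zeros((len(groups), len(STATE_LABELS), len(STATE_LABELS)))
    probs[:, HealthState.DEATH.index, :] = absorbing_death_row()
    lines = _line_lookup(path)
    for idx, rec in df.iterrows():
        line = lines[idx] if idx < len(lines) else None
        try:
            a = AGE_LABELS.index(normalize_age_label(rec["age_group"]))
            i = HealthState.from_label(rec["from_state"]).index
            j = HealthState.from_label(rec["to_state"]).index
        except ConfigurationError as exc:
            raise ParseError(str(exc), line=line) from None
        probs[a, i, j] = float(rec["p"])
    mset = TransitionMatrixSet(probs, age_groups=groups)
    mset.validate(atol=1e-6)
    return mset


def read_schedules(path: str | Path) -> dict[str, StaffingSchedule]:
    """Load staffing schedules from JSON or YAML.

    Format: ``{name: {healthy: 0.1, mild: 0.125, moderate: 0.1667,
    severe: 0.25}}`` (state keys case-insensitive).
    """
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ParseError(f"schedule file {path} must map names to ratio tables")
    schedules = {}
    for name, ratios in data.items():
        if not isinstance(ratios, dict):
            raise ParseError(f"schedule {name!r} must be a mapping of state ratios")
        schedules[name] = StaffingSchedule(
            name, {str(k).upper(): float(v) for k, v in ratios.items()}
        )
    return schedules


def write_report(results: dict, path: str | Path, provenance: dict | None = None) -> None:
    """Write a JSON report with an embedded provenance block."""
    payload = {
        "provenance": {"generator": f"carecast {__version__}", **(provenance or {})},
        **results,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
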