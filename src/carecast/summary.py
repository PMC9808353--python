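"""Descriptive summaries of a two-wave panel.

Percentages use the denominator conventional for each dimension: baseline
dimensions (sex, age band, baseline state) are percentages of the full
panel; follow-up state percentages are of wave-2 survivors only, with
deaths reported separately. The survivor denominator is deliberate and
easy to get wrong — a panel that is 78% healthy at baseline can be 73%
healthy among survivors three years later even though health declined
across the board, because deaths leave the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .states import AGE_LABELS, HealthState, LIVING_LABELS
from .synthetic import PanelDataset

__all__ = ["PanelSummary", "describe_panel"]


@dataclass
class PanelSummary:
    """Counts and percentages per dimension of a panel."""

    n: int
    n_survivors: int
    n_deaths: int
    tables: dict[str, pd.DataFrame]  # dimension -> (category, count, percent)

    def percent(self, dimension: str, category: str) -> float:
        table = self.tables[dimension]
        row = table[table["category"] == category]
        if row.empty:
            raise KeyError(f"{category!r} not present in dimension {dimension!r}")
        return float(row["percent"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for dim, table in self.tables.items():
            part = table.copy()
            part.insert(0, "dimension", dim)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def _tabulate(series: pd.Series, order: list[str], denominator: int) -> pd.DataFrame:
    counts = series.value_counts()
    rows = [
        {
            "category": cat,
            "count": int(counts.get(cat, 0)),
            "percent": round(100.0 * counts.get(cat, 0) / denominator, 2)
            if denominator
            else 0.0,
        }
        for cat in order
    ]
    return pd.DataFrame(rows)


def describe_panel(
    panel: PanelDataset, extra_columns: tuple[str, ...] = ("sex",)
) -> PanelSummary:
    """Tabulate counts and percentages for each panel dimension.

    ``extra_columns`` names optional categorical columns (e.g. ``sex``) to
    summarize when present.
    """
    rec = panel.records
    n = len(rec)
    survivors = rec[rec["state_followup"] != HealthState.DEATH.name]
    n_surv = len(survivors)

    tables = {
        "age_group": _tabulate(rec["age_group"], list(AGE_LABELS), n),
        "state_baseline": _tabulate(rec["state_baseline"], list(LIVING_LABELS), n),
        "state_followup": _tabulate(
            survivors["state_followup"], list(LIVING_LABELS), n_surv
        ),
    }
    for col in extra_columns:
        if col in rec.columns:
            order = sorted(rec[col].astype(str).unique())
            tables[col] = _tabulate(rec[col], order, n)
    return PanelSummary(
        n=n, n_survivors=n_surv, n_deaths=n - n_surv, tables=tables
    )
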