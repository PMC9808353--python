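"""Bundled reference inputs from the published 2008-2011 CLHLS analysis.

The package ships, as plain-text fixtures, the published age-stratified
2008->2011 health transition matrix, the 2010 census state totals for the
65+ population, the published 2025 projection totals, and the marginal
counts of the 13,269-person two-wave panel. These let every downstream
stage run and be tested without access to the original survey microdata.

Tabulated probabilities are printed to four decimals, so a few rows sum to
1 +/- 2e-4; :func:`load_reference_matrices` validates against the rounding
bound and can renormalize on request.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .matrices import TransitionMatrixSet, absorbing_death_row
from .states import AGE_LABELS, HealthState, LIVING_LABELS, default_age_groups

__all__ = [
    "load_reference_matrices",
    "CENSUS_STATE_TOTALS_2010",
    "PROJECTED_STATE_TOTALS_2025",
    "PANEL_MARGINALS",
    "ROUNDING_ROW_SUM_TOL",
]

#: Worst-case deviation of a 5-entry row sum from 1 when each entry is
#: rounded to 4 decimals (5 entries x half an ulp of 1e-4).
ROUNDING_ROW_SUM_TOL = 2.5e-4

#: 2010 census 65+ population by living state (persons).
CENSUS_STATE_TOTALS_2010: dict[HealthState, int] = {
    HealthState.HEALTHY: 107_300_000,
    HealthState.MILD: 6_400_000,
    HealthState.MODERATE: 2_200_000,
    HealthState.SEVERE: 2_900_000,
}

#: Published 2025 projection: 80+ population by living state (persons).
PROJECTED_STATE_TOTALS_2025: dict[HealthState, int] = {
    HealthState.HEALTHY: 46_864_699,
    HealthState.MILD: 3_739_730,
    HealthState.MODERATE: 846_033,
    HealthState.SEVERE: 1_227_704,
}

#: Marginal counts of the two-wave panel (n = 13,269): sex, baseline age
#: band, baseline state, and follow-up state (including deaths between
#: waves, 13,269 - 7,848 survivors = 5,421).
PANEL_MARGINALS: dict[str, dict[str, int]] = {
    "sex": {"MALE": 5655, "FEMALE": 7614},
    "age_group": {
        "65-69": 1111,
        "70-74": 1223,
        "75-79": 1118,
        "80-84": 1593,
        "85+": 8224,
    },
    "state_baseline": {
        "HEALTHY": 10406,
        "MILD": 1461,
        "MODERATE": 683,
        "SEVERE": 719,
    },
    "state_followup": {
        "HEALTHY": 5767,
        "MILD": 1086,
        "MODERATE": 383,
        "SEVERE": 612,
        "DEATH": 5421,
    },
}


def load_reference_matrices(
    normalize: bool = False,
    row_sum_tol: float = ROUNDING_ROW_SUM_TOL,
    open_band_midpoint: float = 87.0,
) -> TransitionMatrixSet:
    """Load the bundled 2008->2011 transition matrices.

    The fixture stores the four living rows per age band verbatim; the
    absorbing death row is appended here. Each row sum is checked against
    ``row_sum_tol`` (default: the 4-decimal rounding bound) and an
    :class:`IntegrityError` naming the row is raised on failure.

    Parameters
    ----------
    normalize : bool
        If True, rescale each row to sum exactly to one, removing the
        tabulation rounding. Use this when feeding the matrices to
        samplers or multi-step projections that assume exact
        stochasticity.
    """
    with resources.files("carecast.data").joinpath(
        "transitions_2008_2011.csv"
    ).open() as fh:
        table = pd.read_csv(fh)

    groups = default_age_groups(open_band_midpoint)
    probs = np.zeros((len(groups), 5, 5))
    probs[:, HealthState.DEATH.index] = absorbing_death_row()
    for _, rec in table.iterrows():
        a = AGE_LABELS.index(rec["age_group"])
        i = HealthState.from_label(rec["from_state"]).index
        probs[a, i] = [rec[lab] for lab in LIVING_LABELS + ("DEATH",)]

    mset = TransitionMatrixSet(probs, age_groups=groups)
    mset.validate(atol=row_sum_tol)
    for lab in LIVING_LABELS:
        if table[table["from_state"] == lab].shape[0] != len(groups):
            raise IntegrityError(f"fixture is missing rows for state {lab}")
    return mset.normalized() if normalize else mset
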