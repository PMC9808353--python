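import numpy as np
import pytest

import carecast as cc


@pytest.fixture(scope="session")
def ref_matrices() -> cc.TransitionMatrixSet:
    """Bundled 2008->2011 matrices, verbatim (rows sum to 1 +/- rounding)."""
    return cc.load_reference_matrices()


@pytest.fixture(scope="session")
def ref_norm(ref_matrices) -> cc.TransitionMatrixSet:
    """Reference matrices with rows rescaled to exact stochasticity."""
    return cc.load_reference_matrices(normalize=True)


@pytest.fixture(scope="session")
def small_panel(ref_norm) -> cc.PanelDataset:
    """A 5,000-record panel drawn from the reference matrices."""
    sizes = np.full((5, 4), 250)
    return cc.simulate_panel(ref_norm, sizes, seed=42)


@pytest.fixture(scope="session")
def small_counts(small_panel) -> cc.TransitionCounts:
    return cc.count_transitions(small_panel)


@pytest.fixture
def uniform_census() -> cc.PopulationTable:
    return cc.simulate_census(
        cc.CENSUS_STATE_TOTALS_2010, np.full(5, 0.2), year=2010
    )
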