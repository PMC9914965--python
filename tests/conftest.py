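import numpy as np
import pytest

from vegattr import GridSpec, SyntheticScenario


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(8, 8, cell_size=250.0, origin_y=8 * 250.0)


@pytest.fixture
def small_scenario(small_grid) -> SyntheticScenario:
    """Fast scenario for structural tests (not the study conditions)."""
    return SyntheticScenario(grid=small_grid, n_years=6, n_flow_records=2000,
                             seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
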