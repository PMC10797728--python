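import numpy as np
import pytest

from tmegraph.core import HistologyMap
from tmegraph.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_map():
    """Small two-class map with a background rim."""
    grid = np.full((8, 8), 0, dtype=np.int64)
    grid[2:5, 2:5] = 1
    grid[6, 6] = 2
    grid[0, :] = -1
    return HistologyMap(grid=grid, patient_id="toy")


@pytest.fixture(scope="session")
def planted_cohort():
    """One default planted cohort shared by patient-level tests."""
    cfg = CohortConfig(n_patients=40, map_shape=(40, 40), effect_size=2.0, seed=7)
    return cfg, generate_cohort(cfg)
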