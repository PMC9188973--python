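import warnings

import numpy as np
import pytest

from specverse.cohort import CohortConfig
from specverse.design import generate_task_design
from specverse.simulate import (
    GenerativeParams,
    simulate_scan,
    simulate_scan_measures,
    simulate_study,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")

META = {
    "participant_id": "sub001",
    "wave": 1,
    "age_at_scan": 8.0,
    "scanner": "scanner_A",
    "block_order": "order_1",
}

# clean generative settings: no noise, drift, global signal, or motion
# artifacts - used wherever an exact oracle comparison is made
CLEAN = GenerativeParams(
    noise_sd=0.0,
    ar1_coef=0.0,
    drift_coefs=(),
    global_amp=0.0,
    motion_artifact_gain=0.0,
    motion_base=0.01,
)


@pytest.fixture(scope="session")
def design():
    return generate_task_design(seed=1)


@pytest.fixture(scope="session")
def scan(design):
    return simulate_scan(design, META, GenerativeParams(), seed=3)


@pytest.fixture(scope="session")
def clean_scan(design):
    return simulate_scan(design, META, CLEAN, seed=3)


@pytest.fixture(scope="session")
def small_study():
    config = CohortConfig(n_participants_by_scan_count={1: 4, 2: 4, 3: 4})
    return simulate_study(config, seed=3)


@pytest.fixture(scope="session")
def measures():
    return simulate_scan_measures(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
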