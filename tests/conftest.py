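import numpy as np
import pytest

from bcancestry.config import CohortConfig
from bcancestry.synthetic import generate_cohort

SMALL_COHORT = {
    "n_per_group": {"EUR": 150, "AFR": 50, "SAS": 50, "Admix": 25},
    "seed": 11,
}


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(**SMALL_COHORT)


@pytest.fixture(scope="session")
def bundle(small_config):
    """One small generated cohort shared across the suite (read-only)."""
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
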