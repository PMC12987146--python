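import numpy as np
import pytest

from oncowatch import SimulationConfig, simulate_cohort
from oncowatch.labeling import label_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Profiles and weekly panel for the default N=200, W=6 study conditions."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def labeled_cohort(default_cohort):
    _, cohort = default_cohort
    return label_cohort(cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
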