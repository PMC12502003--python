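import numpy as np
import pytest

from cpcst import TaskConfig, simulate_cohort


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_cfg():
    """Config with a 60 s continuous phase for fast end-to-end tests."""
    return TaskConfig(continuous_duration_s=60.0)


@pytest.fixture(scope="session")
def small_cohort(short_cfg):
    """Eight simulated participants shared across tests (read-only)."""
    return simulate_cohort(8, config=short_cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
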