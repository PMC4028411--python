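import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thetacoupling import SimConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def small_config(**overrides) -> SimConfig:
    """Compact cohort geometry for fast experiments: 3x3x3 grid, 16 sensors."""
    defaults = dict(
        n_subjects=8,
        n_trials_per_condition=18,
        n_sensors=16,
        grid_shape=(3, 3, 3),
        source_positions={"seed": (0, 1, 1), "coupled": (2, 1, 1), "pac": (1, 2, 2)},
        rng_seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by pipeline-level tests."""
    return simulate_dataset(small_config(rng_seed=5))
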