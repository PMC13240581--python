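import numpy as np
import pytest

from igsched import CohortConfig, build_phantom, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete cohort config for fast tests."""
    return CohortConfig(n_patients=2, grid_shape=(20, 20, 20), seed=3)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return build_phantom(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def zero_noise_config():
    """Degenerate cohort: no setup error at all, so pre = post = planned/n."""
    return CohortConfig(
        n_patients=2, grid_shape=(20, 20, 20),
        sigma_systematic=0.0, sigma_random=0.0, sigma_residual=0.0, seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
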