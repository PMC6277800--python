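import numpy as np
import pytest

from rsnec.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-ROI-per-network cohort for fast structural tests."""
    return SimulationConfig(
        n_control=4,
        n_case=3,
        n_frames=128,
        rois_per_network=(2,) * 11,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


def ar1(rng, phi, n, burn=200):
    """Plain AR(1) series with unit-variance innovations."""
    e = rng.standard_normal(n + burn)
    x = np.empty(n + burn)
    x[0] = e[0]
    for i in range(1, n + burn):
        x[i] = phi * x[i - 1] + e[i]
    return x[burn:]
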