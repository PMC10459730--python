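import numpy as np
import pytest

from leafspec.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy dataset shared by read-only tests (60 samples, 120 bands)."""
    cfg = SimulationConfig(n_samples=60, n_bands=120, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_config():
    """Distortion-free generator config (no scatter/noise/drift)."""
    return SimulationConfig(
        n_samples=40, n_bands=120, scatter_sd=0.0, noise_sd=0.0, drift_sd=0.0, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
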