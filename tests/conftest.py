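import numpy as np
import pytest

from mirprog import SimulationConfig, generate_array_dataset, normalize_samples


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic cohort shared across tests (24 samples, 60 probes)."""
    cfg = SimulationConfig(n_samples=24, n_mirnas=60, n_expressed=30,
                           n_empty_spots=8, seed=11)
    return generate_array_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return normalize_samples(small_dataset.raw_samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
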