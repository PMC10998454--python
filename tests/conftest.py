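import numpy as np
import pytest

from gwaspower import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: 300 null + 60 disease SNPs, moderate effect."""
    return SimConfig(n_null=300, n_disease=60, or_het=2.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, n_cases=120, n_controls=180, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
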