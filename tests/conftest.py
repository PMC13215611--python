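import numpy as np
import pytest

from dualseq.synthdata import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced trial counts for fast unit tests; SNR as in the defaults."""
    return SimConfig(n_participants=4, trials_per_condition=12, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
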