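import numpy as np
import pytest

from halfwave.synthetic import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Default 5-stage synthetic dataset, 12 epochs per class (fast)."""
    return generate_dataset(SimConfig(seed=7), n_epochs_per_class=12)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic dataset: 5 stages x 40 epochs, seed 17."""
    return generate_dataset(SimConfig(seed=17), n_epochs_per_class=40)
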