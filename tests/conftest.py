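import numpy as np
import pytest

import beanspec as bs


@pytest.fixture(scope="session")
def roster():
    return bs.load_roster()


@pytest.fixture(scope="session")
def small_dataset():
    """A light 5-batch synthetic dataset shared across read-only tests."""
    return bs.simulate_bean_dataset(bs.SimulationConfig(n_batches=5, seed=42))


@pytest.fixture(scope="session")
def noiseless_config():
    return bs.SimulationConfig(
        n_batches=1,
        beans_per_batch=10,
        noise_sd=0.0,
        scatter_sd=0.0,
        pixel_jitter=0.0,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
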