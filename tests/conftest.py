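import numpy as np
import pytest

from gcn16s.synthetic_data import SimulationConfig, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40-tip simulated study shared by fast tests."""
    cfg = SimulationConfig(n_tips=40, seq_length=150, seed=3, noise_sd=0.25)
    return make_benchmark(cfg)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(0))
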