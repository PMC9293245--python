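import numpy as np
import pytest

from oropod import SimConfig, Simulation


@pytest.fixture
def cfg():
    return SimConfig(seed=11)


@pytest.fixture
def sim(cfg):
    return Simulation(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def warm_sim():
    """A simulation advanced past the transient, shared where only a
    generic non-trivial state is needed (read-only: clone before mutating)."""
    s = Simulation(SimConfig(seed=5))
    s.run(200.0)
    return s
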