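import numpy as np
import pytest

import dolsim as ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A work-phase-sized configuration for fast unit tests."""
    return ds.SimulationConfig(M=4, N=10, T=10, generations=2, seed=7)


@pytest.fixture
def ff_parents():
    g = ds.make_initial_genotype(ds.FEEDFORWARD)
    return g, g
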