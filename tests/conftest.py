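import numpy as np
import pytest

from apneakit.simulate import SimConfig, generate_recording


@pytest.fixture(scope="session")
def sim_night():
    """One default synthetic night (30 min), shared across tests."""
    rec, truth = generate_recording(SimConfig(seed=123))
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
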