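import numpy as np
import pytest

from scalesid import catalogue


@pytest.fixture
def death_model():
    return catalogue.get_model("death")


@pytest.fixture
def immigration_model():
    return catalogue.get_model("death_immigration")


@pytest.fixture
def twostate_model():
    return catalogue.get_model("twostate_nonlinear")


@pytest.fixture
def twostate_sim_ics():
    """Initial conditions for numeric runs: the declared zero start gives the
    trivial trajectory, so the observed state is seeded away from zero."""
    return dict(catalogue.entry("twostate_nonlinear").simulation_ics)


@pytest.fixture
def short_grid():
    return np.linspace(0.0, 0.3, 25)
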