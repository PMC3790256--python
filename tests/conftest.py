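"""Shared fixtures: one seeded synthetic study reused across the suite."""

import numpy as np
import pytest

from pnmkit import PhysioNoiseModel
from pnmkit.simulate import SimulationParams, simulate_run


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def sim_run(default_params):
    """(data, recording, timing, truth) for the default synthetic study."""
    return simulate_run(default_params)


@pytest.fixture(scope="session")
def fitted(sim_run):
    """Default 34-regressor fit of the default synthetic study."""
    data, recording, timing, _ = sim_run
    return PhysioNoiseModel(data, recording, timing).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
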