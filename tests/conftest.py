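"""Shared fixtures: synthetic trials are generated once per session."""

import numpy as np
import pytest

from gravgait.synthetic import generate_trial
from gravgait.synthetic.walker import Anthropometry, synth_walker_markers


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (1 G, 1.2 m/s) with truth."""
    return generate_trial(seed=11)


@pytest.fixture(scope="session")
def reduced_gravity_trial():
    """A strongly supported trial (0.31 G, 0.8 m/s) with truth."""
    return generate_trial(seed=12, gravity_level=0.31, target_speed=0.8)


@pytest.fixture(scope="session")
def offplate_trial():
    """Second right heel strike beyond the instrumented plates."""
    return generate_trial(seed=13, rhs2_on_plate=False)


@pytest.fixture(scope="session")
def walker_noiseless():
    """Noise-free walker pass plus its anthropometry."""
    anth = Anthropometry.from_basics(70.0, 0.88)
    res = synth_walker_markers(speed=1.2, stride_time=1.1, anthropometry=anth,
                               contact_times=[0.5, 1.6], duration=2.5,
                               rng=None)
    return res, anth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
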