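"""Shared fixtures: toy designs and fast simulation settings.

The ``fast_sim`` configuration shortens the evaluation window so unit
tests exercise full simulation code paths in well under a second; tests
of quantitative locomotion claims use the default 10-s window.
"""

import numpy as np
import pytest

import voxevo as V


@pytest.fixture(scope="session")
def walker():
    return V.make_fixture("walker")


@pytest.fixture(scope="session")
def solid_block():
    return V.make_fixture("solid_block")


@pytest.fixture()
def fast_sim():
    return V.SimulationConfig(settle_time=0.3, eval_time=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
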