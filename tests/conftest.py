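import logging

import numpy as np
import pytest

from opmbeta.containers import HeadModel, Paradigm
from opmbeta.synthetic import make_sensor_array

logging.getLogger("opmbeta").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def small_array():
    """32-sensor triaxial array used by the cheaper beamformer tests."""
    return make_sensor_array(n_sensors=32, seed=0)


@pytest.fixture(scope="session")
def paradigm():
    return Paradigm()


@pytest.fixture(scope="session")
def fixture_cohort():
    """4-subject mini-cohort with planted defects, shared across tests."""
    from opmbeta.pipeline import fixture_generator

    return fixture_generator(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
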