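import numpy as np
import pytest

from jmassoc.splines import BaselineSplineSpec, NcsSpec
from jmassoc.synthetic_data import default_scenario, simulate_scenario


@pytest.fixture(scope="session")
def ncs_spec():
    return NcsSpec((0.0, 24.0), (6.0,))


@pytest.fixture(scope="session")
def baseline_spec():
    return BaselineSplineSpec(3, (10.0, 20.0, 30.0, 40.0, 50.0), (0.0, 60.0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """25-subject current-value trial, shared across read-only tests."""
    sc = default_scenario("current_value", n_subjects=25, seed=7)
    return simulate_scenario(sc), sc


@pytest.fixture(scope="session")
def small_dataset():
    """60-subject current-value trial for fit smoke tests."""
    sc = default_scenario("current_value", n_subjects=60, seed=3)
    return simulate_scenario(sc), sc


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
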