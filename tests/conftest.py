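import numpy as np
import pytest

from drugdyn.control import fbsm_solve, reference_problem
from drugdyn.model import StateVector, get_preset


@pytest.fixture(scope="session")
def baseline():
    return get_preset("table2_baseline")


@pytest.fixture(scope="session")
def lower():
    return get_preset("table2_lower")


@pytest.fixture
def rng():
    return np.random.default_rng(20150383)


@pytest.fixture(scope="session")
def mixed_state():
    return StateVector(0.97, 0.02, 0.01, 0.0, 0.0)


@pytest.fixture(scope="session")
def reference_solution(baseline):
    """FBSM solution of the reference 20-year scenario (computed once)."""
    return fbsm_solve(reference_problem(baseline))
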