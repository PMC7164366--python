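import numpy as np
import pytest

from cetdate.priors import BdParams, ClockModelSpec
from cetdate.substitution import SubstitutionParams
from cetdate.synthetic_data import simulate_timetree


@pytest.fixture
def bd():
    return BdParams(1.0, 1.0, 0.1)


@pytest.fixture
def sub5():
    return SubstitutionParams(kappa=4.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
                              gamma_shape=0.8, n_categories=5)


@pytest.fixture
def sub1():
    return SubstitutionParams(kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
                              gamma_shape=1.0, n_categories=1)


@pytest.fixture
def tree8(bd):
    return simulate_timetree(8, 100.0, bd, seed=42)


@pytest.fixture
def tree16(bd):
    return simulate_timetree(16, 100.0, bd, seed=43)
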