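import numpy as np
import pytest

from adhops.bath import DrudeLorentzBath, decompose_correlation
from adhops.eom import ModeSet


@pytest.fixture
def bath():
    """Reference overdamped bath: lambda = gamma = 50 cm^-1, T = 295 K."""
    return DrudeLorentzBath(50.0, 50.0, 295.0, 500.0)


@pytest.fixture
def bath_no_mark():
    return DrudeLorentzBath(50.0, 50.0, 295.0, None)


@pytest.fixture
def modes(bath):
    return decompose_correlation(bath, site=0)


@pytest.fixture
def dimer_modeset(bath):
    return ModeSet.from_baths([bath, bath])

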