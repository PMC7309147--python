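import numpy as np
import pytest

from obtmon.circuit_models import InterfaceParams
from obtmon.estimation import build_calibration
from obtmon.obt_engine import BandPassSpec, BioimpedanceBlockSpec, ComparatorSpec


@pytest.fixture(scope="session")
def params():
    return InterfaceParams()


@pytest.fixture(scope="session")
def bp():
    return BandPassSpec()


@pytest.fixture(scope="session")
def bio():
    return BioimpedanceBlockSpec()


@pytest.fixture(scope="session")
def comparator():
    return ComparatorSpec()


@pytest.fixture(scope="session")
def calibration(params, bp, bio, comparator):
    """Default-config calibration curve (201 grid points), shared."""
    return build_calibration(params, bp, bio, comparator)


@pytest.fixture(scope="session")
def freq_grid():
    return np.geomspace(1.0, 1e6, 50)
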