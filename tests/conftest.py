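import numpy as np
import pytest

from glioswitch.spatial_model import Grid1D, PDEParams
from glioswitch.switch_network import SwitchParams


@pytest.fixture(scope="session")
def params():
    """Reference switch parameterization."""
    return SwitchParams()


@pytest.fixture(scope="session")
def pde_params():
    return PDEParams()


@pytest.fixture(scope="session")
def grid():
    return Grid1D(100)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
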