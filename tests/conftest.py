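import numpy as np
import pytest

from ivimflow.synthetic import default_protocol, regime_params

#: protocol timing shared by most tests (lobe duration / separation, ms)
DELTA, BIG_DELTA = 8.6, 10.0
B_GRID = np.array([5.0, 10.0, 20.0, 30.0, 100.0, 200.0])
SIGMA_V = 1.5  # mm/s, per component


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def brain_params():
    """Brain-like intermediate-regime parameter set (tau = 130 ms)."""
    return regime_params("intermediate")


@pytest.fixture(scope="session")
def flow_params():
    """Pure-flow parameters matching sigma_v = 1.5 mm/s isotropic flow."""
    from ivimflow.model import IVIMParams

    return IVIMParams(f=1.0, D=0.0, v=SIGMA_V * np.sqrt(3), tau=200.0)
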