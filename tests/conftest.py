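import numpy as np
import pytest

import memhh as M


@pytest.fixture(scope="session")
def hh():
    return M.HHParams()


@pytest.fixture(scope="session")
def nbox():
    return M.MemristorParams.preset("nbox")


@pytest.fixture(scope="session")
def wox():
    return M.MemristorParams.preset("wox")


@pytest.fixture(scope="session")
def nbox_scales():
    return M.ScalingFactors.preset("nbox")


@pytest.fixture(scope="session")
def ou_short():
    """200 ms OU stimulus at the study's default parameters, fixed seed."""
    return M.ou_process(M.OUSpec(duration=200.0, seed=11))


@pytest.fixture(scope="session")
def hh_trace(hh, ou_short):
    return M.simulate_hh(hh, M.resting_state(hh), ou_short)


@pytest.fixture(scope="session")
def hybrid_trace(hh, nbox, nbox_scales, ou_short):
    return M.simulate_hybrid(hh, nbox, nbox_scales, ou_short)
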