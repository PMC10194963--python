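import warnings

import numpy as np
import pytest

from okninfo import syndata


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    """Boundary-blink and tie warnings are expected in bulk simulation."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="blink touches trace boundary")
        warnings.filterwarnings("ignore", message="ties present")
        yield


@pytest.fixture(scope="session")
def clean_session():
    """One default-condition synthetic session shared across tests."""
    cfg = syndata.SimConfig(seed=11)
    return syndata.simulate_session(cfg, session_length=240.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
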