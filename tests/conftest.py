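import numpy as np
import pytest

from thetasamp import behavior, mua
from thetasamp.simulate import SimulationParams, simulate_attention_session


@pytest.fixture(scope="session")
def small_session():
    """A compact attention session shared by behavior/coupling tests."""
    params = SimulationParams(seed=11, n_trials=600, n_channels_disk=3,
                              n_channels_bar=3)
    return simulate_attention_session(params, with_eye=False)


@pytest.fixture(scope="session")
def small_session_rt(small_session):
    det = {}
    for loc in ("center", "flanker"):
        raw = behavior.build_rt_timecourse(small_session.rt_table, loc)
        det[loc] = behavior.detrend_rt(raw)
    return det


@pytest.fixture(scope="session")
def small_session_z(small_session):
    z, _ = mua.zscore_mua(small_session.mua)
    return z
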