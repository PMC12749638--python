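import numpy as np
import pytest

from vocmotion.types import Epoch, Placement, EPOCH_LEN


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_epoch(values, limb="arm", side="left", event=0, infant="inf000",
               tp=6, as_envelope=False):
    """Construct an Epoch directly on the fixed grid for unit tests."""
    values = np.asarray(values, dtype=float)
    assert values.size == EPOCH_LEN
    ep = Epoch(event_index=event, onset=10.0,
               placement=Placement("infant", limb, side),
               infant_id=infant, time_point=tp)
    ep.raw = values.copy()
    ep.baselined = values.copy()
    if as_envelope:
        ep.envelope = values.copy()
    return ep


def sort_median(vals):
    """Independent sort-based median oracle."""
    s = sorted(float(v) for v in vals)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


@pytest.fixture
def quiet_simconfig():
    """Small, imperfection-free generator settings for construction tests."""
    from vocmotion.synthetic import SimConfig
    return SimConfig(session_duration=60.0, voc_rate=5.0, refractory=8.0,
                     carrier="sine", env_noise_sd=0.0, axis_noise=0.0,
                     noise_floor=0.005, n_artifacts=0, n_gaps=0,
                     n_rate_drops=0, lag_audio_imu=0.0)
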