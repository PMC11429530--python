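import numpy as np
import pandas as pd
import pytest

from gonogo import montage
from gonogo.io_core.containers import EpochSet, Recording

ALL_CHANNELS = montage.EEG_CHANNELS + montage.EOG_CHANNELS


def make_epochs(data: np.ndarray, fs: float = 512.0, t0: int = 256,
                conditions=None, channel_names=None,
                onset_sample=None, rt_ms=None) -> EpochSet:
    """EpochSet factory with all-accepted flags."""
    n = data.shape[0]
    return EpochSet(
        data=data, fs=fs, t0_index=t0,
        channel_names=channel_names or ALL_CHANNELS[: data.shape[1]],
        condition=np.array(conditions if conditions is not None
                           else ["Go", "NoGo"] * (n // 2) + ["Go"] * (n % 2),
                           dtype=object),
        accepted=np.ones(n, dtype=bool),
        reason=np.array([""] * n, dtype=object),
        rt_ms=np.full(n, np.nan) if rt_ms is None else np.asarray(rt_ms, float),
        onset_sample=onset_sample,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_recording(rng):
    """20 s, 23-channel low-amplitude noise recording with a few events."""
    fs = 512.0
    n = int(20 * fs)
    data = 5.0 * rng.standard_normal((23, n))
    events = pd.DataFrame({
        "onset_sample": [2048, 2048 + 563, 2048 + 2 * 563 + 100],
        "condition": ["Go", "NoGo", "Go"],
        "block": [0, 0, 0],
    })
    responses = pd.DataFrame({"press_sample": [2048 + 180, 2048 + 2 * 563 + 100 + 200]})
    return Recording(data, fs, ALL_CHANNELS, events, responses)
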