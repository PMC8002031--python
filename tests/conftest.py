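import numpy as np
import pandas as pd
import pytest

from neurolex import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochset(data, sampling_rate=500.0, t0=-200.0, meta=None, labels=None):
    """Build a small EpochSet around a (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_sa = data.shape
    times = t0 + 1000.0 / sampling_rate * np.arange(n_sa)
    if labels is None:
        labels = tuple(f"CH{i}" for i in range(n_ch))
    if meta is None:
        meta = pd.DataFrame({"trial": np.arange(1, n_tr + 1),
                             "correct": 1, "rt_ms": 700.0,
                             "lexicality": "word", "session": 1,
                             "participant": 1})
    return EpochSet(data=data, times_ms=times, channel_labels=labels,
                    trial_meta=meta, sampling_rate=sampling_rate)


@pytest.fixture
def epochset_factory():
    return make_epochset
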