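import numpy as np
import pandas as pd
import pytest

from thetawm import synth
from thetawm.containers import EpochSet


@pytest.fixture(scope="session")
def layout16():
    return synth.make_montage(16, seed=0)


@pytest.fixture(scope="session")
def radius16(layout16):
    return layout16.calibrate_radius(5.7)


@pytest.fixture(scope="session")
def adjacency16(layout16, radius16):
    return layout16.adjacency(radius16)


def make_epochs(data, rate=128.0, tmin=0.0, ch_names=None, metadata=None,
                categories=None):
    """Small EpochSet factory for fixtures."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, _ = data.shape
    if ch_names is None:
        ch_names = [f"c{i}" for i in range(n_ch)]
    if metadata is None:
        cats = (categories if categories is not None
                else ["object", "scene"] * (n_trials // 2 + 1))[:n_trials]
        metadata = pd.DataFrame({
            "participant": "P01", "task": "1back", "epoch": "delay",
            "category": cats,
            "exemplar": [f"{c}{i % 5}" for i, c in enumerate(cats)],
            "block": 0, "trial_index": np.arange(n_trials),
            "correct": True, "rt": 0.5,
        })
    return EpochSet(data=data, rate=rate, tmin=tmin, ch_names=list(ch_names),
                    metadata=metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
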