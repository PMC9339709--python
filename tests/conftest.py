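import numpy as np
import pandas as pd
import pytest

from p300lab.containers import EpochSet


def make_epochs(data: np.ndarray, sfreq: float = 250.0, tmin: float = -0.5, ch_names=None) -> EpochSet:
    """Wrap a (n_epochs, n_channels, n_samples) array into an EpochSet."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, _ = data.shape
    if ch_names is None:
        ch_names = ["Pz"] if n_ch == 1 else [f"ch{i}" for i in range(n_ch)]
        if n_ch > 1:
            ch_names[0] = "Pz"
    return EpochSet(
        data=data,
        sfreq=sfreq,
        ch_names=list(ch_names),
        tmin=tmin,
        events=pd.DataFrame({"onset": np.arange(n_ep, dtype=float)}),
        kept=np.arange(n_ep),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
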