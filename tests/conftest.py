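import numpy as np
import pandas as pd
import pytest

from tagattn.synth_eeg import CHANNELS_30, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """Four trials, full montage, 500 Hz, [-0.1, 4] s epochs of pink-ish noise."""
    n_samples = int(4.1 * 500)
    data = rng.standard_normal((4, len(CHANNELS_30), n_samples))
    meta = pd.DataFrame({"focus": ["a", "a", "b", "b"], "trial": range(4)})
    return EpochSet(data, 500.0, -0.1, CHANNELS_30, meta)
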