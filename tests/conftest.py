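import numpy as np
import pytest

from rrgamma import BeatSequence, extract_feature_table, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 NSR + 30 AF one-minute synthetic series, fixed seed."""
    return make_dataset(30, 30, duration_s=60.0, seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_feature_table(small_dataset)


@pytest.fixture()
def regular_beats():
    """75 beats at a constant 0.75 s rhythm (0.75 is binary-exact, so every
    interval — and hence every derivative — is exactly representable)."""
    return BeatSequence(times=np.arange(75) * 0.75, label="NSR", record_id="const")
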