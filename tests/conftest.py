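import numpy as np
import pytest

from tmaquant import SegmentationConfig


@pytest.fixture
def small_cfg():
    """Desk-scale config: thresholds at the published values, cylinder size
    filter scaled down for ~150-px-radius synthetic cores."""
    return SegmentationConfig(min_object_area=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
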