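import numpy as np
import pytest

from gravscan.io import RetinaFrame
from gravscan.synthetic import Blob, make_blob_stimulus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gray_frame():
    """A constant mid-gray 32x32 frame (no gradients anywhere)."""
    return RetinaFrame(np.full((32, 32, 3), 0.5))


@pytest.fixture
def random_frame(rng):
    return RetinaFrame(rng.uniform(0.0, 1.0, size=(32, 32, 3)))


@pytest.fixture
def single_blob_frame():
    """64x64 stimulus with one Gaussian blob at (40, 30)."""
    return make_blob_stimulus((64, 64), [Blob(center=(40.0, 30.0), sigma=6.0,
                                              amplitude=0.5)])
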