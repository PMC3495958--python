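import numpy as np
import pytest

from whasa.core import BinaryMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(data=np.asarray(data, dtype=float), spacing=spacing)


def make_mask(data, grid=None):
    data = np.asarray(data).astype(bool)
    if grid is None:
        grid = Volume(data=np.zeros(data.shape))
    return BinaryMask(data=data, grid=grid)


@pytest.fixture
def straight_boundary_case():
    """GM (left, 120) / WM (right, 100) split by a straight vertical
    boundary; hard probability maps.  Useful wherever an analytically
    tractable GM/WM interface is needed."""
    shape = (12, 10, 3)
    img = np.full(shape, 100.0)
    img[:6, :, :] = 120.0
    gm = np.zeros(shape)
    gm[:6, :, :] = 1.0
    wm = np.zeros(shape)
    wm[6:, :, :] = 1.0
    return (make_volume(img), make_volume(gm), make_volume(wm))
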