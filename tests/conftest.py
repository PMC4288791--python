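import numpy as np
import pytest

from gbsi.volumes import ProbMask, ScanPair, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(data, voxel_size=(1.0, 1.0, 1.0)):
    return VolumeGrid(data=np.asarray(data, dtype=float), voxel_size=voxel_size)


def make_mask(prob, grid=None, voxel_size=(1.0, 1.0, 1.0)):
    prob = np.asarray(prob, dtype=float)
    if grid is None:
        grid = make_grid(np.zeros(prob.shape), voxel_size)
    return ProbMask(prob=prob, grid=grid)


@pytest.fixture
def small_phantom_pair():
    """A coarse (2 mm / 40^3) 2%-loss noiseless phantom pair, for fast tests."""
    from gbsi.phantom import PhantomSpec, make_phantom

    spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_size=2.0, atrophy_fraction=0.02)
    return make_phantom(spec)


@pytest.fixture
def identical_pair():
    """A pair whose baseline and repeat (images and masks) are identical."""
    from gbsi.phantom import PhantomSpec, make_phantom

    spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_size=2.0, atrophy_fraction=0.0)
    pair, _ = make_phantom(spec)
    return pair
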