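import numpy as np
import pytest

from contourqa import BinaryMask, ImageVolume


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
              organ="brain", role="ground_truth"):
    return BinaryMask(voxels=np.asarray(voxels, dtype=bool), spacing=spacing,
                      origin=origin, organ=organ, role=role)


def sphere_voxels(shape, center, radius):
    """Voxel-center-inside rasterization of a sphere in index units."""
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def cube_pair():
    """gt = 2x2x2 cube at 0..1, test = same cube shifted +1 in x."""
    g = np.zeros((4, 4, 4), dtype=bool)
    g[0:2, 0:2, 0:2] = True
    t = np.zeros((4, 4, 4), dtype=bool)
    t[1:3, 0:2, 0:2] = True
    return make_mask(g), make_mask(t)


@pytest.fixture
def small_image():
    return ImageVolume(voxels=np.full((6, 6, 6), 40.0), spacing=(1, 1, 1.5))
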