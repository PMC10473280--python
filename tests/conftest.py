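import numpy as np
import pytest

from wdhub import BoldSeries, MaskGeometry, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sim_config():
    """Small, fast study conditions for structural tests."""
    return SimConfig(grid_shape=(6, 6, 6), n_communities=2, n_timepoints=80,
                     seed=7)


def make_geometry(shape=(6, 6, 6), voxel_mm=3.0, mask=None):
    affine = np.diag([voxel_mm] * 3 + [1.0])
    n = int(np.prod(shape))
    indices = np.arange(n) if mask is None else np.flatnonzero(mask.ravel())
    return MaskGeometry(shape=shape, affine=affine, indices=indices)


def make_series(data, voxel_mm=3.0, tr=1.5, shape=None):
    """Wrap a (voxels, time) array as a BoldSeries on a cubic grid."""
    data = np.asarray(data, dtype=float)
    if shape is None:
        side = 1
        while side ** 3 < data.shape[0]:
            side += 1
        shape = (side, side, side)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    geom = MaskGeometry(shape=shape, affine=affine,
                        indices=np.arange(data.shape[0]))
    return BoldSeries(data=data, geometry=geom, tr_seconds=tr)
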