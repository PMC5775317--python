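import numpy as np
import pytest

from tumorica.imaging import BinaryMask, Series4D, VoxelGrid, Volume3D


@pytest.fixture
def grid12():
    return VoxelGrid.isotropic((12, 12, 12), 2.0)


@pytest.fixture
def sphere_image(grid12):
    """Two-level image: intensity 100 inside a radius-5-voxel sphere, 0 outside."""
    idx = np.indices(grid12.shape, dtype=float)
    dist2 = ((idx - 5.5) ** 2).sum(axis=0)
    data = np.where(dist2 <= 25.0, 100.0, 0.0)
    return Volume3D(grid12, data)


def make_series(shape=(8, 8, 8), n_frames=20, voxel_mm=2.0, seed=0, tr=2.0):
    rng = np.random.default_rng(seed)
    grid = VoxelGrid.isotropic(shape, voxel_mm)
    return Series4D(grid, rng.standard_normal(shape + (n_frames,)), tr_seconds=tr)


def full_mask(grid):
    return BinaryMask(grid, np.ones(grid.shape, bool))
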