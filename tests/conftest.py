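import numpy as np
import pytest

from msburden.burden import LesionMask, TractBundle, VoxelGrid
from msburden.synth import make_toy_bundles


@pytest.fixture
def unit_grid():
    """24^3 grid, 1 mm isotropic, identity orientation."""
    return VoxelGrid(shape=(24, 24, 24), affine=np.eye(4))


@pytest.fixture(scope="session")
def toy_bundles():
    """Small cached bundle set: UF_left/right, fornix_left/right on 32^3."""
    return make_toy_bundles((32, 32, 32), 1.0, 20, seed=7)


@pytest.fixture(scope="session")
def toy_grid():
    return VoxelGrid(shape=(32, 32, 32), affine=np.eye(4))


def straight_bundle(name, n=3, spacing=4.0, length=12.0, y0=4.0, z0=4.0):
    """Parallel straight streamlines along x, spaced in y (disjoint voxel rows)."""
    sls = [
        np.array([[1.0, y0 + i * spacing, z0], [1.0 + length, y0 + i * spacing, z0]])
        for i in range(n)
    ]
    return TractBundle(name=name, streamlines=sls)


def mask_from_voxels(grid, voxels):
    arr = np.zeros(grid.shape, dtype=np.uint8)
    for v in voxels:
        arr[tuple(v)] = 1
    return LesionMask(grid=arr, affine=grid.affine)
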