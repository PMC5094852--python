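import numpy as np
import pytest
from hypothesis import settings

from granulemetry.geometry import REFERENCE_GEOMETRY, VoxelGeometry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def em_geometry():
    """The reference anisotropic FIB/SEM voxel geometry."""
    return REFERENCE_GEOMETRY


@pytest.fixture
def iso_geometry():
    """Isotropic 10 nm voxels: convenient for hand-checkable arithmetic."""
    return VoxelGeometry(10.0, 10.0, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sphere_voxels(shape, center, radius_vox):
    """Boolean mask of a digitized sphere (isotropic voxel units)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox**2


@pytest.fixture
def make_sphere():
    return sphere_voxels
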