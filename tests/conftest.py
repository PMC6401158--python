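import numpy as np
import pytest

from xerosubvol.grid import Mask, VoxelGrid


@pytest.fixture
def unit_grid():
    """Isotropic 1 mm grid, 40^3, origin at 0."""
    return VoxelGrid((40, 40, 40), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture
def sphere_mask(unit_grid):
    """Digital sphere of radius 10 mm centered in the unit grid."""
    x, y, z = unit_grid.coordinate_grids()
    c = 19.5
    v = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 10.0**2
    return Mask("sphere", unit_grid, np.broadcast_to(v, unit_grid.dims).copy())


def make_box_mask(grid, lo, hi, name="box"):
    """Axis-aligned box mask by voxel-index bounds (inclusive)."""
    v = np.zeros(grid.dims, dtype=bool)
    v[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
    return Mask(name, grid, v)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small, fast cohort configuration shared by integration tests."""
    from xerosubvol.synthetic import CohortConfig

    return CohortConfig(n_patients=8, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    from xerosubvol.synthetic import generate_cohort

    return generate_cohort(tiny_cohort_config, keep_volumes=True)
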