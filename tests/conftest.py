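import numpy as np
import pytest

from xlct.forward import DetectorModel, ForwardModel, XRaySource
from xlct.geometry import OpticalProperties, VoxelGrid, make_cylinder_phantom, simulation_phantom
from xlct.mesh import mesh_cylinder


@pytest.fixture(scope="session")
def phantom():
    return simulation_phantom()


@pytest.fixture(scope="session")
def coarse_mesh(phantom):
    """Coarse mesh of the simulation phantom for fast FEM tests."""
    return mesh_cylinder(phantom, 0.25)


@pytest.fixture(scope="session")
def coarse_forward(phantom, coarse_mesh):
    """Small end-to-end forward model: 6 views, 24^2 detector, 16x16x3 grid."""
    detector = DetectorModel.for_phantom(phantom, n_pix=24, n_views=6)
    grid = VoxelGrid.for_phantom(phantom, nx=16, ny=16, nz=3)
    return ForwardModel(phantom, coarse_mesh, detector, XRaySource(), grid)


@pytest.fixture(scope="session")
def coarse_weight_matrix(coarse_forward):
    return coarse_forward.build_weight_matrix(dtype=np.float64)
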