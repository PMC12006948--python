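import numpy as np
import pytest

from galvox import (
    CellModel,
    ElectrodeGeometry,
    build_mesh,
    calibrated_medium,
    galvanostatic_boundary_flux,
    solve_steady,
    solve_transient,
)


@pytest.fixture(scope="session")
def geometry():
    return ElectrodeGeometry()


@pytest.fixture(scope="session")
def cell():
    return CellModel()


@pytest.fixture(scope="session")
def medium():
    return calibrated_medium()


@pytest.fixture(scope="session")
def mesh_l1(geometry, cell):
    """Coarse (level-1) axisymmetric mesh shared across solver tests."""
    return build_mesh(geometry, refinement_level=1, cells=(cell,))


@pytest.fixture(scope="session")
def flux_m7(geometry):
    return galvanostatic_boundary_flux(-7e-9, geometry.disk_radius)


@pytest.fixture(scope="session")
def steady_m7(mesh_l1, medium, flux_m7, cell):
    return solve_steady(mesh_l1, medium, flux_m7, (cell,))


@pytest.fixture(scope="session")
def transient_m7(mesh_l1, medium, flux_m7, cell):
    return solve_transient(
        mesh_l1, medium, flux_m7, (cell,),
        t_end=120.0, output_times=np.arange(0.0, 121.0, 2.0),
    )
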