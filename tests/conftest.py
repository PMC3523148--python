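import numpy as np
import pytest

from memfem.assembly import BoundaryCondition, build_system
from memfem.geometry import make_cell, place_cells


@pytest.fixture(scope="session")
def cell4():
    return make_cell((0.0, 0.0), n_holes=4)


@pytest.fixture(scope="session")
def cell2h():
    return make_cell((0.0, 0.0), n_holes=2, orientation="horizontal")


@pytest.fixture(scope="session")
def cell0():
    return make_cell((0.0, 0.0), n_holes=0)


@pytest.fixture(scope="session")
def geom1(cell4):
    """Single 4-hole cell at the origin (model a)."""
    return place_cells(1, cell4)


@pytest.fixture(scope="session")
def bc_h():
    return BoundaryCondition.horizontal_injection()


@pytest.fixture(scope="session")
def sys16(geom1, bc_h):
    """Assembled model-a system on the N=16 mesh, shared across tests."""
    return build_system(geom1, bc_h, 16)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
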