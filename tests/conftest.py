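import numpy as np
import pytest

from emistrand.fixtures import make_fixture
from emistrand.geometry import membrane_areas
from emistrand.ionic import grandi_epicardial, reduced_test_model


@pytest.fixture(scope="session")
def tiny_cell_mesh():
    return make_fixture("tiny_cell")


@pytest.fixture(scope="session")
def tiny_two_cell_mesh():
    return make_fixture("tiny_two_cell")


@pytest.fixture(scope="session")
def single_cuboid_mesh():
    return make_fixture("single_cuboid")


@pytest.fixture(scope="session")
def tiny_quad(tiny_cell_mesh):
    return membrane_areas(tiny_cell_mesh)


@pytest.fixture(scope="session")
def reduced_model():
    return reduced_test_model()


@pytest.fixture(scope="session")
def grandi_model():
    return grandi_epicardial()


@pytest.fixture(scope="session")
def default_cell_mesh():
    """Reference single cell at the reference spacings (1, 1, 2) µm."""
    from emistrand.geometry import CellGeometry, StrandLayout, Spacings, build_strand
    return build_strand(CellGeometry.default(), StrandLayout(1),
                        Spacings.from_um(1, 1, 2))
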