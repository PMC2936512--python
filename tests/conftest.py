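import numpy as np
import pytest

from canfat.network import Cell, CellNetwork, CrossSectionGeometry, generate_network
from canfat.params import AGED_MLE, YOUNG_MLE


@pytest.fixture(scope="session")
def young_theta():
    return YOUNG_MLE


@pytest.fixture(scope="session")
def aged_theta():
    return AGED_MLE


@pytest.fixture(scope="session")
def default_network():
    """Full-size young cross-section (seeded once per session)."""
    return generate_network(age_class="young", seed=1)


@pytest.fixture(scope="session")
def small_geometry():
    """Compact cross-section for affordable simulation tests."""
    return CrossSectionGeometry(outer_a=220, outer_b=170, inner_a=150,
                                inner_b=105, n_subsectors=96,
                                n_surface_sectors=24)


@pytest.fixture(scope="session")
def small_network(small_geometry):
    return generate_network(geometry=small_geometry, age_class="young", seed=3)


@pytest.fixture(scope="session")
def calib_geometry():
    """Very small cross-section used for calibration studies."""
    return CrossSectionGeometry(outer_a=130, outer_b=100, inner_a=75,
                                inner_b=50, n_subsectors=32,
                                n_surface_sectors=8)


@pytest.fixture(scope="session")
def calib_network(calib_geometry):
    return generate_network(geometry=calib_geometry, age_class="young", seed=11)


def make_toy_network(cell_specs, edges, geometry=None):
    """Hand-built network: cell_specs are (id, kind, x, y, surface)."""
    geometry = geometry or CrossSectionGeometry()
    cells = [Cell(i, kind, float(x), float(y), surface, 0)
             for (i, kind, x, y, surface) in cell_specs]
    adjacency = {(min(a, b), max(a, b)) for a, b in edges}
    return CellNetwork(geometry, cells, adjacency, "young", 0)


@pytest.fixture
def pair_network():
    """One osteocyte at the extreme periosteal fiber + one precursor."""
    return make_toy_network(
        [(0, "osteocyte", 600.0, 0.0, "none"),
         (1, "precursor", 570.0, 20.0, "periosteal")],
        [(0, 1)],
    )
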