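import numpy as np
import pytest

from oligoring.ring_builder import PlacementParams, build_ring
from oligoring.synthetic import make_toy_monomer

# placement that puts the flat toy subunit into a doughnut whose dimensions
# fall inside the TEM/AFM experimental ranges (see docs/methods.md)
RING_RADIUS_A = 88.0
RING_TILT_RAD = np.radians(8.0)


@pytest.fixture(scope="session")
def toy_monomer():
    return make_toy_monomer(n_residues=120, seed=0)


@pytest.fixture(scope="session")
def toy_structure(toy_monomer):
    return toy_monomer.structure


@pytest.fixture(scope="session")
def toy_ca(toy_structure):
    idx = toy_structure.atom_indices(lambda a: a.name == "CA")
    return toy_structure.coords[idx]


@pytest.fixture(scope="session")
def dodecamer(toy_structure):
    return build_ring(toy_structure, 12, PlacementParams(ring_radius=RING_RADIUS_A, tilt=RING_TILT_RAD))


@pytest.fixture(scope="session")
def decamer(toy_structure):
    return build_ring(toy_structure, 10, PlacementParams(ring_radius=RING_RADIUS_A, tilt=RING_TILT_RAD))
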