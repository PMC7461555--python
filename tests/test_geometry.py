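"""Ring geometry measurement, radii of gyration, constraint filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from oligoring.geometry import (
    AFM_CONSTRAINTS,
    ConstraintSet,
    TEM_CONSTRAINTS,
    annulus_rg,
    combine_constraints,
    filter_by_constraints,
    measure_ring_geometry,
    radius_of_gyration,
    RingGeometry,
)
from oligoring.structures import Atom, Structure
from oligoring.synthetic import make_hollow_cylinder


def bead_structure(coords):
    return Structure(
        [
            Atom(serial=i + 1, name="CA", element="C", chain_id="A", residue_seq=i + 1,
                 residue_name="ALA", position=p)
            for i, p in enumerate(np.asarray(coords))
        ]
    )


# ---- radius_of_gyration ----------------------------------------------------

def test_rg_two_unit_masses():
    coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    assert radius_of_gyration(coords) == pytest.approx(0.1)  # 1 Å in nm


def test_rg_hoop_limit():
    theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    r = 70.0  # Å
    coords = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)], axis=1)
    assert radius_of_gyration(coords) == pytest.approx(7.0, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rg_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 5, size=(30, 3))
    masses = rng.uniform(1, 20, size=30)
    rot = Rotation.random(random_state=seed).as_matrix()
    moved = coords @ rot.T + rng.uniform(-100, 100, size=3)
    assert radius_of_gyration(moved, masses) == pytest.approx(
        radius_of_gyration(coords, masses), abs=1e-12
    )


def test_rg_validation():
    with pytest.raises(ValueError):
        radius_of_gyration(np.empty((0, 3)))
    with pytest.raises(ValueError):
        radius_of_gyration(np.zeros((2, 3)), masses=np.array([1.0, -1.0]))


# ---- annulus closed form ---------------------------------------------------

def test_annulus_hoop_and_disc_limits():
    assert annulus_rg(5.0, 5.0, 0.0) == pytest.approx(5.0)
    assert annulus_rg(1.0, 0.0, 0.0) == pytest.approx(1.0 / np.sqrt(2.0))


def test_annulus_ordering_enforced():
    with pytest.raises(ValueError):
        annulus_rg(3.0, 5.0, 1.0)
    with pytest.raises(ValueError):
        annulus_rg(5.0, 3.0, -1.0)


def test_annulus_matches_bead_fixture():
    beads = make_hollow_cylinder(100.0, 35.0, 25.0, 100_000, seed=1)
    assert radius_of_gyration(beads) == pytest.approx(annulus_rg(10.0, 3.5, 2.5), rel=0.01)


# ---- measure_ring_geometry -------------------------------------------------

def test_hollow_cylinder_measured_dimensions():
    beads = bead_structure(make_hollow_cylinder(100.0, 35.0, 12.5, 50_000, seed=2))
    g = measure_ring_geometry(beads, uniform_mass=True)
    assert g.outer_diameter == pytest.approx(20.0, rel=0.01)
    assert g.cavity_diameter == pytest.approx(7.0, rel=0.01)
    assert g.height == pytest.approx(1.25, rel=0.02)
    assert g.ring_width == pytest.approx((g.outer_diameter - g.cavity_diameter) / 2, abs=1e-12)


def test_single_point_degenerate():
    g = measure_ring_geometry(bead_structure([[3.0, 4.0, 5.0]]), uniform_mass=True)
    assert g.outer_diameter == g.cavity_diameter == g.height == 0.0


def test_axis_recovery_under_random_rotation():
    beads = make_hollow_cylinder(100.0, 35.0, 25.0, 30_000, seed=3)
    g0 = measure_ring_geometry(bead_structure(beads), uniform_mass=True)
    rot = Rotation.random(random_state=11).as_matrix()
    g1 = measure_ring_geometry(bead_structure(beads @ rot.T + np.array([50.0, -20.0, 5.0])), uniform_mass=True)
    for attr in ("outer_diameter", "cavity_diameter", "height", "rg"):
        assert getattr(g1, attr) == pytest.approx(getattr(g0, attr), abs=1e-3)


def test_ring_geometry_invariants():
    with pytest.raises(ValueError):
        RingGeometry(outer_diameter=5.0, cavity_diameter=7.0, height=1.0, rg=3.0)
    with pytest.raises(ValueError):
        RingGeometry(outer_diameter=5.0, cavity_diameter=2.0, height=-1.0, rg=3.0)


# ---- constraint filtering --------------------------------------------------

def test_filter_experimental_ranges_pass():
    g = RingGeometry(outer_diameter=21.0, cavity_diameter=10.0, height=2.0, rg=8.0)
    verdict = filter_by_constraints(g, combine_constraints(TEM_CONSTRAINTS, AFM_CONSTRAINTS))
    assert verdict.passed and not verdict.failed_parameters


def test_filter_vacuous_and_boundary():
    g = RingGeometry(outer_diameter=16.0, cavity_diameter=6.0, height=2.0, rg=7.0)
    assert filter_by_constraints(g, ConstraintSet()).passed
    # inclusive bounds: exactly 16 passes the 16-24 interval
    assert filter_by_constraints(g, ConstraintSet(outer_diameter=(16.0, 24.0))).passed


def test_filter_reports_every_violation():
    g = RingGeometry(outer_diameter=30.0, cavity_diameter=20.0, height=4.0, rg=8.0)
    verdict = filter_by_constraints(g, combine_constraints(TEM_CONSTRAINTS, AFM_CONSTRAINTS))
    assert not verdict.passed
    names = {n for n, _, _ in verdict.failed_parameters}
    assert names == {"outer_diameter", "height"}


def test_combine_takes_tightest_bounds():
    merged = combine_constraints(
        ConstraintSet(outer_diameter=(16.0, 24.0)), ConstraintSet(outer_diameter=(20.0, 30.0))
    )
    assert merged.outer_diameter == (20.0, 24.0)


def test_constraint_validation():
    with pytest.raises(ValueError):
        ConstraintSet(outer_diameter=(5.0, 2.0))
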