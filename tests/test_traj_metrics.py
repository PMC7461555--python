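"""Superposition, TM-score, H-bond occupancy, secondary structure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oligoring.structures import Atom, MonomerStructure, Structure
from oligoring.synthetic import (
    HAIRPIN_TURN,
    HELIX,
    LOOP,
    SHEET,
    _residues_to_atoms,
    build_backbone,
    make_toy_monomer,
    make_trajectory,
)
from oligoring.traj_metrics import (
    HBondCriteria,
    assign_secondary_structure,
    hbond_occupancy,
    kabsch_superpose,
    rmsd_series,
    ss_content,
    tm_score,
    tm_score_d0,
)


def backbone_structure(torsions, resname="ALA"):
    return MonomerStructure(_residues_to_atoms(build_backbone(torsions), resname=resname))


# ---- Kabsch ----------------------------------------------------------------

def test_kabsch_identity(toy_ca):
    sup = kabsch_superpose(toy_ca, toy_ca)
    assert sup.rmsd < 1e-12
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)


def test_kabsch_recovers_known_transform(toy_ca):
    rot = Rotation.from_euler("zyx", [0.7, -0.3, 1.1]).as_matrix()
    moved = toy_ca @ rot.T + np.array([10.0, -4.0, 2.5])
    sup = kabsch_superpose(moved, toy_ca)
    assert sup.rmsd < 1e-9
    assert np.abs(sup.rotation @ rot - np.eye(3)).max() < 1e-9


def test_kabsch_never_reflects():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 3, (6, 3))
    mirrored = a * np.array([1.0, 1.0, -1.0])
    sup = kabsch_superpose(mirrored, a)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
    assert sup.rmsd > 0.1  # a reflection cannot be undone by a proper rotation


def brute_force_min_rmsd(mob, ref, coarse=24, fine=16):
    """Two-stage exhaustive minimization over zyz Euler rotations."""
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)

    def rmsd_at(angles):
        r = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ r.T - ref_c) ** 2, axis=1)))

    best_angles, best = None, np.inf
    for a in np.linspace(-np.pi, np.pi, coarse, endpoint=False):
        for b in np.linspace(0.0, np.pi, coarse // 2):
            for c in np.linspace(-np.pi, np.pi, coarse, endpoint=False):
                v = rmsd_at([a, b, c])
                if v < best:
                    best, best_angles = v, (a, b, c)
    step = 2.0 * np.pi / coarse
    for _ in range(8):  # shrink the grid around the running optimum
        a0, b0, c0 = best_angles
        for a in np.linspace(a0 - step, a0 + step, fine):
            for b in np.linspace(b0 - step, b0 + step, fine):
                for c in np.linspace(c0 - step, c0 + step, fine):
                    v = rmsd_at([a, b, c])
                    if v < best:
                        best, best_angles = v, (a, b, c)
        step /= 2.5
    return best


def test_kabsch_matches_bruteforce_grid():
    """Refined exhaustive rotation search converges to the Kabsch optimum."""
    rng = np.random.default_rng(8)
    ref = rng.normal(0, 4, (4, 3))
    mob = ref + rng.normal(0, 0.7, (4, 3))
    best = kabsch_superpose(mob, ref).rmsd
    brute = brute_force_min_rmsd(mob, ref)
    assert best <= brute + 1e-9
    assert brute - best < 1e-3


def test_kabsch_input_validation():
    with pytest.raises(ValueError, match="differ"):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)


# ---- RMSD series -----------------------------------------------------------

def test_rmsd_series_static_zero(toy_structure):
    traj = make_trajectory(toy_structure, 5)
    assert np.allclose(rmsd_series(traj), 0.0, atol=1e-12)


def test_rmsd_series_rigid_motion_removed(toy_structure):
    traj = make_trajectory(
        toy_structure,
        8,
        rigid_motion=lambda i: (Rotation.from_euler("xz", [0.2 * i, -0.1 * i]).as_matrix(), np.array([5.0 * i, 0.0, 1.0 * i])),
    )
    assert np.allclose(rmsd_series(traj), 0.0, atol=1e-9)


def test_rmsd_series_noise_level(toy_structure):
    sigma = 0.5
    traj = make_trajectory(toy_structure, 30, noise_sigma=sigma, seed=7)
    series = rmsd_series(traj, reference=toy_structure.coords)
    # Monte-Carlo expectation: per-atom displacement sigma*sqrt(3)
    assert series.mean() == pytest.approx(sigma * np.sqrt(3.0), rel=0.15)


def test_rmsd_series_empty_selection(toy_structure):
    traj = make_trajectory(toy_structure, 2)
    with pytest.raises(ValueError, match="empty"):
        rmsd_series(traj, selection=lambda a: a.name == "ZZ")


# ---- TM-score --------------------------------------------------------------

def test_tm_identity(toy_ca):
    result = tm_score(toy_ca, toy_ca)
    assert result.score == pytest.approx(1.0)
    assert result.length_target == 120


def test_tm_d0_formula():
    assert tm_score_d0(120) == pytest.approx(1.24 * 105 ** (1.0 / 3.0) - 1.8)
    assert tm_score_d0(120) == pytest.approx(4.05, abs=0.01)
    with pytest.raises(ValueError):
        tm_score_d0(15)


def uniform_d0_family(scale=1.0, L=120, seed=42):
    """Reference cloud in +/- pairs; radial displacement of magnitude scale*d0.

    The pairing makes the cross-covariance of reference and displacement
    exactly symmetric positive definite, so the optimal superposition is
    the identity and every residue sits exactly scale*d0 away.
    """
    rng = np.random.default_rng(seed)
    half = rng.normal(0, 10, (L // 2, 3))
    ref = np.vstack([half, -half])
    d0 = tm_score_d0(L)
    u = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    return ref, ref + scale * d0 * u, d0


def test_tm_uniform_d0_displacement_scores_half():
    ref, model, d0 = uniform_d0_family()
    sup = kabsch_superpose(model, ref)
    assert np.abs(sup.rotation - np.eye(3)).max() < 1e-9
    assert np.allclose(np.linalg.norm(sup.apply(model) - ref, axis=1), d0, atol=1e-9)
    result = tm_score(model, ref)
    # search may only ever find >= the plug-in value
    assert 0.5 - 1e-9 <= result.score <= 0.52


def test_tm_monotone_in_displacement_magnitude():
    scores = []
    for scale in (0.5, 1.0, 1.5, 2.0):
        ref, model, _ = uniform_d0_family(scale=scale)
        scores.append(tm_score(model, ref).score)
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_tm_rigid_motion_invariance(toy_ca):
    rot = Rotation.from_euler("xyz", [0.4, 1.0, -0.6]).as_matrix()
    ref, model, _ = uniform_d0_family()
    base = tm_score(model, ref).score
    moved = tm_score(model @ rot.T + np.array([3.0, 4.0, 5.0]), ref).score
    assert moved == pytest.approx(base, abs=1e-6)


# ---- hydrogen bonds --------------------------------------------------------

def test_hbond_schedule_occupancies(toy_structure):
    pair = (("A", 10, "N"), ("A", 40, "O"))
    always = make_trajectory(toy_structure, 50, hbond_schedule={pair: np.ones(50, bool)}, seed=1)
    assert hbond_occupancy(always, [pair])[0].occupancy == 1.0
    mask = np.zeros(50, bool)
    mask[:42] = True
    partial = make_trajectory(toy_structure, 50, hbond_schedule={pair: mask}, seed=1)
    assert hbond_occupancy(partial, [pair])[0].occupancy == 0.84
    never = make_trajectory(toy_structure, 50, hbond_schedule={pair: np.zeros(50, bool)}, seed=1)
    assert hbond_occupancy(never, [pair])[0].occupancy == 0.0


def test_hbond_unknown_atom_named_in_error(toy_structure):
    traj = make_trajectory(toy_structure, 3)
    with pytest.raises(KeyError, match="ZZ"):
        hbond_occupancy(traj, [(("A", 10, "ZZ"), ("A", 40, "O"))])


def test_hbond_criteria_validation():
    with pytest.raises(ValueError):
        HBondCriteria(max_donor_acceptor_distance=-1.0)
    with pytest.raises(ValueError):
        HBondCriteria(min_dha_angle=200.0)


# ---- secondary structure ---------------------------------------------------

def test_ideal_helix_assigns_helix():
    labels = assign_secondary_structure(backbone_structure([HELIX] * 20))
    assert ss_content(labels).helix >= 0.8


def test_extended_chain_has_no_structure():
    labels = assign_secondary_structure(backbone_structure([(-139.0, 135.0)] * 20))
    content = ss_content(labels)
    assert content.helix == 0.0 and content.sheet == 0.0


def test_hairpin_strands_assign_sheet():
    torsions = [SHEET] * 10 + HAIRPIN_TURN + [SHEET] * 10
    labels = assign_secondary_structure(backbone_structure(torsions))
    first, second = labels[2:8], labels[-8:-2]
    assert all(x == "E" for x in first)
    assert all(x == "E" for x in second)


def test_backbone_only_dependence_gly_vs_ala():
    torsions = [HELIX] * 12 + LOOP * 2 + [SHEET] * 6
    ala = assign_secondary_structure(backbone_structure(torsions, resname="ALA"))
    gly = assign_secondary_structure(backbone_structure(torsions, resname="GLY"))
    assert ala == gly


def test_missing_backbone_labelled_coil():
    atoms = [
        Atom(serial=1, name="CA", element="C", chain_id="A", residue_seq=1,
             residue_name="ALA", position=np.zeros(3))
    ]
    assert assign_secondary_structure(Structure(atoms)) == ["C"]


def test_ss_agreement_with_independent_dssp(tmp_path):
    """Cross-check against mdtraj's DSSP on the toy subunit."""
    mdtraj = pytest.importorskip("mdtraj")
    from oligoring.structures import write_pdb

    fixture = make_toy_monomer(seed=0)
    path = tmp_path / "toy.pdb"
    write_pdb(fixture.structure, path)
    simplified = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=True)[0]
    mine = ["H" if x == "H" else ("E" if x == "E" else "C") for x in assign_secondary_structure(fixture.structure)]
    agreement = np.mean([a == b for a, b in zip(simplified, mine)])
    assert agreement >= 0.9


def test_ss_content_fractions():
    content = ss_content(list("HHEETTCC"))
    assert content.helix == content.sheet == content.turn == content.coil == 0.25
    assert ss_content(["H"] * 10).helix == 1.0
    with pytest.raises(ValueError):
        ss_content([])
    with pytest.raises(ValueError):
        ss_content(["H", "Q"])


def test_ss_content_sums_to_one(toy_structure):
    content = ss_content(assign_secondary_structure(toy_structure))
    assert content.helix + content.sheet + content.turn + content.coil == pytest.approx(1.0, abs=1e-12)
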