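"""PDB containers and IO: parsing, round trips, gaps, sequences."""

import numpy as np
import pytest

from oligoring.structures import (
    Atom,
    MonomerStructure,
    detect_missing_segments,
    read_pdb,
    read_trajectory,
    write_pdb,
    write_trajectory,
)
from oligoring.synthetic import make_trajectory

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.004   1.421   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.246   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.320   1.548   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.950   2.860   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.460   2.740   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.010   1.640   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   2       3.540   3.660   1.240  1.00  0.00           C
END
"""


@pytest.fixture()
def gly_ala(tmp_path):
    path = tmp_path / "gly_ala.pdb"
    path.write_text(GLY_ALA_PDB)
    return path


def test_read_small_pdb(gly_ala):
    st = read_pdb(gly_ala)
    assert isinstance(st, MonomerStructure)
    assert len(st) == 9
    assert st.residues("A") == [(1, "GLY"), (2, "ALA")]
    assert st.sequence_of("A") == "GA"


def test_sequence_of_unknown_chain(gly_ala):
    st = read_pdb(gly_ala)
    with pytest.raises(KeyError):
        st.sequence_of("Z")


def test_read_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(ValueError, match="no ATOM"):
        read_pdb(empty)


def test_round_trip_preserves_everything(toy_structure, tmp_path):
    path = tmp_path / "toy.pdb"
    write_pdb(toy_structure, path)
    back = read_pdb(path)
    assert len(back) == len(toy_structure)
    assert [a.name for a in back.atoms] == [a.name for a in toy_structure.atoms]
    assert [a.residue_seq for a in back.atoms] == [a.residue_seq for a in toy_structure.atoms]
    assert [a.chain_id for a in back.atoms] == [a.chain_id for a in toy_structure.atoms]
    # PDB stores 3 decimals
    assert np.allclose(back.coords, toy_structure.coords, atol=5e-4)


def test_round_trip_idempotent(toy_structure, tmp_path):
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_pdb(toy_structure, p1)
    write_pdb(read_pdb(p1), p2)
    assert p1.read_text() == p2.read_text()


def test_multichain_read_gives_assembly(dodecamer, tmp_path):
    path = tmp_path / "ring.pdb"
    write_pdb(dodecamer, path)
    back = read_pdb(path)
    assert back.chain_ids() == dodecamer.chain_ids()
    assert back.n_subunits == 12


@pytest.mark.parametrize(
    "present, expected",
    [
        ([1, 2, 3, 4], {}),
        ([1, 2, 5, 6], {"A": [(3, 4)]}),
        ([1, 3, 7, 8, 10], {"A": [(2, 2), (4, 6), (9, 9)]}),
    ],
)
def test_gap_detection_matches_bruteforce(present, expected):
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", chain_id="A", residue_seq=r,
             residue_name="ALA", position=np.array([float(r), 0.0, 0.0]))
        for i, r in enumerate(present)
    ]
    assert detect_missing_segments(atoms) == expected
    # brute-force oracle: every absent number between min and max is missing
    missing = sorted(set(range(min(present), max(present) + 1)) - set(present))
    flat = [r for seg in detect_missing_segments(atoms).get("A", []) for r in range(seg[0], seg[1] + 1)]
    assert flat == missing


def test_trajectory_single_model_equals_read_pdb(toy_structure, tmp_path):
    path = tmp_path / "one.pdb"
    write_pdb(toy_structure, path)
    traj = read_trajectory(path)
    assert len(traj) == 1
    assert np.allclose(traj.frames[0], read_pdb(path).coords)


def test_trajectory_round_trip(toy_structure, tmp_path):
    traj = make_trajectory(toy_structure, n_frames=50, noise_sigma=0.2, seed=4)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path, toy_structure)
    assert len(back) == 50
    assert np.allclose(back.frames[49], traj.frames[49], atol=5e-4)


def test_trajectory_inconsistent_models_rejected(tmp_path):
    body = GLY_ALA_PDB.replace("END\n", "")
    truncated = "\n".join(body.splitlines()[:5])
    path = tmp_path / "bad.pdb"
    path.write_text(f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{truncated}\nENDMDL\nEND\n")
    with pytest.raises(ValueError, match="inconsistent atom count"):
        read_trajectory(path)


def test_atom_validation():
    with pytest.raises(ValueError, match="occupancy"):
        Atom(serial=1, name="CA", element="C", chain_id="A", residue_seq=1,
             residue_name="ALA", position=np.zeros(3), occupancy=1.5)
    with pytest.raises(ValueError, match="finite"):
        Atom(serial=1, name="CA", element="C", chain_id="A", residue_seq=1,
             residue_name="ALA", position=np.array([np.nan, 0, 0]))
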