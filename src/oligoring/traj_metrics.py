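"""Structural stability and similarity metrics.

Four metric families used to judge oligomer model stability:

* Kabsch superposition and Cα RMSD series over a trajectory;
* TM-score, the length-normalized template-quality score with distance
  scale d0 = 1.24·(L-15)^(1/3) - 1.8 Å;
* hydrogen-bond occupancy — the fraction of frames in which a named
  donor/acceptor pair satisfies geometric criteria;
* secondary-structure assignment by Kabsch–Sander backbone hydrogen-bond
  energies, collapsed to the four-bin {helix, sheet, turn, coil} scheme
  in which secondary-structure tables for these oligomers are reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structures import Atom, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondOccupancy",
    "SSContent",
    "SuperpositionResult",
    "TMScoreResult",
    "assign_secondary_structure",
    "hbond_occupancy",
    "kabsch_superpose",
    "rmsd_series",
    "ss_content",
    "tm_score",
]


# ---------------------------------------------------------------------------
# Kabsch superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal proper rigid alignment of ``mobile`` onto ``reference``.

    ``apply`` maps mobile coordinates into the reference frame:
    x -> R x + t.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition restricted to proper rotations.

    Solves the orthogonal Procrustes problem by SVD of the cross-covariance
    matrix, with the determinant sign corrected so reflections are never
    returned. Requires >= 3 paired, non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[0] < 3 or mobile.shape[1] != 3:
        raise ValueError("need at least 3 paired 3-d points")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set: rotation is not determined")

    cov = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = reference.mean(axis=0) - rotation @ mobile.mean(axis=0)
    aligned = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref_c) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _default_selection(atom: Atom) -> bool:
    return atom.name == "CA"


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection=_default_selection,
) -> np.ndarray:
    """Per-frame Kabsch RMSD (Å) of the selected atoms against a reference.

    ``reference`` is a frame index or an explicit coordinate array over the
    full topology; the selection (default Cα) applies to both.
    """
    idx = traj.topology.atom_indices(selection)
    if len(idx) == 0:
        raise ValueError("empty atom selection")
    if isinstance(reference, (int, np.integer)):
        ref = traj.frames[int(reference)][idx]
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (len(traj.topology), 3):
            raise ValueError("reference must cover the full topology")
        ref = reference[idx]
    return np.array([kabsch_superpose(frame[idx], ref).rmsd for frame in traj.frames])


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

@dataclass
class TMScoreResult:
    score: float
    d0: float
    length_target: int


def tm_score_d0(length: int) -> float:
    """Length-dependent distance scale; defined for L > 15."""
    if length <= 15:
        raise ValueError(f"d0 formula requires L > 15, got {length}")
    return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8


def _tm_from_superposition(model: np.ndarray, reference: np.ndarray, sup: SuperpositionResult, d0: float) -> float:
    d = np.linalg.norm(sup.apply(model) - reference, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def tm_score(model: np.ndarray, reference: np.ndarray, d0: float | None = None) -> TMScoreResult:
    """TM-score of a model against a reference under a fixed 1:1 residue pairing.

    score = max over rigid superpositions of (1/L) Σ 1/(1 + (d_i/d0)²),
    normalized by the reference length. The maximization heuristic seeds
    superpositions from contiguous fragments (lengths L, L/2, L/4 at
    staggered offsets), then iterates: superpose on the included subset,
    re-include residues closer than a cutoff, with the cutoff schedule
    descending from 8 Å to d0, keeping the best score seen.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError("model and reference must pair 1:1")
    length = len(reference)
    if d0 is None:
        d0 = tm_score_d0(length)

    cutoffs = [8.0]
    while cutoffs[-1] / 2.0 > d0:
        cutoffs.append(cutoffs[-1] / 2.0)
    cutoffs.append(max(d0, 0.5))

    best = 0.0
    frag_lengths = sorted({length, max(length // 2, 4), max(length // 4, 4)}, reverse=True)
    for frag in frag_lengths:
        offsets = range(0, length - frag + 1, max(frag // 2, 1))
        for start in offsets:
            included = np.arange(start, start + frag)
            for cutoff in cutoffs:
                for _ in range(20):
                    if len(included) < 3:
                        break
                    sup = kabsch_superpose(model[included], reference[included])
                    # rigid transform from the subset, scored over all residues
                    full_sup = SuperpositionResult(
                        rotation=sup.rotation, translation=sup.translation, rmsd=sup.rmsd
                    )
                    best = max(best, _tm_from_superposition(model, reference, full_sup, d0))
                    d = np.linalg.norm(full_sup.apply(model) - reference, axis=1)
                    new = np.where(d < cutoff)[0]
                    if len(new) < 3 or np.array_equal(new, included):
                        break
                    included = new
    return TMScoreResult(score=best, d0=float(d0), length_target=length)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (MD-analysis convention)."""

    max_donor_acceptor_distance: float = 3.5  # Å
    min_dha_angle: float = 120.0              # degrees

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class HBondOccupancy:
    donor: tuple[str, int, str]     # (chain, residue, atom)
    acceptor: tuple[str, int, str]
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


def _donor_hydrogen_indices(topology: Structure, donor_idx: int) -> list[int]:
    """Hydrogens covalently attached to the donor heavy atom.

    Identified by name (starts with H, same residue) and topology-frame
    proximity (< 1.3 Å). Returns an empty list when the structure carries
    no explicit hydrogens.
    """
    donor = topology.atoms[donor_idx]
    out = []
    for i, a in enumerate(topology.atoms):
        if (
            a.chain_id == donor.chain_id
            and a.residue_seq == donor.residue_seq
            and a.element.upper() == "H"
            and np.linalg.norm(a.position - donor.position) < 1.3
        ):
            out.append(i)
    return out


def _amide_h_position(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray, bond: float = 1.01) -> np.ndarray:
    """Ideal amide hydrogen: 1.01 Å from N, opposed to the C_prev/CA bisector."""
    u1 = (n - c_prev) / np.linalg.norm(n - c_prev)
    u2 = (n - ca) / np.linalg.norm(n - ca)
    d = u1 + u2
    return n + bond * d / np.linalg.norm(d)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_occupancy(
    traj: Trajectory,
    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondOccupancy]:
    """Fraction of frames in which each donor/acceptor pair is bonded.

    A frame counts when the donor-acceptor distance is within the cutoff
    AND the donor-H-acceptor angle meets the minimum (the most favourable
    attached hydrogen is used). Explicit hydrogens are taken from the
    topology when present; for backbone amide donors without hydrogens an
    ideal H is constructed each frame from the local heavy-atom geometry.
    When no hydrogen exists or can be built, the distance criterion alone
    decides (documented fallback for coarse fixtures).
    """
    top = traj.topology
    atom_pos_index = {
        (a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(top.atoms)
    }

    results = []
    for donor_key, acceptor_key in pairs:
        if donor_key not in atom_pos_index:
            raise KeyError(f"donor atom {donor_key} not found in topology (pair {donor_key}->{acceptor_key})")
        if acceptor_key not in atom_pos_index:
            raise KeyError(f"acceptor atom {acceptor_key} not found in topology (pair {donor_key}->{acceptor_key})")
        di = atom_pos_index[donor_key]
        ai = atom_pos_index[acceptor_key]
        h_indices = _donor_hydrogen_indices(top, di)

        # backbone amide construction support
        prev_c = None
        if not h_indices and donor_key[2] == "N":
            try:
                prev_c = atom_pos_index[(donor_key[0], donor_key[1] - 1, "C")]
                ca_i = atom_pos_index[(donor_key[0], donor_key[1], "CA")]
            except KeyError:
                prev_c = None

        hits = 0
        for frame in traj.frames:
            d_pos, a_pos = frame[di], frame[ai]
            if np.linalg.norm(d_pos - a_pos) > criteria.max_donor_acceptor_distance:
                continue
            if h_indices:
                angle = max(_angle_deg(d_pos, frame[h], a_pos) for h in h_indices)
            elif prev_c is not None:
                h_pos = _amide_h_position(d_pos, frame[ca_i], frame[prev_c])
                angle = _angle_deg(d_pos, h_pos, a_pos)
            else:
                angle = 180.0  # no hydrogen available: distance-only criterion
            if angle >= criteria.min_dha_angle:
                hits += 1
        results.append(
            HBondOccupancy(donor=donor_key, acceptor=acceptor_key, occupancy=hits / len(traj.frames))
        )
    return results


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander hydrogen bonds, 4-bin collapse)
# ---------------------------------------------------------------------------

_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol·Å, electrostatic H-bond model constant
_KS_CUTOFF = -0.5           # kcal/mol; weaker contacts are not bonds


@dataclass
class SSContent:
    """Four-bin secondary structure fractions (sum to 1)."""

    helix: float
    sheet: float
    turn: float
    coil: float

    def __post_init__(self) -> None:
        total = self.helix + self.sheet + self.turn + self.coil
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return {"helix": self.helix, "sheet": self.sheet, "turn": self.turn, "coil": self.coil}


class _Residue:
    __slots__ = ("chain", "seq", "name", "n", "ca", "c", "o", "h", "complete")

    def __init__(self, chain, seq, name):
        self.chain, self.seq, self.name = chain, seq, name
        self.n = self.ca = self.c = self.o = self.h = None
        self.complete = False


def _collect_residues(structure: Structure) -> list[_Residue]:
    residues: list[_Residue] = []
    current: _Residue | None = None
    for a in structure.atoms:
        if current is None or (a.chain_id, a.residue_seq) != (current.chain, current.seq):
            current = _Residue(a.chain_id, a.residue_seq, a.residue_name)
            residues.append(current)
        if a.name == "N":
            current.n = a.position
        elif a.name == "CA":
            current.ca = a.position
        elif a.name == "C":
            current.c = a.position
        elif a.name == "O":
            current.o = a.position
        elif a.name in ("H", "HN") and current.h is None:
            current.h = a.position
    for r in residues:
        r.complete = all(x is not None for x in (r.n, r.ca, r.c, r.o))
    return residues


def _chain_connected(a: _Residue, b: _Residue) -> bool:
    # consecutive in the same chain, contiguous numbering, bonded distance
    if a.chain != b.chain or b.seq != a.seq + 1:
        return False
    if a.c is None or b.n is None:
        return False
    return bool(np.linalg.norm(b.n - a.c) < 2.5)


def _ks_energy(donor: _Residue, acceptor: _Residue) -> float:
    """Kabsch–Sander electrostatic energy of N-H(donor) ... C=O(acceptor)."""
    if donor.h is None or donor.n is None or acceptor.c is None or acceptor.o is None:
        return 0.0
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atom clash: treat as no bond
        return 0.0
    return _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(structure: Structure) -> list[str]:
    """Per-residue labels in {H, E, T, C} from backbone geometry alone.

    Backbone N-H...O=C hydrogen bonds are scored with the Kabsch–Sander
    electrostatic model (bond when E < -0.5 kcal/mol; amide hydrogens are
    constructed at ideal geometry when absent). Helices come from runs of
    i→i+4 (and i→i+3, i→i+5) turns, strands from parallel/antiparallel
    bridge ladders, turns from isolated 3/4/5-turns; everything else is
    coil. The 8-class internal states collapse as {H,G,I}→H, {E,B}→E,
    {T}→T, rest→C. Residues missing backbone atoms are labelled C.
    """
    residues = _collect_residues(structure)
    n_res = len(residues)
    if n_res == 0:
        raise ValueError("no residues")

    # ideal amide hydrogens where the file carries none (X-ray convention)
    for i in range(1, n_res):
        r, p = residues[i], residues[i - 1]
        if r.h is None and r.complete and r.name != "PRO" and _chain_connected(p, r):
            r.h = _amide_h_position(r.n, r.ca, p.c)

    # H-bond matrix: hbond[i][j] == True when N-H of i donates to C=O of j
    hbond = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        di = residues[i]
        if di.h is None or not di.complete:
            continue
        for j in range(n_res):
            if abs(i - j) < 2 and residues[i].chain == residues[j].chain:
                continue
            aj = residues[j]
            if not aj.complete:
                continue
            if np.linalg.norm(di.n - aj.o) > 5.2:  # KS energy is negligible beyond this
                continue
            if _ks_energy(di, aj) < _KS_CUTOFF:
                hbond[i, j] = True

    def connected_run(i: int, j: int) -> bool:
        return all(_chain_connected(residues[k], residues[k + 1]) for k in range(i, j))

    # n-turns: turn[n][i] true when C=O of i accepts from N-H of i+n
    turn = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if hbond[i + n, i] and connected_run(i, i + n):
                turn[n][i] = True

    eight = np.array(["-"] * n_res, dtype=object)

    # helices: two consecutive n-turns make an n-helix at i+1..i+n;
    # the alpha pattern is processed first and takes precedence
    for n, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n_res - n):
            if turn[n][i - 1] and turn[n][i]:
                for k in range(i, i + n):
                    if eight[k] == "-":
                        eight[k] = code

    # bridges (sheet): Kabsch–Sander parallel/antiparallel patterns
    is_bridge = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            same_chain = residues[i].chain == residues[j].chain
            if same_chain and j - i < 3:
                continue
            parallel = (hbond[i, j - 1] and hbond[j + 1, i]) or (hbond[j, i - 1] and hbond[i + 1, j])
            antiparallel = (hbond[i, j] and hbond[j, i]) or (hbond[i + 1, j - 1] and hbond[j + 1, i - 1])
            if parallel or antiparallel:
                is_bridge[i] = is_bridge[j] = True

    for i in range(n_res):
        if is_bridge[i] and eight[i] not in ("H",):
            eight[i] = "E"

    # turns: residues spanned by an isolated n-turn
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if turn[n][i]:
                for k in range(i + 1, i + n):
                    if eight[k] == "-":
                        eight[k] = "T"

    collapse = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E", "T": "T", "-": "C"}
    return [collapse[x] for x in eight]


def ss_content(labels: list[str]) -> SSContent:
    """Fractions of H/E/T/C labels; they sum to one exactly."""
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    unknown = set(counts) - {"H", "E", "T", "C"}
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    total = len(labels)
    return SSContent(
        helix=counts["H"] / total,
        sheet=counts["E"] / total,
        turn=counts["T"] / total,
        coil=counts["C"] / total,
    )
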