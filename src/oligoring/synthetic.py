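"""Deterministic synthetic fixtures for every stage of the pipeline.

Generators emulate the statistical and geometric structure the analysis
assumes — an idealized compact subunit with known secondary-structure
layout, annular bead clouds of known dimensions, trajectories with
scripted rigid motion / noise / hydrogen-bond schedules, and scattering
curves of known R_g — each with its ground truth carried alongside, so
tests never have to re-derive truth from the fixture itself.

Reproducibility: every stochastic generator derives its stream as
``np.random.default_rng([GENERATOR_CODE, seed])``, so adding a generator
never perturbs the output of existing ones for the same root seed.

Backbone construction uses ideal internal coordinates (N-CA 1.458 Å,
CA-C 1.525 Å, C-N 1.329 Å; angles 111.0/116.2/121.7°; trans peptide)
propagated by the standard internal-to-Cartesian (NeRF) recursion, which
is sufficient for secondary-structure assignment, swap bookkeeping and
ring geometry without any force field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saxs import ScatteringCurve
from .structures import Atom, MonomerStructure, Structure, Trajectory

__all__ = [
    "LabelledStructure",
    "HELIX",
    "SHEET",
    "build_backbone",
    "make_guinier_curve",
    "make_hollow_cylinder",
    "make_sphere_curve",
    "make_toy_monomer",
    "make_trajectory",
    "synthetic_cystatin_dimer",
    "synthetic_cystatin_monomer",
]

# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

_GENERATOR_CODES = {
    "toy_monomer": 11,
    "hollow_cylinder": 12,
    "trajectory": 13,
    "guinier_curve": 14,
}


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_GENERATOR_CODES[kind], int(seed)])


# ---------------------------------------------------------------------------
# ideal backbone builder
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.2, 121.7

HELIX = (-57.0, -47.0)          # canonical alpha torsions
SHEET = (-120.0, 120.0)         # gently pleated strand; pairs along its full length
HAIRPIN_TURN = [(60.0, -120.0), (-80.0, 0.0)]   # two-residue chain-reversal turn
LOOP = [(-70.0, 140.0), (-100.0, 60.0)]          # irregular coil torsion pair


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Position d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d) as given."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) from a φ/ψ list at ideal internal geometry."""
    if not phi_psi:
        raise ValueError("empty torsion list")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(phi_psi)):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca = _place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            u1 = r["C"] - r["CA"]
            u2 = r["C"] - res[i + 1]["N"]
            d = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        else:
            d = r["C"] - r["CA"]
        r["O"] = r["C"] + _B_C_O * d / np.linalg.norm(d)
    return res


def _residues_to_atoms(
    residues: list[dict[str, np.ndarray]],
    chain_id: str = "A",
    start_seq: int = 1,
    resname: str = "ALA",
    start_serial: int = 1,
) -> list[Atom]:
    atoms = []
    serial = start_serial - 1
    for i, r in enumerate(residues):
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    chain_id=chain_id,
                    residue_seq=start_seq + i,
                    residue_name=resname,
                    position=r[name],
                )
            )
    return atoms


def _principal_rotation(coords: np.ndarray) -> np.ndarray:
    """Rotation whose rows map largest→x, middle→y, smallest→z spread."""
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    return rot


def _align_piece(residues: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    coords = np.array([r[n] for r in residues for n in ("N", "CA", "C", "O")])
    rot = _principal_rotation(coords)
    centre = coords.mean(axis=0)
    return [{k: rot @ (v - centre) for k, v in r.items()} for r in residues]


def _translate(residues, offset):
    return [{k: v + offset for k, v in r.items()} for r in residues]


# ---- coil paths -----------------------------------------------------------

def _backbone_from_ca_path(
    cas: list[np.ndarray],
    prev_anchor: np.ndarray | None = None,
    next_anchor: np.ndarray | None = None,
) -> list[dict[str, np.ndarray]]:
    """Approximate backbone for a coil given its CA positions.

    N and C sit along the local chain direction with offsets that leave
    near-bonded C-N separations; carbonyl O alternates above/below the
    local plane so the coil cannot masquerade as regular structure.
    """
    ext = ([prev_anchor] if prev_anchor is not None else []) + list(cas) + (
        [next_anchor] if next_anchor is not None else []
    )
    lo = 1 if prev_anchor is not None else 0
    out = []
    for i, ca in enumerate(cas):
        j = i + lo
        u_in = ext[j] - ext[j - 1] if j - 1 >= 0 else ext[j + 1] - ext[j]
        u_out = ext[j + 1] - ext[j] if j + 1 < len(ext) else u_in
        d_in, d_out = np.linalg.norm(u_in), np.linalg.norm(u_out)
        u_in, u_out = u_in / d_in, u_out / d_out
        off_in = max((d_in - _B_C_N) / 2.0, 0.9)
        off_out = max((d_out - _B_C_N) / 2.0, 0.9)
        w = np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0])
        out.append(
            {
                "N": ca - off_in * u_in,
                "CA": ca,
                "C": ca + off_out * u_out,
                "O": ca + off_out * u_out + _B_C_O * w,
            }
        )
    return out


def _bezier_path(start: np.ndarray, end: np.ndarray, n: int, step: float, lateral: np.ndarray) -> list[np.ndarray]:
    """n points along a quadratic Bézier whose length matches (n+1)·step."""
    need = (n + 1) * step
    direct = np.linalg.norm(end - start)
    mid = (start + end) / 2.0

    def sample(bow):
        ctrl = mid + bow * lateral
        ts = np.linspace(0, 1, 256)
        pts = (
            np.outer((1 - ts) ** 2, start) + np.outer(2 * (1 - ts) * ts, ctrl) + np.outer(ts**2, end)
        )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        return pts, arc

    bow_lo, bow_hi = 0.0, max(need, direct)
    for _ in range(40):
        bow = (bow_lo + bow_hi) / 2.0
        pts, arc = sample(bow)
        if arc[-1] < need:
            bow_lo = bow
        else:
            bow_hi = bow
    pts, arc = sample((bow_lo + bow_hi) / 2.0)
    targets = np.linspace(0, arc[-1], n + 2)[1:-1]
    return [pts[np.searchsorted(arc, t)] for t in targets]


def _serpentine(
    start: np.ndarray,
    n: int,
    step: float,
    x_limits: tuple[float, float],
    row_spacing: float,
    rng: np.random.Generator,
    direction: int = 1,
    row_direction: int = -1,
) -> list[np.ndarray]:
    """A boustrophedon CA path filling rows of a planar box."""
    pts = []
    x, y, z = start
    d = direction
    while len(pts) < n:
        x_new = x + d * step
        if x_new > x_limits[1] or x_new < x_limits[0]:
            y += row_direction * row_spacing
            d = -d
            x_new = x
        x = x_new
        jitter = rng.normal(0.0, 0.15, size=3)
        pts.append(np.array([x, y, z]) + jitter)
    return pts


# ---------------------------------------------------------------------------
# toy monomer
# ---------------------------------------------------------------------------

@dataclass
class LabelledStructure:
    """A generated structure with its designed per-residue SS ground truth."""

    structure: Structure
    ss_truth: list[str]
    layout: dict[str, int]


def _allocate_blocks(n: int) -> dict[str, int]:
    blocks = {
        "head": max(2, round(0.05 * n)),
        "helix": max(5, round(0.18 * n)),
        "loop": max(3, round(0.066 * n)),
        "strand": max(4, round(0.13 * n)),
    }
    used = lambda: blocks["head"] + blocks["helix"] + blocks["loop"] + 2 * blocks["strand"] + 2
    while used() > n - 2:
        largest = max(("helix", "strand", "loop", "head"), key=lambda k: blocks[k])
        blocks[largest] -= 1
    blocks["tail"] = n - used()
    return blocks


def make_toy_monomer(n_residues: int = 120, seed: int = 0) -> LabelledStructure:
    """A flat, slab-like idealized subunit with known SS layout.

    Residue order: coil head — α-helix — connecting loop — two-strand
    antiparallel hairpin — coil tail, all arranged in a plane roughly
    55 x 35 x 12 Å at the default size, emulating the footprint of a
    small globular subunit seen edge-on. The flat shape is what makes
    rings built from this monomer reproduce the thin doughnut geometry
    of the experimental oligomers. Ground-truth labels follow the design:
    helix H, strands E, hairpin turn T, everything else C.
    """
    if n_residues < 20:
        raise ValueError(f"need at least 20 residues, got {n_residues}")
    rng = _rng("toy_monomer", seed)
    blocks = _allocate_blocks(n_residues)

    # hairpin: continuous build, aligned into the xy-plane, strand axis x
    hp_tors = [SHEET] * blocks["strand"] + HAIRPIN_TURN + [SHEET] * blocks["strand"]
    hairpin = _align_piece(build_backbone(hp_tors))
    # put the open (N/C-terminal) end of the hairpin at -x
    if hairpin[0]["CA"][0] > hairpin[blocks["strand"]]["CA"][0]:
        hairpin = [{k: v * np.array([-1.0, -1.0, 1.0]) for k, v in r.items()} for r in hairpin]
    hp_ca = np.array([r["CA"] for r in hairpin])
    hp_x_min, hp_x_max = hp_ca[:, 0].min(), hp_ca[:, 0].max()
    hp_y_max = hp_ca[:, 1].max()

    # helix: aligned along x, C-terminal end at -x, shifted above the hairpin
    helix = _align_piece(build_backbone([HELIX] * blocks["helix"]))
    if helix[-1]["CA"][0] > helix[0]["CA"][0]:
        helix = [{k: v * np.array([-1.0, -1.0, 1.0]) for k, v in r.items()} for r in helix]
    helix = _translate(helix, np.array([0.0, hp_y_max + 11.0, 0.0]))
    helix_n_ca = helix[0]["CA"]
    helix_c_ca = helix[-1]["CA"]

    # head coil: rows above the helix, ending one bonded step before its N
    head_path = _serpentine(
        helix_n_ca + np.array([0.0, 5.0, 0.0]),
        blocks["head"],
        3.35,
        (hp_x_min, hp_x_max),
        5.0,
        rng,
        direction=1,
        row_direction=1,
    )
    head_path.reverse()  # chain runs toward the helix
    head = _backbone_from_ca_path(head_path, next_anchor=helix_n_ca)

    # connecting loop: helix C-terminus -> hairpin N-terminus
    loop_path = _bezier_path(
        helix_c_ca, hairpin[0]["CA"], blocks["loop"], 3.35, np.array([-0.2, 0.4, 0.9])
    )
    loop = _backbone_from_ca_path(loop_path, prev_anchor=helix_c_ca, next_anchor=hairpin[0]["CA"])

    # tail coil: rows below the hairpin
    if blocks["tail"] > 0:
        tail_path = _serpentine(
            hairpin[-1]["CA"] + np.array([0.0, -5.0, 0.0]),
            blocks["tail"],
            3.35,
            (hp_x_min, hp_x_max),
            5.0,
            rng,
            direction=1,
            row_direction=-1,
        )
        tail = _backbone_from_ca_path(tail_path, prev_anchor=hairpin[-1]["CA"])
    else:
        tail = []

    residues = head + helix + loop + hairpin + tail
    atoms = _residues_to_atoms(residues)
    truth = (
        ["C"] * blocks["head"]
        + ["H"] * blocks["helix"]
        + ["C"] * blocks["loop"]
        + ["E"] * blocks["strand"]
        + ["T"] * 2
        + ["E"] * blocks["strand"]
        + ["C"] * blocks["tail"]
    )
    return LabelledStructure(structure=MonomerStructure(atoms), ss_truth=truth, layout=blocks)


# ---------------------------------------------------------------------------
# cystatin-fold stand-ins (synthetic: the real crystal structures are not
# bundled; these reproduce the fold's published composition, not its fold)
# ---------------------------------------------------------------------------

def _cystatin_monomer_torsions() -> tuple[list[tuple[float, float]], list[str]]:
    tors: list[tuple[float, float]] = []
    truth: list[str] = []

    def add(tt, labels):
        tors.extend(tt)
        truth.extend(labels)

    add(LOOP * 3, "C" * 6)
    add([HELIX] * 22, "H" * 22)
    add(LOOP * 3, "C" * 6)
    for i in range(5):
        add([SHEET] * 11, "E" * 11)
        if i < 4:
            add(HAIRPIN_TURN, "TT")
    add(LOOP * 2, "C" * 4)
    add(HAIRPIN_TURN, "TT")
    add(LOOP * 2, "C" * 4)
    add([HELIX] * 3, "TTT")  # isolated single alpha-turn reads as turn
    add(LOOP * 5, "C" * 10)
    return tors, truth


def synthetic_cystatin_monomer() -> LabelledStructure:
    """Synthetic stand-in for the 120-residue cystatin C monomer fold.

    A deterministic idealized chain whose designed secondary-structure
    layout — one ~20-residue α-helix against a five-stranded antiparallel
    sheet plus turns — reproduces the composition reported for the
    monomer crystal structure (≈17% helix, 45% sheet, 11% turn, 27%
    coil). It is a composition stand-in, not a model of the real fold:
    use it where only secondary-structure statistics matter.
    """
    tors, truth = _cystatin_monomer_torsions()
    atoms = _residues_to_atoms(build_backbone(tors))
    return LabelledStructure(structure=MonomerStructure(atoms), ss_truth=truth, layout={"n": len(tors)})


def _cystatin_dimer_chain_torsions() -> tuple[list[tuple[float, float]], list[str]]:
    tors: list[tuple[float, float]] = []
    truth: list[str] = []

    def add(tt, labels):
        tors.extend(tt)
        truth.extend(labels)

    add(LOOP * 2 + LOOP[:1], "C" * 5)
    add([HELIX] * 24, "H" * 24)
    add(LOOP[:1], "C")
    for i in range(4):
        add([SHEET] * 11, "E" * 11)
        if i < 3:
            add(HAIRPIN_TURN, "TT")
    for _ in range(4):
        add(LOOP, "CC")
        add(HAIRPIN_TURN, "TT")
    add(LOOP * 2, "C" * 4)
    for _ in range(3):
        add([HELIX] * 3, "TTT")
        add(LOOP * 2, "C" * 4)
    return tors, truth


def synthetic_cystatin_dimer() -> LabelledStructure:
    """Synthetic stand-in for the domain-swapped cystatin C dimer.

    Two identical idealized chains (far apart, so assignment sees two
    independent monomers) whose designed layout reproduces the dimer's
    published composition (≈18% helix, 36% sheet, 19% turn, 27% coil) —
    relative to the monomer, part of the sheet is traded for turns, the
    signature of the partially unwound domain-swapped subunit. Again a
    composition stand-in only.
    """
    tors, truth = _cystatin_dimer_chain_torsions()
    residues = build_backbone(tors)
    atoms = _residues_to_atoms(residues, chain_id="A")
    atoms += _residues_to_atoms(
        _translate(residues, np.array([200.0, 0.0, 0.0])), chain_id="B", start_serial=len(atoms) + 1
    )
    return LabelledStructure(structure=Structure(atoms), ss_truth=truth + truth, layout={"n_per_chain": len(tors)})


# ---------------------------------------------------------------------------
# bead models and trajectories
# ---------------------------------------------------------------------------

def make_hollow_cylinder(
    outer_radius: float,
    inner_radius: float,
    height: float,
    n_beads: int,
    seed: int = 0,
) -> np.ndarray:
    """Beads uniform in an annular cylinder volume (rejection sampling), Å.

    The fixture realizes the uniform-density doughnut whose closed-form
    R_g the geometry module computes; its coordinate R_g converges to
    that value as the bead count grows.
    """
    if not outer_radius >= inner_radius >= 0:
        raise ValueError("need outer_radius >= inner_radius >= 0")
    if height < 0:
        raise ValueError("height must be >= 0")
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = _rng("hollow_cylinder", seed)
    out = np.empty((n_beads, 3))
    filled = 0
    while filled < n_beads:
        m = 2 * (n_beads - filled) + 16
        xy = rng.uniform(-outer_radius, outer_radius, size=(m, 2))
        r2 = np.sum(xy**2, axis=1)
        ok = (r2 <= outer_radius**2) & (r2 >= inner_radius**2)
        take = min(int(ok.sum()), n_beads - filled)
        out[filled : filled + take, :2] = xy[ok][:take]
        filled += take
    out[:, 2] = rng.uniform(-height / 2.0, height / 2.0, size=n_beads) if height > 0 else 0.0
    return out


def make_trajectory(
    base: Structure,
    n_frames: int,
    rigid_motion=None,
    noise_sigma: float = 0.0,
    hbond_schedule: dict | None = None,
    seed: int = 0,
) -> Trajectory:
    """Scripted trajectory over a fixed topology.

    Frame i applies ``rigid_motion(i) -> (R, t)`` (default identity) to the
    base coordinates and adds i.i.d. Gaussian noise of width noise_sigma Å.
    ``hbond_schedule`` maps (donor_key, acceptor_key) — keys are
    (chain, residue, atom) triples — to a boolean mask over frames: on
    scheduled frames the acceptor atom is placed 2.9 Å from the donor
    (inside usual geometric criteria), otherwise 10 Å away, overriding
    motion and noise for that atom.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = _rng("trajectory", seed)
    coords0 = base.coords
    index = {(a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(base.atoms)}

    schedule = {}
    if hbond_schedule:
        for (donor_key, acceptor_key), mask in hbond_schedule.items():
            mask = np.asarray(mask, dtype=bool)
            if len(mask) > n_frames:
                raise ValueError(
                    f"schedule for {donor_key}->{acceptor_key} has {len(mask)} entries > {n_frames} frames"
                )
            full = np.zeros(n_frames, dtype=bool)
            full[: len(mask)] = mask
            # along the donor's amide-H direction when constructible, so the
            # placed acceptor satisfies the angle criterion in any frame
            chain, res, name = donor_key
            aux = None
            if name == "N" and (chain, res - 1, "C") in index and (chain, res, "CA") in index:
                aux = (index[(chain, res - 1, "C")], index[(chain, res, "CA")])
            schedule[(index[donor_key], index[acceptor_key])] = (full, aux)

    frames = []
    for i in range(n_frames):
        if rigid_motion is not None:
            rot, trans = rigid_motion(i)
            frame = coords0 @ np.asarray(rot, dtype=float).T + np.asarray(trans, dtype=float)
        else:
            frame = coords0.copy()
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        for (di, ai), (mask, aux) in schedule.items():
            if aux is not None:
                c_prev, ca = frame[aux[0]], frame[aux[1]]
                direction = _amide_direction(frame[di], ca, c_prev)
            else:
                direction = np.array([1.0, 0.0, 0.0])
            frame[ai] = frame[di] + (2.9 if mask[i] else 10.0) * direction
        frames.append(frame)
    return Trajectory(topology=base, frames=frames)


def _amide_direction(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    u1 = (n - c_prev) / np.linalg.norm(n - c_prev)
    u2 = (n - ca) / np.linalg.norm(n - ca)
    d = u1 + u2
    return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# scattering curves
# ---------------------------------------------------------------------------

def _default_s_grid() -> np.ndarray:
    return np.linspace(0.02, 0.6, 80)


def make_guinier_curve(
    rg: float,
    i0: float = 1.0,
    s_grid: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """Exact Guinier-law curve I(s) = I0 exp(-s²R_g²/3), optionally noisy.

    Multiplicative Gaussian noise of relative width ``noise_fraction``;
    the sigma column is noise_fraction·I, as a reduced data file would
    report. R_g in nm, s in nm⁻¹.
    """
    if rg <= 0:
        raise ValueError("rg must be > 0")
    s = _default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    ideal = i0 * np.exp(-(s**2) * rg**2 / 3.0)
    if noise_fraction > 0:
        rng = _rng("guinier_curve", seed)
        intensity = ideal * (1.0 + rng.normal(0.0, noise_fraction, size=len(s)))
        return ScatteringCurve(s=s, intensity=intensity, sigma=noise_fraction * ideal)
    return ScatteringCurve(s=s, intensity=ideal)


def make_sphere_curve(radius: float, s_grid: np.ndarray | None = None) -> ScatteringCurve:
    """Exact form factor of a homogeneous sphere, normalized to I(0) = 1.

    I(s) = [3 (sin x - x cos x) / x³]² with x = s·R; its Guinier region
    encodes R_g = sqrt(3/5)·R, making it an analytic oracle for the
    Guinier fit. First minimum at x ≈ 4.493 (the root of tan x = x).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    s = _default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    x = s * radius
    amp = np.ones_like(x)
    nz = x > 1e-8
    amp[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return ScatteringCurve(s=s, intensity=amp**2)
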