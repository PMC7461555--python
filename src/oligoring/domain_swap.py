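"""Cyclic intermolecular domain swap and gap rebuilding.

Cystatin C oligomerizes by three-dimensional domain swapping: the
N-terminal segment (residues 1-58, ending at the L1 loop) of one subunit
replaces the equivalent segment of its neighbour, reconstituting the
monomer fold across two chains. In a closed ring this exchange is cyclic —
every subunit donates its segment to the next one around the ring.

The swap here is a pure relabeling of chain ownership: no coordinate
changes. In the original modelling protocol the broken 58/59 backbone
connection was subsequently relaxed by restrained molecular dynamics;
since dynamics is out of scope, the across-junction C(58)-N(59) distance
is reported as a quality metric instead of being minimized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import Atom, MonomerStructure, RingAssembly, Structure

__all__ = [
    "JunctionEntry",
    "JunctionReport",
    "SwapSpec",
    "apply_cyclic_swap",
    "junction_report",
    "rebuild_missing_segment",
]


@dataclass(frozen=True)
class SwapSpec:
    """Which segment moves where.

    junction  : ordered residue pair whose backbone bond is broken;
                (58, 59) for cystatin C.
    segment   : inclusive residue range transferred between subunits;
                must end exactly at the first junction residue.
    direction : 'successor' — the tail (residues after the junction) of
                chain k+1 completes the head of chain k, i.e. chain k
                donates its N-terminal segment to the ring neighbour;
                'predecessor' reverses the sense. The underlying physics
                does not distinguish the two.
    """

    junction: tuple[int, int] = (58, 59)
    segment: tuple[int, int] = (1, 58)
    direction: str = "successor"

    def __post_init__(self) -> None:
        if self.junction[1] != self.junction[0] + 1:
            raise ValueError(f"junction residues must be sequence-adjacent, got {self.junction}")
        if self.segment[1] != self.junction[0]:
            raise ValueError(
                f"segment must end at the first junction residue: segment {self.segment}, junction {self.junction}"
            )
        if self.direction not in ("successor", "predecessor"):
            raise ValueError(f"direction must be 'successor' or 'predecessor', got {self.direction!r}")


def _split_chain(assembly: Structure, chain_id: str, spec: SwapSpec) -> tuple[list[Atom], list[Atom]]:
    """Partition one chain into (head = segment, tail = rest after junction)."""
    residues = {r for r, _ in assembly.residues(chain_id)}
    for res in spec.junction:
        if res not in residues:
            raise ValueError(f"chain {chain_id!r} lacks junction residue {res}; cannot swap")
    head = [a for a in assembly.chain_atoms(chain_id) if a.residue_seq <= spec.junction[0]]
    tail = [a for a in assembly.chain_atoms(chain_id) if a.residue_seq >= spec.junction[1]]
    return head, tail


def apply_cyclic_swap(assembly: RingAssembly, spec: SwapSpec = SwapSpec()) -> RingAssembly:
    """Rewire chain ownership so each output chain spans two input subunits.

    Output chain k keeps residues ``segment`` of input chain k and adopts
    the post-junction residues of the neighbouring input chain; applying
    the swap n times restores the original partition (it is the n-cycle
    permutation on segment ownership). Atom coordinates are untouched.
    """
    chain_ids = assembly.chain_ids()
    n = len(chain_ids)
    if n < 2:
        raise ValueError("cyclic swap undefined for a single-chain assembly")

    parts = {cid: _split_chain(assembly, cid, spec) for cid in chain_ids}
    step = 1 if spec.direction == "successor" else -1

    atoms: list[Atom] = []
    serial = 0
    for k, cid in enumerate(chain_ids):
        donor = chain_ids[(k + step) % n]
        for src in parts[cid][0] + parts[donor][1]:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=src.name,
                    element=src.element,
                    chain_id=cid,
                    residue_seq=src.residue_seq,
                    residue_name=src.residue_name,
                    position=src.position.copy(),
                    insertion_code=src.insertion_code,
                    occupancy=src.occupancy,
                    b_factor=src.b_factor,
                )
            )

    return RingAssembly(
        atoms,
        n_subunits=assembly.n_subunits,
        transforms=None,  # chains are no longer rigid copies of the template
        symmetry_axis=None if assembly.symmetry_axis is None else assembly.symmetry_axis.copy(),
        disulfides=list(assembly.disulfides),
    )


@dataclass
class JunctionEntry:
    chain: str
    donor_chain: str
    acceptor_chain: str
    distance_A: float


@dataclass
class JunctionReport:
    """Across-junction C-N distances, one entry per composite chain."""

    junction: tuple[int, int]
    entries: list[JunctionEntry]

    @property
    def distances(self) -> np.ndarray:
        return np.array([e.distance_A for e in self.entries])

    @property
    def min(self) -> float:
        return float(self.distances.min())

    @property
    def max(self) -> float:
        return float(self.distances.max())

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "junction": list(self.junction),
            "entries": [e.__dict__ for e in self.entries],
            "summary": {"min_A": self.min, "max_A": self.max, "mean_A": self.mean},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def junction_report(assembly: Structure, spec: SwapSpec = SwapSpec(), donors: dict[str, str] | None = None) -> JunctionReport:
    """Measure the C(j1)-N(j2) backbone distance within every chain.

    On an intact monomer this is the peptide-bond length (~1.33 Å in
    crystal geometry); on a freshly swapped ring it quantifies how far the
    relabeled junction is from a bonded backbone, i.e. how much relaxation
    the ring would need.
    """
    entries = []
    for cid in assembly.chain_ids():
        try:
            c_atom = assembly.find_atom(cid, spec.junction[0], "C")
            n_atom = assembly.find_atom(cid, spec.junction[1], "N")
        except KeyError as exc:
            raise ValueError(f"chain {cid!r}: missing backbone atom at junction {spec.junction}: {exc}") from exc
        d = float(np.linalg.norm(c_atom.position - n_atom.position))
        donor = donors.get(cid, cid) if donors else cid
        entries.append(JunctionEntry(chain=cid, donor_chain=cid, acceptor_chain=donor, distance_A=d))
    return JunctionReport(junction=spec.junction, entries=entries)


# ---------------------------------------------------------------------------
# Rebuilding crystallographically missing segments
# ---------------------------------------------------------------------------

_IDEAL_N_CA = 1.46
_IDEAL_CA_C = 1.52
_IDEAL_C_O = 1.23
_IDEAL_CA_CB = 1.53
_MIN_CA_STEP = 2.8
_MAX_CA_STEP = 4.2


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = np.cross(u, ref)
    return w / np.linalg.norm(w)


def _bowed_ca_path(p0: np.ndarray, p1: np.ndarray, m: int) -> list[np.ndarray]:
    """CA positions for m inserted residues between anchors p0, p1.

    Straight-line interpolation when the implied step is stereochemically
    plausible; when the anchors are too close the path bows onto a
    circular arc with m+1 equal chords of ~3.2 Å, which always exists
    as long as the straight-line step does not exceed the chord length.
    """
    d = float(np.linalg.norm(p1 - p0))
    step = d / (m + 1)
    if step > _MAX_CA_STEP:
        raise ValueError(
            f"gap too wide to rebuild by interpolation: implied CA step {step:.2f} Å > {_MAX_CA_STEP} Å"
        )
    if step >= _MIN_CA_STEP:
        return [p0 + (i + 1) / (m + 1) * (p1 - p0) for i in range(m)]

    chord = 3.2  # comfortable mid-range CA-CA distance, Å
    u = (p1 - p0) / d if d > 1e-9 else np.array([1.0, 0.0, 0.0])
    w = _perpendicular(u)
    # m+1 equal chords of length `chord` on a circle whose span chord is d:
    # solve sin((m+1)φ)/sin(φ) = d/chord for the half-angle per chord φ
    ratio = d / chord
    lo, hi = 1e-9, np.pi / (m + 1) - 1e-9
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if np.sin((m + 1) * mid) / np.sin(mid) > ratio:
            lo = mid
        else:
            hi = mid
    phi = (lo + hi) / 2.0
    radius = chord / (2.0 * np.sin(phi))
    h = np.sqrt(max(radius**2 - (d / 2.0) ** 2, 0.0))
    centre_2d = np.array([d / 2.0, h])
    a0 = np.arctan2(0.0 - h, 0.0 - d / 2.0)
    # choose the sweep direction whose endpoint lands back on p1
    for sign in (+1.0, -1.0):
        a_end = a0 + sign * 2.0 * (m + 1) * phi
        end = centre_2d + radius * np.array([np.cos(a_end), np.sin(a_end)])
        if np.linalg.norm(end - np.array([d, 0.0])) < 1e-6 * max(d, 1.0) + 1e-9:
            break
    pts = []
    for i in range(1, m + 1):
        a = a0 + sign * 2.0 * phi * i
        xy = centre_2d + radius * np.array([np.cos(a), np.sin(a)])
        pts.append(p0 + xy[0] * u + xy[1] * w)
    return pts


def rebuild_missing_segment(
    structure: Structure,
    gap: tuple[int, int] | None = None,
    chain_id: str | None = None,
    residue_names: list[str] | None = None,
) -> Structure:
    """Insert backbone atoms for a crystallographically unresolved segment.

    The stab-1 cystatin C monomer entry 3GAX lacks electron density for
    Pro78-Asn79; completing the chain before ring building keeps every
    subunit's numbering contiguous. Inserted residues receive N, CA, C, O
    (and CB for non-glycine) at ideal local geometry along an interpolated
    CA path; side chains beyond CB are not modelled. A structure with no
    recorded gaps is returned unchanged (as a copy).

    gap is an inclusive missing residue range; by default the first
    recorded missing segment of the (first) chain is rebuilt. Terminal
    gaps are rejected — extension beyond the resolved chain is a different
    problem than interpolation between anchors.
    """
    out = structure.copy()
    if chain_id is None:
        chain_id = out.chain_ids()[0]
    if gap is None:
        chain_gaps = out.missing_segments.get(chain_id, [])
        if not chain_gaps:
            return out
        gap = chain_gaps[0]
    start, end = gap
    m = end - start + 1
    if m < 1:
        raise ValueError(f"empty gap range {gap}")

    present = {r for r, _ in out.residues(chain_id)}
    if (start - 1) not in present or (end + 1) not in present:
        raise ValueError(
            f"gap {gap} in chain {chain_id!r} is not flanked by resolved residues on both sides; "
            "terminal extension is unsupported"
        )

    ca_prev = out.find_atom(chain_id, start - 1, "CA").position
    ca_next = out.find_atom(chain_id, end + 1, "CA").position
    ca_path = _bowed_ca_path(ca_prev, ca_next, m)

    if residue_names is None:
        residue_names = ["ALA"] * m
    if len(residue_names) != m:
        raise ValueError(f"residue_names must have {m} entries, got {len(residue_names)}")

    full_path = [ca_prev] + ca_path + [ca_next]
    w = _perpendicular((ca_next - ca_prev) / np.linalg.norm(ca_next - ca_prev))
    new_atoms: list[Atom] = []
    for i, (ca, resname) in enumerate(zip(ca_path, residue_names)):
        res_seq = start + i
        # N and C sit along the local chain direction, offset so the
        # peptide C(i)-N(i+1) separation comes out near the 1.33 Å bond
        u_in = ca - full_path[i]
        u_in /= np.linalg.norm(u_in)
        u_out = full_path[i + 2] - ca
        step_out = np.linalg.norm(u_out)
        u_out /= step_out
        off_in = (np.linalg.norm(ca - full_path[i]) - 1.33) / 2.0
        off_out = (step_out - 1.33) / 2.0
        positions = {
            "N": ca - off_in * u_in,
            "CA": ca,
            "C": ca + off_out * u_out,
            "O": ca + off_out * u_out + _IDEAL_C_O * w,
        }
        if resname != "GLY":
            positions["CB"] = ca - _IDEAL_CA_CB * w
        for name, pos in positions.items():
            new_atoms.append(
                Atom(
                    serial=0,
                    name=name,
                    element=name[0],
                    chain_id=chain_id,
                    residue_seq=res_seq,
                    residue_name=resname,
                    position=pos,
                )
            )

    # splice: after the last atom of residue start-1 within the chain
    insert_at = max(
        i for i, a in enumerate(out.atoms) if a.chain_id == chain_id and a.residue_seq == start - 1
    ) + 1
    atoms = out.atoms[:insert_at] + new_atoms + out.atoms[insert_at:]
    for serial, atom in enumerate(atoms, start=1):
        atom.serial = serial

    cls = MonomerStructure if isinstance(structure, MonomerStructure) else Structure
    return cls(atoms, disulfides=list(out.disulfides))
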