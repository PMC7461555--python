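"""Macromolecular coordinate containers and PDB input/output.

The containers keep author residue numbering untouched (human cystatin C is
numbered 1-120), so residue references that matter to the domain-swap model
— the 58/59 junction, the engineered 47-69 disulfide, the 78-79 gap in the
monomer crystal structure — stay literal throughout the pipeline.

Parsing is delegated to :mod:`gemmi`; writing emits fixed-width wwPDB v3.3
columns. Multi-model PDB files are the trajectory container.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "MonomerStructure",
    "RingAssembly",
    "Structure",
    "Trajectory",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """One atom record, PDB conventions (coordinates in Å)."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_seq: int
    residue_name: str
    position: np.ndarray
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} ({self.name}): position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} ({self.name}): occupancy {self.occupancy} outside [0, 1]")


class Structure:
    """An ordered collection of atoms with chain/residue bookkeeping.

    ``missing_segments`` maps chain id to inclusive residue ranges absent
    from the coordinates (detected from numbering discontinuities), and
    ``disulfides`` records engineered bridges such as the stabilizing
    L47C-G69C pair of stab-1 cystatin C.
    """

    def __init__(
        self,
        atoms: list[Atom],
        disulfides: list[tuple[int, int]] | None = None,
        missing_segments: dict[str, list[tuple[int, int]]] | None = None,
    ) -> None:
        if not atoms:
            raise ValueError("empty structure: no atoms")
        self.atoms = list(atoms)
        self.disulfides = list(disulfides or [])
        self.missing_segments = (
            missing_segments if missing_segments is not None else detect_missing_segments(self.atoms)
        )

    # ---- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} != ({len(self.atoms)}, 3)")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise KeyError(f"no chain {chain_id!r} in structure (chains: {self.chain_ids()})")
        return atoms

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        """Ordered (residue_seq, residue_name) pairs of one chain."""
        out: list[tuple[int, str]] = []
        for a in self.chain_atoms(chain_id):
            key = (a.residue_seq, a.residue_name)
            if not out or out[-1] != key:
                out.append(key)
        return out

    def residue_atoms(self, chain_id: str, residue_seq: int) -> list[Atom]:
        atoms = [a for a in self.chain_atoms(chain_id) if a.residue_seq == residue_seq]
        if not atoms:
            raise KeyError(f"chain {chain_id!r} has no residue {residue_seq}")
        return atoms

    def find_atom(self, chain_id: str, residue_seq: int, name: str) -> Atom:
        for a in self.residue_atoms(chain_id, residue_seq):
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {chain_id}/{residue_seq}")

    def atom_indices(self, predicate) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    # ---- sequences ---------------------------------------------------

    def sequence_of(self, chain_id: str) -> str:
        """One-letter sequence of a chain; non-standard residues map to X."""
        return "".join(THREE_TO_ONE.get(name, "X") for _, name in self.residues(chain_id))


class MonomerStructure(Structure):
    """A single-subunit structure (one chain)."""


class RingAssembly(Structure):
    """n rigid subunit copies sharing a symmetry axis.

    ``transforms`` holds per-subunit (rotation, translation) pairs when the
    assembly was built parametrically; externally loaded assemblies carry
    ``None`` and measurement code recovers the axis from the coordinates.
    """

    def __init__(
        self,
        atoms: list[Atom],
        n_subunits: int,
        transforms: list[tuple[np.ndarray, np.ndarray]] | None = None,
        symmetry_axis: np.ndarray | None = None,
        **kwargs,
    ) -> None:
        if n_subunits < 1:
            raise ValueError(f"n_subunits must be >= 1, got {n_subunits}")
        super().__init__(atoms, **kwargs)
        self.n_subunits = n_subunits
        self.transforms = transforms
        self.symmetry_axis = None if symmetry_axis is None else np.asarray(symmetry_axis, dtype=float)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology (Å; times in ns)."""

    topology: Structure
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {i} has shape {f.shape}, expected ({n}, 3)")

    def __len__(self) -> int:
        return len(self.frames)


def detect_missing_segments(atoms: list[Atom]) -> dict[str, list[tuple[int, int]]]:
    """Missing residue ranges per chain, from numbering discontinuities.

    A jump from residue a to residue b > a + 1 within one chain records the
    inclusive range (a+1, b-1) as unresolved — e.g. the Pro78-Asn79 segment
    lacking electron density in the stab-1 cystatin C monomer entry 3GAX.
    """
    gaps: dict[str, list[tuple[int, int]]] = {}
    by_chain: dict[str, list[int]] = {}
    for a in atoms:
        seq = by_chain.setdefault(a.chain_id, [])
        if not seq or seq[-1] != a.residue_seq:
            seq.append(a.residue_seq)
    for chain_id, seq in by_chain.items():
        chain_gaps = [(a + 1, b - 1) for a, b in zip(seq, seq[1:]) if b > a + 1]
        if chain_gaps:
            gaps[chain_id] = chain_gaps
    return gaps


# ---------------------------------------------------------------------------
# PDB reading (via gemmi)
# ---------------------------------------------------------------------------

def _atoms_from_model(model: "gemmi.Model") -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for at in residue:
                if at.altloc not in ("", "\x00", "A"):  # keep the first conformer only
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        residue_name=residue.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        insertion_code=residue.seqid.icode.strip(),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                    )
                )
    return atoms


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`MonomerStructure` or :class:`RingAssembly`.

    Single-chain files give a monomer; multi-chain files an assembly with one
    subunit per chain. Only the first model of a multi-model file is read
    (use :func:`read_trajectory` for the rest). Altloc conformers other than
    '' / 'A' are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    atoms = _atoms_from_model(st[0])
    if not atoms:
        raise ValueError(f"{path}: no ATOM records")
    chains = {a.chain_id for a in atoms}
    if len(chains) == 1:
        return MonomerStructure(atoms)
    return RingAssembly(atoms, n_subunits=len(chains))


def read_trajectory(path: str | Path, topology: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Frames are ordered by MODEL number. All models must contain the same
    number of atoms; ``topology`` defaults to the first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    per_model = [_atoms_from_model(m) for m in st]
    counts = {len(m) for m in per_model}
    if len(counts) != 1:
        raise ValueError(f"{path}: inconsistent atom counts across models: {sorted(counts)}")
    if topology is None:
        atoms = per_model[0]
        chains = {a.chain_id for a in atoms}
        topology = MonomerStructure(atoms) if len(chains) == 1 else RingAssembly(atoms, n_subunits=len(chains))
    elif len(topology) != len(per_model[0]):
        raise ValueError(f"topology has {len(topology)} atoms, file models have {len(per_model[0])}")
    frames = [np.array([a.position for a in m]) for m in per_model]
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# PDB writing (fixed-width wwPDB v3.3 columns)
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # one-letter elements start in column 14 unless the name is 4 chars wide
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: Atom, serial: int, coords: np.ndarray) -> str:
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(atom.name, atom.element)} "
        f"{atom.residue_name:<3s} {atom.chain_id[:1]}{atom.residue_seq:>4d}{atom.insertion_code[:1] or ' '}"
        f"   {coords[0]:>8.3f}{coords[1]:>8.3f}{coords[2]:>8.3f}"
        f"{atom.occupancy:>6.2f}{atom.b_factor:>6.2f}          {atom.element:>2s}"
    )


def _model_lines(structure: Structure, coords: np.ndarray) -> list[str]:
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for atom, xyz in zip(structure.atoms, coords):
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_atom_line(atom, serial, xyz))
        prev_chain = atom.chain_id
    lines.append("TER")
    return lines


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as a fixed-width PDB file (TER between chains)."""
    lines = _model_lines(structure, structure.coords)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    lines: list[str] = []
    for i, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.extend(_model_lines(traj.topology, frame))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
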