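"""Parametric C_n ring assembly of a monomeric subunit.

Doughnut-like cystatin oligomers are modelled as n rigid copies of one
subunit arranged with exact n-fold rotational symmetry about a common axis
(n = 10 and 12 for the decamer/dodecamer cases). Candidate generation is a
deterministic grid over placement parameters — ring radius plus three
orientation angles — whose role is to propose geometries that are then
screened against experimentally measured ring dimensions. Docking-style
shape scoring is deliberately not part of this stage: the selection
criterion downstream is purely geometric.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import Atom, MonomerStructure, RingAssembly, write_pdb

__all__ = [
    "Candidate",
    "PlacementParams",
    "build_ring",
    "clash_count",
    "enumerate_candidates",
    "write_candidates",
]

# chain identifiers assigned in angular order
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"

DEFAULT_CLASH_CUTOFF = 2.0  # Å between CA atoms of different chains


@dataclass(frozen=True)
class PlacementParams:
    """Rigid placement of the reference subunit before C_n replication.

    ring_radius : Å, distance from the symmetry axis to the subunit centroid.
    tilt        : rad, rotation about the local tangential axis.
    spin        : rad, rotation about the local (outward) radial axis.
    twist       : rad, rotation about the subunit's centroid-to-axis vector.
    """

    ring_radius: float
    tilt: float = 0.0
    spin: float = 0.0
    twist: float = 0.0

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError(f"ring_radius must be > 0, got {self.ring_radius}")

    def local_rotation(self) -> np.ndarray:
        """Orientation applied to the centred subunit at the +x placement site.

        At the reference site the outward radial direction is +x, the
        tangential direction +y and the symmetry axis +z; twist acts about
        the centroid-to-axis vector (-x). Order: twist, then tilt, then spin.
        """
        return (
            Rotation.from_euler("x", self.spin)
            * Rotation.from_euler("y", self.tilt)
            * Rotation.from_euler("x", -self.twist)
        ).as_matrix()


def _rotation_z(angle: float) -> np.ndarray:
    return Rotation.from_euler("z", angle).as_matrix()


def build_ring(monomer: MonomerStructure, n: int, params: PlacementParams) -> RingAssembly:
    """Replicate a monomer into an exact C_n ring about the z axis.

    Subunit k is subunit 0 rotated by 2πk/n about z; chains are lettered
    A, B, C, ... in angular order and keep the monomer's residue numbering.
    """
    if n < 1:
        raise ValueError(f"ring size n must be >= 1, got {n}")
    if n > len(_CHAIN_IDS):
        raise ValueError(f"ring size n={n} exceeds available chain identifiers ({len(_CHAIN_IDS)})")

    coords = monomer.coords
    centred = coords - coords.mean(axis=0)
    r_local = params.local_rotation()
    t0 = np.array([params.ring_radius, 0.0, 0.0])
    base = centred @ r_local.T + t0

    atoms: list[Atom] = []
    transforms: list[tuple[np.ndarray, np.ndarray]] = []
    serial = 0
    for k in range(n):
        rz = _rotation_z(2.0 * np.pi * k / n)
        sub = base @ rz.T
        transforms.append((rz @ r_local, rz @ t0))
        chain_id = _CHAIN_IDS[k]
        for template, xyz in zip(monomer.atoms, sub):
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=template.name,
                    element=template.element,
                    chain_id=chain_id,
                    residue_seq=template.residue_seq,
                    residue_name=template.residue_name,
                    position=xyz,
                    insertion_code=template.insertion_code,
                    occupancy=template.occupancy,
                    b_factor=template.b_factor,
                )
            )

    return RingAssembly(
        atoms,
        n_subunits=n,
        transforms=transforms,
        symmetry_axis=np.array([0.0, 0.0, 1.0]),
        disulfides=list(monomer.disulfides),
    )


def clash_count(assembly: RingAssembly, cutoff: float = DEFAULT_CLASH_CUTOFF) -> int:
    """Number of inter-chain CA-CA pairs closer than ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    ca = [(a.chain_id, a.position) for a in assembly.atoms if a.name == "CA"]
    if len(ca) < 2:
        return 0
    chains = np.array([c for c, _ in ca])
    pts = np.array([p for _, p in ca])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    return int(np.sum(chains[pairs[:, 0]] != chains[pairs[:, 1]]))


@dataclass
class Candidate:
    """One enumerated ring geometry with its provenance and clash flag."""

    candidate_id: str
    n_subunits: int
    params: PlacementParams
    assembly: RingAssembly
    n_clashes: int

    @property
    def clashing(self) -> bool:
        return self.n_clashes > 0


def enumerate_candidates(
    monomer: MonomerStructure,
    n_values: list[int],
    radius_grid: list[float],
    orientation_grid: list[tuple[float, float, float]],
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> list[Candidate]:
    """Build the full Cartesian grid of candidate rings, in sorted order.

    Candidates with inter-subunit backbone clashes are flagged (never
    dropped) — whether a geometry survives is decided later against the
    experimental dimension ranges.
    """
    if not n_values or not radius_grid or not orientation_grid:
        raise ValueError("all parameter grids must be non-empty")
    candidates: list[Candidate] = []
    grid = product(sorted(n_values), sorted(radius_grid), sorted(orientation_grid))
    for i, (n, radius, (tilt, spin, twist)) in enumerate(grid):
        params = PlacementParams(ring_radius=radius, tilt=tilt, spin=spin, twist=twist)
        assembly = build_ring(monomer, n, params)
        candidates.append(
            Candidate(
                candidate_id=f"cand_{i:04d}",
                n_subunits=n,
                params=params,
                assembly=assembly,
                n_clashes=clash_count(assembly, clash_cutoff),
            )
        )
    return candidates


def write_candidates(candidates: list[Candidate], outdir: str | Path) -> Path:
    """Export candidates as multi-chain PDB files plus a CSV index.

    Returns the path of the index file mapping candidate id to placement
    parameters and clash count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cand in candidates:
        write_pdb(cand.assembly, outdir / f"{cand.candidate_id}.pdb")
        rows.append(
            {
                "candidate_id": cand.candidate_id,
                "n_subunits": cand.n_subunits,
                "ring_radius_A": cand.params.ring_radius,
                "tilt_rad": cand.params.tilt,
                "spin_rad": cand.params.spin,
                "twist_rad": cand.params.twist,
                "n_clashes": cand.n_clashes,
            }
        )
    index_path = outdir / "candidates.csv"
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path
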