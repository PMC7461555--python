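"""Doughnut geometry: ring dimensions, radii of gyration, constraint filtering.

A flat ring oligomer is characterized by four lengths, all reported in nm:
the outer diameter d1, the diameter of the central cavity, the ring width
d2 = (d1 - cavity)/2 (the radial thickness of the annulus — the distance
from the cavity edge to the outer edge), and the height. The phrase
"inner diameter" is deliberately absent from this interface: in the
experimental literature it is used both for the cavity diameter and for
the annulus width, and the two differ by a factor that matters.

The closed-form radius of gyration of a uniform annular cylinder,

    R_g^2 = (R_in^2 + R_out^2) / 2 + h^2 / 12,

links the ring dimensions to the R_g measured by SAXS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure
from .units import angstrom_to_nm

__all__ = [
    "ConstraintSet",
    "FilterVerdict",
    "RingGeometry",
    "AFM_CONSTRAINTS",
    "SAXS_CONSTRAINTS",
    "TEM_CONSTRAINTS",
    "annulus_rg",
    "combine_constraints",
    "filter_by_constraints",
    "measure_ring_geometry",
    "radius_of_gyration",
]

# standard atomic masses (u) for mass-weighted R_g
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}
DEFAULT_MASS = 12.011


@dataclass(frozen=True)
class RingGeometry:
    """Measured dimensions of a ring assembly, in nm."""

    outer_diameter: float
    cavity_diameter: float
    height: float
    rg: float

    def __post_init__(self) -> None:
        if not self.outer_diameter >= self.cavity_diameter >= 0:
            raise ValueError(
                f"need outer_diameter >= cavity_diameter >= 0, got {self.outer_diameter}, {self.cavity_diameter}"
            )
        if self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")

    @property
    def ring_width(self) -> float:
        """Radial annulus thickness d2 = (outer - cavity)/2, nm."""
        return (self.outer_diameter - self.cavity_diameter) / 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "outer_diameter_nm": self.outer_diameter,
            "cavity_diameter_nm": self.cavity_diameter,
            "ring_width_nm": self.ring_width,
            "height_nm": self.height,
            "rg_nm": self.rg,
        }


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted coordinate R_g: sqrt(sum m_i |r_i - rbar|^2 / sum m_i).

    Coordinates in Å, result in nm. Uniform weights when ``masses`` is None.
    Translation- and rotation-invariant by construction.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1 or coords.shape[1] != 3:
        raise ValueError(f"need an (n, 3) coordinate array with n >= 1, got shape {coords.shape}")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    center = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - center) ** 2, axis=1)
    return angstrom_to_nm(float(np.sqrt(np.average(sq, weights=masses))))


def annulus_rg(outer_radius: float, inner_radius: float, height: float) -> float:
    """R_g of a uniform annular cylinder (hoop and disc limits included), nm in, nm out."""
    if not outer_radius >= inner_radius >= 0:
        raise ValueError(f"need outer_radius >= inner_radius >= 0, got {outer_radius}, {inner_radius}")
    if height < 0:
        raise ValueError(f"height must be >= 0, got {height}")
    return float(np.sqrt((inner_radius**2 + outer_radius**2) / 2.0 + height**2 / 12.0))


def _torus_rg(tube_center_radius: float, tube_radius: float) -> float:
    # solid torus with circular cross-section: R_g^2 = c^2 + 3a^2/4;
    # internal cross-check only — the annular-cylinder form is the reported one
    return float(np.sqrt(tube_center_radius**2 + 0.75 * tube_radius**2))


def atom_masses(structure: Structure) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(a.element.upper(), DEFAULT_MASS) for a in structure.atoms])


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit axis normal to the ring plane: the smallest-spread direction."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    return eigvecs[:, 0]  # eigenvector of the smallest eigenvalue


def measure_ring_geometry(
    assembly: Structure,
    uniform_mass: bool = False,
    include_hydrogens: bool = False,
) -> RingGeometry:
    """Measure doughnut dimensions of an assembly, in nm.

    The symmetry axis is the stored build axis when available, otherwise
    the smallest-spread principal axis of the heavy-atom coordinates (for
    a flat ring that is the normal of the ring plane). Diameters are twice
    the extreme radial distances of heavy atoms from the axis through the
    centroid; the hydration shell plays no role. R_g is mass-weighted over
    the same atoms unless ``uniform_mass`` (useful for bead models).
    """
    keep = np.array([include_hydrogens or a.element.upper() != "H" for a in assembly.atoms])
    coords = assembly.coords[keep]
    if len(coords) == 0:
        raise ValueError("no heavy atoms to measure")
    masses = None if uniform_mass else atom_masses(assembly)[keep]

    axis = getattr(assembly, "symmetry_axis", None)
    if axis is None:
        axis = _principal_axis(coords)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    centered = coords - coords.mean(axis=0)
    z = centered @ axis
    radial = np.linalg.norm(centered - np.outer(z, axis), axis=1)

    return RingGeometry(
        outer_diameter=angstrom_to_nm(2.0 * float(radial.max())),
        cavity_diameter=angstrom_to_nm(2.0 * float(radial.min())),
        height=angstrom_to_nm(float(z.max() - z.min())),
        rg=radius_of_gyration(coords, masses),
    )


# ---------------------------------------------------------------------------
# Constraint filtering
# ---------------------------------------------------------------------------

Interval = tuple[float, float]


@dataclass(frozen=True)
class ConstraintSet:
    """Inclusive [min, max] bounds in nm; absent parameters are unconstrained."""

    outer_diameter: Interval | None = None
    ring_width: Interval | None = None
    height: Interval | None = None
    rg: Interval | None = None

    def __post_init__(self) -> None:
        for name, bound in self.items():
            if bound[0] > bound[1]:
                raise ValueError(f"{name}: min {bound[0]} > max {bound[1]}")

    def items(self) -> list[tuple[str, Interval]]:
        return [
            (name, bound)
            for name, bound in (
                ("outer_diameter", self.outer_diameter),
                ("ring_width", self.ring_width),
                ("height", self.height),
                ("rg", self.rg),
            )
            if bound is not None
        ]


# Experimentally determined dimension ranges for the stab-1 cystatin C
# oligomers, one set per technique. TEM gives the outer diameter and the
# annulus width; AFM the height (its lateral dimensions were uncalibrated);
# SAXS the doughnut parameterization consistent with the measured R_g.
TEM_CONSTRAINTS = ConstraintSet(outer_diameter=(16.0, 24.0), ring_width=(5.0, 6.0))
AFM_CONSTRAINTS = ConstraintSet(height=(1.6, 2.5))
SAXS_CONSTRAINTS = ConstraintSet(outer_diameter=(20.0, 23.0), ring_width=(7.0, 8.0), height=(2.4, 2.6))

CONSTRAINT_ROWS = {"tem": TEM_CONSTRAINTS, "afm": AFM_CONSTRAINTS, "saxs": SAXS_CONSTRAINTS}


def combine_constraints(*sets: ConstraintSet) -> ConstraintSet:
    """Intersection of several constraint sets (tightest bound wins)."""
    merged: dict[str, Interval] = {}
    for cs in sets:
        for name, (lo, hi) in cs.items():
            if name in merged:
                merged[name] = (max(merged[name][0], lo), min(merged[name][1], hi))
            else:
                merged[name] = (lo, hi)
    return ConstraintSet(**merged)


@dataclass
class FilterVerdict:
    """Outcome of screening one geometry against one constraint set."""

    passed: bool
    failed_parameters: list[tuple[str, float, Interval]]

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_parameters) == 0):
            raise ValueError("verdict inconsistent with its violation list")


def filter_by_constraints(geometry: RingGeometry, constraints: ConstraintSet) -> FilterVerdict:
    """Inclusive interval membership per constrained parameter."""
    values = {
        "outer_diameter": geometry.outer_diameter,
        "ring_width": geometry.ring_width,
        "height": geometry.height,
        "rg": geometry.rg,
    }
    failures = [
        (name, values[name], (lo, hi))
        for name, (lo, hi) in constraints.items()
        if not lo <= values[name] <= hi
    ]
    return FilterVerdict(passed=not failures, failed_parameters=failures)
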