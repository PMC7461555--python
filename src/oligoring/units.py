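"""Length-unit boundary.

Coordinates are handled internally in ångström (the PDB convention).
Report-level ring dimensions are quoted in nanometres, the unit in which
TEM/AFM/SAXS dimensions of protein oligomers are conventionally given.
All conversion goes through this module so the factor appears exactly once.
"""

ANGSTROM_PER_NM: float = 10.0


def angstrom_to_nm(value_angstrom: float) -> float:
    """Convert a length from Å to nm."""
    return value_angstrom / ANGSTROM_PER_NM


def nm_to_angstrom(value_nm: float) -> float:
    """Convert a length from nm to Å."""
    return value_nm * ANGSTROM_PER_NM
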