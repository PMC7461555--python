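"""Build candidate ring oligomers and screen them against measured dimensions.

A flat ~120-residue subunit is replicated into C10 and C12 rings over a
small placement grid; each candidate's doughnut geometry (outer diameter,
ring width, height, R_g, all nm) is measured and compared with the
TEM/AFM dimension ranges for the stabilized cystatin C oligomers.
"""

import numpy as np

from oligoring.geometry import AFM_CONSTRAINTS, TEM_CONSTRAINTS, combine_constraints, filter_by_constraints, measure_ring_geometry
from oligoring.ring_builder import enumerate_candidates
from oligoring.synthetic import make_toy_monomer

monomer = make_toy_monomer(n_residues=120, seed=0).structure
constraints = combine_constraints(TEM_CONSTRAINTS, AFM_CONSTRAINTS)

candidates = enumerate_candidates(
    monomer,
    n_values=[10, 12],
    radius_grid=[70.0, 80.0, 88.0, 100.0],
    orientation_grid=[(np.radians(8.0), 0.0, 0.0)],
)

print(f"{len(candidates)} candidates (ring size x radius grid)")
print(f"{'id':<10}{'n':>3}{'R(Å)':>7}{'outer':>7}{'width':>7}{'height':>8}{'pass':>6}")
for cand in candidates:
    g = measure_ring_geometry(cand.assembly)
    verdict = filter_by_constraints(g, constraints)
    print(
        f"{cand.candidate_id:<10}{cand.n_subunits:>3}{cand.params.ring_radius:>7.0f}"
        f"{g.outer_diameter:>7.1f}{g.ring_width:>7.2f}{g.height:>8.2f}{str(verdict.passed):>6}"
    )

# Reading the table: 'outer' must fall in the TEM range 16-24 nm, 'width'
# in 5-6 nm and 'height' in the AFM range 1.6-2.5 nm. Small radii fail by
# exceeding the ring-width bound (the cavity closes); very large radii
# push the outer diameter beyond the TEM range.
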