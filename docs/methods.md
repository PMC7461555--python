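# Methods

This note documents the models and procedures oligoring implements, the
parameters that matter, the numerical conventions, and what the synthetic
fixtures do and do not establish about real data.

## The modelling problem

Stabilized human cystatin C (stab-1 HCC) forms SDS-resistant oligomers of
10–12 subunits that appear in TEM and AFM as flat rings ("doughnuts"):
outer diameter roughly 16–24 nm, central cavity, height about 2 nm, with
the annulus width matching the cross-section of a single subunit. Because
the oligomers no longer inhibit papain, the subunits are believed to be
joined by three-dimensional domain swapping — the N-terminal segment up to
Ala58 of each subunit completes the fold of its neighbour. oligoring
reconstructs the computational arm of that argument: propose C_n rings,
keep the ones compatible with the measured dimensions, rewire them by the
cyclic swap, and score structural stability.

## Units and conventions

Coordinates are ångström throughout (PDB convention); every report-level
ring dimension is nanometres, converted at a single boundary
(`oligoring.units`). Residue numbering is author numbering (cystatin C
1–120) and is never re-indexed, so the 58/59 junction, the 47–69
engineered disulfide and the 78–79 gap stay literal. The phrase
"inner diameter" is deliberately absent from all interfaces: the
experimental literature uses it both for the cavity diameter and for the
annulus width d₂ = (outer − cavity)/2, which differ by a factor of ~2
here, so the two quantities carry separate names (`cavity_diameter`,
`ring_width`).

## Ring construction

`build_ring` centres the subunit on its centroid, applies an orientation
(tilt about the local tangential axis, spin about the outward radial
axis, twist about the centroid-to-axis vector; order twist→tilt→spin),
translates it to the ring radius on +x, and replicates it by exact
rotations of 2πk/n about z. Chains are lettered in angular order. The
construction guarantees, to floating-point accuracy, that R_z(2π/n)
permutes the chains and that all subunits are rigid copies; both are
asserted as properties in the tests.

Candidate generation is a deterministic Cartesian grid over
(n, ring radius, orientation triple), sorted, with inter-chain CA–CA
contacts under 2.0 Å counted and flagged — never silently dropped,
because whether a candidate survives is decided by the geometric filter,
not by packing. A docking-energetic stage is intentionally absent: in
this workflow the only selection criterion applied to proposed rings is
geometric agreement with the TEM/AFM/SAXS dimension ranges, so a
transparent parametric grid plays the role a black-box symmetric docking
search would otherwise play. No clustering of candidates into
subfamilies is attempted (no reproducible rule exists for it).

## Cyclic domain swap

`apply_cyclic_swap` is a pure relabeling: output chain k consists of
residues 1–58 of input chain k and residues 59–end of input chain k±1
(direction is a flag; the physics does not distinguish the two senses).
Atom coordinates are untouched, so the multiset of coordinates is
conserved bitwise, every output chain carries the full monomer sequence,
and the swap is the n-cycle permutation on segment ownership (its n-th
power is the identity) — all three are tested directly. The freshly
swapped junction is unphysical by construction (the C(58)–N(59) pair
spans neighbouring subunits); in the original modelling protocol it was
relaxed by restrained molecular dynamics, which is out of scope here, so
`junction_report` quantifies the distance instead of minimizing it. On
an intact monomer the same report returns the peptide bond (~1.33 Å),
which doubles as a sanity check.

`rebuild_missing_segment` completes crystallographically unresolved
interior segments (the monomer entry 3GAX lacks Pro78–Asn79). Inserted
CAs are placed on the straight anchor-to-anchor line when the implied
step is plausible (2.8–4.2 Å), otherwise on a circular arc with equal
chords of 3.2 Å, which exists whenever the gap is not too wide for
interpolation; N/C/O (and CB for non-Gly) follow at ideal local
geometry. Terminal gaps are rejected — extension beyond the resolved
chain is a different problem. Side chains beyond CB are not modelled;
nothing downstream (Cα metrics, backbone hydrogen bonds) needs them.

## Doughnut geometry and filtering

`measure_ring_geometry` uses the stored build axis when present;
otherwise the axis is recovered as the smallest-spread principal axis of
the heavy-atom coordinates (the normal of a flat ring's plane), which
makes the measurement invariant to rigid motion of a loaded assembly
(tested to 10⁻³ nm). Diameters are twice the extreme radial distances of
heavy atoms from the axis through the centroid; hydrogens and hence any
hydration shell are excluded. R_g is mass-weighted with standard atomic
masses; a uniform-mass switch exists for bead models.

The constraint sets encode the experimental ranges row by row
(TEM outer 16–24 nm and width 5–6 nm; AFM height 1.6–2.5 nm; SAXS outer
20–23 nm, annulus width 7–8 nm, height 2.4–2.6 nm), with inclusive
bounds; `combine_constraints` intersects rows, and verdicts list every
violated parameter rather than stopping at the first.

The closed form for a uniform annular cylinder,
R_g² = (R_in² + R_out²)/2 + h²/12, is validated against ≥10⁶-sample
Monte-Carlo volume integration to 0.5% across a grid including the hoop
(R_in → R_out, h = 0) and disc (R_in = 0) limits; at the SAXS-derived
doughnut parameterization (R_out 10.75, R_in 3.25, h 2.5 nm) it gives
7.97 nm. A solid-torus variant (R_g² = c² + 3a²/4) exists as an internal
cross-check only, since the shape parameterization used by external
"universal R_g" calculators is not fully specified. On that note: the
annular form at the Table-consistent dimensions does not reproduce the
experimentally fitted R_g of 5.28 nm; the package treats the closed form
and the Guinier fit as independent routes and does not force agreement.

## SAXS

`debye_intensity` evaluates the exact Debye double sum with per-bead
form factors; sinc is evaluated through numpy's stable implementation,
so s·r → 0 is exact, and I(0) = (Σf)². The O(n²) pair distances cap
practical bead counts at a few thousand, ample for validation fixtures.

`guinier_fit` regresses ln I on s² (1/σ²-weighted when uncertainties are
present, unweighted otherwise — whether experimental reductions weight
this fit is usually unstated, so the default is documented rather than
asserted), starting from the lower half of the admissible range and
iterating window ↔ fit until s_max·R_g ≤ limit is a fixed point (max 20
iterations; an oscillating window is flagged, not raised). The default
limit 1.3 is the conventional rule; at R_g = 5.28 nm it reproduces the
standard printed fit window (upper bound 1.3/5.28 ≈ 0.246 nm⁻¹).
R_g = √(−3·slope), with the standard error propagated from the slope.

One systematic is worth knowing: for an exact sphere curve, unweighted
regression over a dense window up to sR_g = 1.3 overestimates R_g by
≈1.9%, because ln I of a sphere is −x²/5 − x⁴/350 + …, not a pure
parabola. That is a property of the Guinier approximation, not of the
fitter — the tests that use the sphere as an analytic oracle therefore
evaluate the fit at s_rg_limit = 0.8, where the residual bias is ≈0.7%
and the √(3/5)·R identity is recovered within 1%. Ideal Guinier-law
curves are recovered to machine precision at any limit.

## Stability metrics

**Kabsch.** SVD solution of the orthogonal Procrustes problem with the
determinant correction, so reflections are never returned; degenerate
(collinear) inputs are rejected. Verified against a two-stage exhaustive
rotation-grid minimization on small instances. `rmsd_series` superposes
every frame on the reference over a selection (default Cα).

**TM-score.** score = max over rigid superpositions of
(1/L)·Σ 1/(1 + (dᵢ/d₀)²), normalized by the reference length, with
d₀ = 1.24(L−15)^⅓ − 1.8 Å. The maximization heuristic seeds from
contiguous fragments of lengths L, L/2, L/4 at staggered offsets and
iterates subset superposition with an inclusion cutoff descending from
8 Å to d₀. Fixed points used as oracles: identity → 1.0; a family in
which every residue is displaced exactly d₀ in a way the optimal
superposition cannot reduce (± point pairs with radial displacements,
making the cross-covariance symmetric positive definite) → 0.5, with
the search allowed to exceed the plug-in value only marginally.

**Hydrogen bonds.** A pair is bonded in a frame when the donor–acceptor
distance is ≤ 3.5 Å and the donor–H–acceptor angle is ≥ 120° (common
MD-analysis defaults; both are configuration keys, since occupancy
numbers are only comparable under stated criteria). Explicit hydrogens
are used when the topology has them; backbone amide donors without
hydrogens get an ideal H constructed per frame (1.01 Å from N, opposed
to the C_prev/CA bisector); if no hydrogen exists or can be built, the
distance criterion alone decides (documented fallback for coarse
fixtures). Occupancy is exact rational counting of frames.

**Secondary structure.** Backbone N–H···O=C bonds are scored with the
Kabsch–Sander electrostatic model, E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN)·332 kcal/mol, bond when E < −0.5 kcal/mol. Helices need two
consecutive n-turns (α first, then 3₁₀/π into unassigned positions),
sheets come from the parallel/antiparallel bridge patterns, isolated
turns label T, the rest C; the 8-class states collapse as {H,G,I}→H,
{E,B}→E, {T}→T, rest→C. This is a DSSP-style scheme: the torsion-based
assigner used for the published composition tables is not fully
re-derivable from its description, and hydrogen-bond schemes agree with
it on ~95% of residues, hence the ±3-percentage-point tolerance wherever
compositions are compared. On the toy subunit the assignment agrees with
an independent DSSP implementation (mdtraj) on 98% of residues.

## Synthetic fixtures: what they establish

All generators are pure functions of (parameters, seed); streams derive
from `default_rng([generator_code, seed])`, so adding a generator never
perturbs existing fixtures.

Backbones are built from ideal internal coordinates (N–CA 1.458, CA–C
1.525, C–N 1.329 Å; angles 111.0/116.2/121.7°; trans peptide) by the
standard internal-to-Cartesian recursion. Canonical torsions: helix
(−57, −47); strand (−120, 120), chosen because it hydrogen-bonds along
the full strand length in built hairpins where the classic twisted
(−139, 135) pair drifts apart after ~5 residues; a two-residue
chain-reversal turn (60, −120)/(−80, 0); an irregular coil pair.

`make_toy_monomer` arranges coil head — 22-residue helix — loop —
two-strand hairpin — coil tail as a flat slab (~55 × 51 × 14 Å at the
default 120 residues), with designed per-residue labels stored alongside
(assignment agrees with the design on ≥90% of non-terminal residues).
The flat shape is deliberate: it is what lets a C₁₂ ring of subunits
reproduce the thin experimental doughnut. The reference placement used
in tests and the acceptance script — ring radius 88 Å, tilt 8° — was
chosen from the slab dimensions so the predicted ring (outer
≈ 2·(88 + 27) Å ≈ 23 nm, width ≈ slab length ≈ 5.5 nm, height ≈ slab
thickness tilted ≈ 2 nm) sits inside the TEM+AFM ranges; the measured
ring confirms the prediction.

`synthetic_cystatin_monomer` / `synthetic_cystatin_dimer` are
**composition stand-ins, not fold models**: deterministic idealized
chains whose designed layouts (one α-helix against a five-stranded,
respectively four-stranded, antiparallel sheet plus turns) reproduce the
published 4-bin composition of the cystatin C monomer (17/45/11/27) and
domain-swapped dimer (18/36/19/27, the sheet partially traded for turns).
The real crystal structures are not bundled with the package, so the
secondary-structure regression validates that the assigner recovers
designed content at the published composition point — it does not
re-derive the composition from the real coordinates. Running
`assign_secondary_structure` on the actual PDB entries is the
recommended check wherever those files are available.

Trajectory fixtures apply scripted rigid motion (removed exactly by
superposition — an oracle for the RMSD code), i.i.d. Gaussian coordinate
noise (mean RMSD → σ√3), and hydrogen-bond schedules that place the
acceptor 2.9 Å along the donor's amide-H direction on "on" frames and
10 Å away otherwise, so occupancy equals the schedule fraction exactly.

What passing these tests does **not** show: that real oligomer models
are stable (that requires force-field dynamics, which is out of scope),
that the toy subunit resembles the cystatin fold (only its footprint and
label statistics are designed), or that the experimental R_g and the
Table-consistent annulus dimensions are mutually consistent (they are
not forced to be; see above).

## Problem sizes

The test suite and acceptance script run at: 120-residue subunits,
rings of 10–12 subunits (~5,800 backbone atoms), 50-frame trajectories,
10⁵-bead R_g fixtures, 10⁶-sample Monte-Carlo integration, and
100-replicate noisy Guinier ensembles — sizes at which every check is
exact or statistically stable while the whole suite stays around half a
minute.

## Known limitations

* The swap junction is reported, not relaxed; swapped rings are starting
  structures for external refinement, not end states.
* `rebuild_missing_segment` is an interpolation, appropriate for 1–3
  residue interior gaps only; no fragment library, no terminal extension.
* The Guinier window iteration assumes a monotone low-angle regime;
  strongly aggregated or inter-particle-interference curves need manual
  s_min.
* Secondary-structure assignment is backbone-only and will differ from
  torsion-propensity schemes at element termini (the tolerance above).
* `debye_intensity` uses point form factors; no solvent-excluded-volume
  correction, no ab initio shape reconstruction, no p(r).
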