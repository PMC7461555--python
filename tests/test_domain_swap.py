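"""Cyclic domain swap: relabeling semantics, cyclicity, gap rebuilding."""

import numpy as np
import pytest

from oligoring.domain_swap import SwapSpec, apply_cyclic_swap, junction_report, rebuild_missing_segment
from oligoring.ring_builder import PlacementParams, build_ring
from oligoring.structures import MonomerStructure
from oligoring.synthetic import HELIX, build_backbone, _residues_to_atoms


def test_swap_spec_validation():
    with pytest.raises(ValueError):
        SwapSpec(junction=(58, 60))
    with pytest.raises(ValueError):
        SwapSpec(junction=(58, 59), segment=(1, 57))
    with pytest.raises(ValueError):
        SwapSpec(direction="sideways")


def test_two_membered_swap_exchanges_tails(toy_structure):
    ring = build_ring(toy_structure, 2, PlacementParams(ring_radius=60.0))
    swapped = apply_cyclic_swap(ring)
    # chain A head must be the original A head; chain A tail the original B tail
    for cid, donor in (("A", "B"), ("B", "A")):
        head = np.array([a.position for a in swapped.chain_atoms(cid) if a.residue_seq <= 58])
        tail = np.array([a.position for a in swapped.chain_atoms(cid) if a.residue_seq >= 59])
        orig_head = np.array([a.position for a in ring.chain_atoms(cid) if a.residue_seq <= 58])
        orig_tail = np.array([a.position for a in ring.chain_atoms(donor) if a.residue_seq >= 59])
        assert np.array_equal(head, orig_head)
        assert np.array_equal(tail, orig_tail)


@pytest.mark.parametrize("n", [10, 12])
def test_swap_conserves_coordinates_and_sequence(toy_structure, n):
    ring = build_ring(toy_structure, n, PlacementParams(ring_radius=88.0, tilt=0.14))
    swapped = apply_cyclic_swap(ring)
    assert len(swapped) == len(ring)
    assert swapped.chain_ids() == ring.chain_ids()
    # pure relabeling: the multiset of coordinates is bitwise identical
    orig = sorted(map(tuple, ring.coords.tolist()))
    new = sorted(map(tuple, swapped.coords.tolist()))
    assert orig == new
    monomer_seq = toy_structure.sequence_of("A")
    for cid in swapped.chain_ids():
        assert swapped.sequence_of(cid) == monomer_seq


@pytest.mark.parametrize("n", [2, 10, 12])
def test_swap_is_an_n_cycle(toy_structure, n):
    ring = build_ring(toy_structure, n, PlacementParams(ring_radius=88.0))
    current = ring
    for _ in range(n):
        current = apply_cyclic_swap(current)
    # n applications restore the original chain partition exactly
    for cid in ring.chain_ids():
        a = np.array([at.position for at in ring.chain_atoms(cid)])
        b = np.array([at.position for at in current.chain_atoms(cid)])
        assert np.array_equal(a, b)


def test_swap_rejects_single_chain(toy_structure):
    ring = build_ring(toy_structure, 1, PlacementParams(ring_radius=50.0))
    with pytest.raises(ValueError, match="single-chain"):
        apply_cyclic_swap(ring)


def test_junction_report_on_intact_monomer(toy_structure):
    report = junction_report(toy_structure)
    assert len(report.entries) == 1
    # intact peptide bond at ideal geometry
    assert report.mean == pytest.approx(1.329, abs=0.02)


def test_junction_report_on_swapped_dodecamer(dodecamer):
    swapped = apply_cyclic_swap(dodecamer)
    report = junction_report(swapped)
    assert len(report.entries) == 12
    assert report.mean == pytest.approx(np.mean(report.distances))
    assert report.min <= report.mean <= report.max


# ---- missing-segment rebuilding -------------------------------------------

@pytest.fixture()
def helix_with_gap():
    residues = build_backbone([HELIX] * 20)
    atoms = [a for a in _residues_to_atoms(residues) if a.residue_seq not in (10, 11)]
    return MonomerStructure(atoms)


def test_rebuild_noop_without_gap(toy_structure):
    out = rebuild_missing_segment(toy_structure)
    assert len(out) == len(toy_structure)
    assert np.array_equal(out.coords, toy_structure.coords)


def test_rebuild_restores_contiguity_with_plausible_steps(helix_with_gap):
    assert helix_with_gap.missing_segments == {"A": [(10, 11)]}
    out = rebuild_missing_segment(helix_with_gap)
    assert [r for r, _ in out.residues("A")] == list(range(1, 21))
    assert out.missing_segments == {}
    for res in (10, 11):
        names = {a.name for a in out.residue_atoms("A", res)}
        assert {"N", "CA", "C", "O", "CB"} <= names
    cas = [out.find_atom("A", r, "CA").position for r in range(8, 14)]
    steps = [np.linalg.norm(b - a) for a, b in zip(cas, cas[1:])]
    assert all(2.8 <= s <= 4.2 for s in steps)


def test_rebuild_respects_residue_names(helix_with_gap):
    out = rebuild_missing_segment(helix_with_gap, residue_names=["PRO", "ASN"])
    assert out.residues("A")[9:11] == [(10, "PRO"), (11, "ASN")]


def test_rebuild_rejects_terminal_gap():
    residues = build_backbone([HELIX] * 10)
    atoms = [a for a in _residues_to_atoms(residues) if a.residue_seq > 2]
    st = MonomerStructure(atoms)
    with pytest.raises(ValueError, match="terminal"):
        rebuild_missing_segment(st, gap=(1, 2))
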