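"""End-to-end orchestration: build → measure → filter → swap → report.

The stages mirror how ring-oligomer models are screened in practice:
candidate C_n assemblies are generated over a parameter grid, measured,
and kept only when their doughnut dimensions fall inside the
experimentally determined ranges; survivors receive the cyclic domain
swap; trajectories of any model are scored with the stability metrics.
Every run is deterministic given its configuration, and reports carry
the full effective configuration for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .domain_swap import JunctionReport, SwapSpec, apply_cyclic_swap, junction_report
from .geometry import (
    CONSTRAINT_ROWS,
    ConstraintSet,
    combine_constraints,
    filter_by_constraints,
    measure_ring_geometry,
)
from .ring_builder import Candidate, enumerate_candidates
from .structures import MonomerStructure, RingAssembly, Structure, read_pdb, write_pdb
from .synthetic import make_toy_monomer
from .traj_metrics import (
    HBondCriteria,
    assign_secondary_structure,
    hbond_occupancy,
    rmsd_series,
    ss_content,
    tm_score,
)

__all__ = ["PipelineConfig", "RunReport", "StabilityReport", "run_analyze_traj", "run_build_and_filter", "run_swap"]


class PipelineConfig(BaseModel):
    """Validated, flat configuration for all pipeline stages.

    Unknown keys are rejected outright so a typo cannot silently fall
    back to a default. Angles are radians, lengths Å unless noted.
    """

    model_config = ConfigDict(extra="forbid")

    monomer_path: str | None = None          # None -> built-in toy monomer
    n_values: list[int] = [10, 12]
    radius_grid: list[float] = [80.0, 85.0, 88.0, 92.0]
    orientation_grid: list[tuple[float, float, float]] = [(0.14, 0.0, 0.0)]
    constraint_rows: list[str] = ["tem", "afm"]
    clash_cutoff: float = 2.0
    swap_junction: tuple[int, int] = (58, 59)
    swap_direction: str = "successor"
    hbond_max_distance: float = 3.5
    hbond_min_angle: float = 120.0
    outdir: str = "oligoring_out"
    seed: int = 0

    @field_validator("constraint_rows")
    @classmethod
    def _rows_known(cls, v):
        unknown = set(v) - set(CONSTRAINT_ROWS)
        if unknown:
            raise ValueError(f"unknown constraint rows {sorted(unknown)}; known: {sorted(CONSTRAINT_ROWS)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def constraints(self) -> ConstraintSet:
        if not self.constraint_rows:
            return ConstraintSet()
        return combine_constraints(*(CONSTRAINT_ROWS[r] for r in self.constraint_rows))

    def swap_spec(self) -> SwapSpec:
        j = tuple(self.swap_junction)
        return SwapSpec(junction=j, segment=(1, j[0]), direction=self.swap_direction)

    def load_monomer(self) -> MonomerStructure:
        if self.monomer_path is None:
            return make_toy_monomer(seed=self.seed).structure
        st = read_pdb(self.monomer_path)
        if not isinstance(st, MonomerStructure):
            raise ValueError(f"{self.monomer_path}: expected a single-chain monomer")
        return st


@dataclass
class RunReport:
    """Per-candidate geometry, verdicts and provenance for one build run."""

    rows: list[dict]
    survivors: list[str]
    config: dict
    version: str = __version__

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "candidates_report.csv", index=False)
        payload = {
            "version": self.version,
            "config": self.config,
            "n_candidates": len(self.rows),
            "survivors": self.survivors,
            "candidates": self.rows,
        }
        (outdir / "run_report.json").write_text(json.dumps(payload, indent=2) + "\n")


def _candidate_row(cand: Candidate, constraints: ConstraintSet) -> tuple[dict, bool]:
    geometry = measure_ring_geometry(cand.assembly)
    verdict = filter_by_constraints(geometry, constraints)
    row = {
        "candidate_id": cand.candidate_id,
        "n_subunits": cand.n_subunits,
        "ring_radius_A": cand.params.ring_radius,
        "tilt_rad": cand.params.tilt,
        "spin_rad": cand.params.spin,
        "twist_rad": cand.params.twist,
        "n_clashes": cand.n_clashes,
        **geometry.as_dict(),
        "passed": verdict.passed,
        "failed_parameters": ";".join(f"{n}={v:.3f}!in[{lo},{hi}]" for n, v, (lo, hi) in verdict.failed_parameters),
    }
    return row, verdict.passed


def run_build_and_filter(config: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Enumerate candidate rings, measure, filter, persist the survivors.

    Zero survivors is a valid outcome (reported, not raised): it is how a
    constraint set falsifies a whole region of placement space.
    """
    monomer = config.load_monomer()
    constraints = config.constraints()
    candidates = enumerate_candidates(
        monomer,
        config.n_values,
        config.radius_grid,
        [tuple(o) for o in config.orientation_grid],
        clash_cutoff=config.clash_cutoff,
    )
    rows, survivors = [], []
    outdir = Path(config.outdir)
    for cand in candidates:
        row, passed = _candidate_row(cand, constraints)
        rows.append(row)
        if passed:
            survivors.append(cand.candidate_id)
            if write_outputs:
                outdir.mkdir(parents=True, exist_ok=True)
                write_pdb(cand.assembly, outdir / f"{cand.candidate_id}.pdb")
    report = RunReport(rows=rows, survivors=survivors, config=config.model_dump(mode="json"))
    if write_outputs:
        report.write(outdir)
    return report


def run_swap(
    config: PipelineConfig,
    assemblies: list[RingAssembly] | list[str | Path],
    write_outputs: bool = True,
) -> list[tuple[RingAssembly, JunctionReport]]:
    """Apply the cyclic domain swap to each assembly and report junctions."""
    spec = config.swap_spec()
    out = []
    for i, item in enumerate(assemblies):
        assembly = item if isinstance(item, RingAssembly) else read_pdb(item)
        if not isinstance(assembly, RingAssembly) or len(assembly.chain_ids()) < 2:
            raise ValueError("cyclic swap needs a multi-chain ring assembly")
        swapped = apply_cyclic_swap(assembly, spec)
        report = junction_report(swapped, spec)
        if write_outputs:
            outdir = Path(config.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_pdb(swapped, outdir / f"swapped_{i:03d}.pdb")
            report.to_json(outdir / f"junctions_{i:03d}.json")
        out.append((swapped, report))
    return out


@dataclass
class StabilityReport:
    """All four stability metric families for one trajectory."""

    rmsd_A: list[float]
    tm: dict
    occupancies: list[dict]
    ss_reference: dict
    ss_final: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"frame": range(len(self.rmsd_A)), "rmsd_A": self.rmsd_A}).to_csv(
            outdir / "rmsd_series.csv", index=False
        )
        payload = {
            "tm_score": self.tm,
            "hbond_occupancies": self.occupancies,
            "secondary_structure": {"reference": self.ss_reference, "final_frame": self.ss_final},
        }
        (outdir / "stability_report.json").write_text(json.dumps(payload, indent=2) + "\n")


def run_analyze_traj(
    config: PipelineConfig,
    traj,
    reference: Structure | None = None,
    hbond_pairs: list | None = None,
) -> StabilityReport:
    """RMSD series, TM-score, H-bond occupancies and SS content in one pass."""
    from .structures import Trajectory, read_trajectory

    if not isinstance(traj, Trajectory):
        traj = read_trajectory(traj)
    reference = reference if reference is not None else traj.topology
    if len(reference) != len(traj.topology):
        raise ValueError(
            f"reference atom count {len(reference)} != trajectory atom count {len(traj.topology)}"
        )

    rmsd = rmsd_series(traj, reference=reference.coords)

    ca_idx = traj.topology.atom_indices(lambda a: a.name == "CA")
    tm = tm_score(traj.frames[-1][ca_idx], reference.coords[ca_idx])

    criteria = HBondCriteria(
        max_donor_acceptor_distance=config.hbond_max_distance, min_dha_angle=config.hbond_min_angle
    )
    occupancies = (
        [o.__dict__ for o in hbond_occupancy(traj, hbond_pairs, criteria)] if hbond_pairs else []
    )

    ss_ref = ss_content(assign_secondary_structure(reference)).as_dict()
    final = traj.topology.copy()
    final.set_coords(traj.frames[-1])
    ss_fin = ss_content(assign_secondary_structure(final)).as_dict()

    return StabilityReport(
        rmsd_A=[float(x) for x in rmsd],
        tm={"score": tm.score, "d0_A": tm.d0, "length": tm.length_target},
        occupancies=occupancies,
        ss_reference=ss_ref,
        ss_final=ss_fin,
    )
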