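"""Stability metrics on a scripted trajectory: RMSD, TM-score, H-bonds, SS.

A synthetic trajectory applies known rigid motion and coordinate noise
to the toy subunit, plus an on/off schedule for one donor/acceptor pair,
so every metric has an exact expected value.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from oligoring.pipeline import PipelineConfig, run_analyze_traj
from oligoring.synthetic import make_toy_monomer, make_trajectory

monomer = make_toy_monomer(seed=0).structure

pair = (("A", 10, "N"), ("A", 40, "O"))
mask = np.zeros(50, bool)
mask[:42] = True  # bonded in 42 of 50 frames -> occupancy 0.84

traj = make_trajectory(
    monomer,
    n_frames=50,
    rigid_motion=lambda i: (Rotation.from_euler("z", 0.05 * i).as_matrix(), np.zeros(3)),
    noise_sigma=0.4,
    hbond_schedule={pair: mask},
    seed=0,
)

report = run_analyze_traj(PipelineConfig(), traj, hbond_pairs=[pair])

print(f"mean RMSD: {np.mean(report.rmsd_A):.2f} Å "
      f"(rigid motion removed; noise alone predicts {0.4*np.sqrt(3):.2f} Å)")
print(f"TM-score last frame vs reference: {report.tm['score']:.3f} (d0 = {report.tm['d0_A']:.2f} Å)")
print(f"H-bond occupancy {pair[0]} -> {pair[1]}: {report.occupancies[0]['occupancy']:.2f} "
      "(schedule: 42/50 = 0.84)")
print("SS content of the reference:",
      {k: f"{100*v:.0f}%" for k, v in report.ss_reference.items()})
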