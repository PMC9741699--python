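"""Interdomain orientation metrics and their response to a torsion.

A reference frame (per-domain origin + two principal axes) is defined on
the bound pose; the six metrics (dC, AB, AC1, AC2, BC1, BC2) are measured
per frame of a dissociation whose encounter phase applies a 30-degree
interdomain torsion.
"""

import numpy as np

from metadiss import orientation as O
from metadiss.synthetic import (
    DissociationSchedule,
    build_toy_dimer,
    generate_dissociation_trajectory,
)

dimer = build_toy_dimer(60, 10, seed=2)
schedule = DissociationSchedule(n_frames=200, t_encounter=100, t_unbound=160,
                                seed=5, torsion_deg=30.0, noise_sigma=0.15,
                                encounter_separation=0.4)
traj = generate_dissociation_trajectory(dimer, schedule)

core = list(range(11, 61))  # rear-block residues define the domain frames
dfd = O.define_reference_frames(traj.frame(0), core, core)
metrics = O.orientation_timeseries(traj, dfd)

ab_bound = metrics.AB[:100].mean()
ab_enc = metrics.AB[100:160].mean()
print(f"AB torsion, bound window     : {ab_bound:7.2f} deg")
print(f"AB torsion, encounter window : {ab_enc:7.2f} deg  (applied: 30)")

summary = O.variability_summary(metrics[list(O.METRIC_NAMES)], schedule.labels())
print(summary[["window", "sd_AB", "sd_AC1", "sd_BC1", "largest_variance_angle"]]
      .to_string(index=False))
# the AB change tracks the applied torsion and AB carries the largest
# angular variance — torsion, not tilt, dominates the dissociation.
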