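"""Spindle orientation relative to the bead, with the randomized null.

Simulates anaphase geometries for a bead-responsive condition (70% of
divisions oriented towards the bead) and a bead-blind control (uniform
angles), measures the angle of every event, bins rose-plot histograms, and
tests each distribution against the randomized three-bin null.
"""

import numpy as np

from wntbead import simulate, spindle
from wntbead.config import SimulationConfig

conditions = {
    "WT": SimulationConfig(angle_mix_p=0.7, angle_kappa=0.01, seed=21),
    "control": SimulationConfig(angle_mix_p=0.0, seed=22),
}

angle_sets = {}
for name, cfg in conditions.items():
    events = simulate.simulate_divisions(cfg, 60, condition=name)
    angles = np.array([spindle.spindle_angle(ev) for ev in events])
    angle_sets[name] = angles
    dist = spindle.rose_histogram(angles)
    top = dist.bin_edges[np.argmax(dist.counts)]
    chi2, df, p = spindle.randomized_null_chisq(angles)
    print(f"{name:8} n={len(angles)}  modal bin {top:.0f}-{top + 5:.0f} deg  "
          f"chi2({df}) = {chi2:.1f} vs randomized null, p = {p:.2g}")

d, p = spindle.ks_two_sample(angle_sets["WT"], angle_sets["control"])
print(f"WT vs control: K-S D = {d:.2f}, p = {p:.2g}")
# 90 deg is a fully bead-oriented division; a WT excess in the 60-90 bin
# rejects the bead-independent (equal-thirds) null, the control does not.
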