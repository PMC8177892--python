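"""Quantify bead position on the membrane, motility, and retention.

For a cohort relaxing towards an equilibrium radius fraction r_eq = 0.85
(bead held at the periphery), computes the per-cell mean bead position in
the three post-uptake windows, the 1-min MSD of cell and bead, the
drop/retain split, and a Fisher exact comparison against a second cohort
that drops beads at a higher rate.
"""

import numpy as np

from wntbead import bead_dynamics as bd
from wntbead import simulate
from wntbead.config import SimulationConfig
from wntbead.stats import fisher_exact

cfg = SimulationConfig(n_cells=40, contact_hazard=1.0, drop_hazard=0.0,
                       division_hazard=0.0, r0=1.0, r_eq=0.85,
                       k_reloc=0.1, sigma_r=0.02, seed=2)
tracks = simulate.simulate_cohort(cfg)

window_mats = []
for tr in tracks:
    series = bd.position_series(tr)
    window_mats.append([wm.mean for wm in bd.window_means(series)])
means = np.mean(window_mats, axis=0)
for (lo, hi), m in zip(bd.DEFAULT_WINDOWS, means):
    zone = bd.assign_zone(m).zone
    print(f"window {lo:>3}-{hi:<3} min: mean radius ratio {m:.3f} ({zone})")

msd_cell = np.mean([bd.msd_cell(tr) for tr in tracks])
msd_bead = np.mean([bd.msd_bead(tr) for tr in tracks])
print(f"MSD_cell(tau=1) = {msd_cell:.2f} um^2/min, "
      f"MSD_bead(tau=1) = {msd_bead:.2f} um^2/min")

# retention: this cohort vs one that loses beads quickly
def retention_counts(config):
    outcomes = [bd.classify_retention(tr).outcome
                for tr in simulate.simulate_cohort(config)]
    return outcomes.count("drops"), outcomes.count("retains")

a = retention_counts(cfg.replace(drop_hazard=0.0005, seed=3))
b = retention_counts(cfg.replace(drop_hazard=0.01, seed=3))
p = fisher_exact([list(a), list(b)])
print(f"drops/retains: {a} vs {b}; Fisher exact p = {p:.3g}")
# The radius ratio staying near 0.85 means the bead is held at the cell
# periphery; the small bead MSD shows it barely moves in the cell's frame.
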