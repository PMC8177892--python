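# Methods

## The measurement model

The package operates on manually-tracked coordinates from 1-min-resolution
time-lapse videos of single embryonic stem cells co-cultured with
Wnt3a-coated microbeads. Three 2D points are tracked per cell per minute:
the cell centre `P_cell`, the bead `P_bead` (only while in contact) and a
membrane reference point `P_membrane`. All quantities are in micrometres
and minutes; time is an integer minute index starting at 0. Only 2D
projections are analysed — the source videos are single-plane brightfield —
so all geometry is planar.

### Bead position

The radius ratio at minute *t* is
`|P_bead(t) − P_cell(t)| / |P_membrane(t) − P_cell(t)|`. The membrane point
is an independently tracked landmark, not re-measured along the centre→bead
ray, so the ratio can exceed 1 when the bead sits beyond the membrane
reference; such values are flagged (`out_of_cell`), never clamped. Zone
edges: peripheral strictly above 0.7, central at or below 0.3,
intermediate in between — the published band descriptions overlap at the
boundaries, so a half-open convention is required; the upper-inclusive
choice (0.7 → intermediate, 0.3 → centre) is used. Per-cell means are taken
over the inclusive minute windows (0–30), (31–120), (121–180) counted from
uptake (the first in-contact minute re-indexed to 0). Windows only
partially covered are averaged over the available minutes and flagged
rather than dropping the cell, keeping the operation total.

### Motility

MSD uses overlapping consecutive displacements at lag τ = 1 min:
`mean_t |X(t+1) − X(t)|²`. No multi-τ fitting or diffusion-coefficient
regression is attempted; the assay reports per-minute motility only. For
the bead, X is the cell-normalised position `NP_bead = P_bead − P_cell`,
which removes rigid co-movement with the cell exactly (a translation
applied to both tracks cancels). Bead MSD uses only minute pairs with both
endpoints in contact.

### Retention

Uptake is the first in-contact minute; the cell is then watched for a
180-min window. Contact lost **at or before** `t_uptake + 180` is *drops*
(the window is inclusive), maintained beyond is *retains*, and a division
at or before the deadline excludes the cell. Exclusion takes precedence
over the drop/retain call.

### Cytonemes and population kinetics

Per-cell cytoneme statistics follow the sampled-timepoint protocol
(~10 samples, 10 min apart): the average count over samples, and the
maximum centre-to-tip distance minus the mean centre-to-membrane distance
(floored at 0 with a flag when negative). Population percentages are
computed per experiment on counts summed over imaging positions —
`100 · Σ n_event / Σ n_total` — never as a mean of per-position
percentages, and then averaged with SEM across experiments: experiments,
not cells or positions, are the replication unit. Default grids are hourly,
0–4 h for cytoneme formation and 0–12 h for bead contact; both are
arguments.

### Spindle orientation

At anaphase the major axis joins the two pole masses; the minor axis is its
perpendicular through the midpoint. The orientation angle is the acute
angle between the undirected minor axis and the midpoint→bead vector,
computed as 90° minus the folded angle to the major axis; it is invariant
under pole swap, rigid motions and reflection. Rose histograms use 5° bins
by default — inferred from the assay's modal 85–90° reporting, and
configurable — with the 90° edge assigned to the last bin. The randomized
null spreads divisions equally over 0–30°/30–60°/60–90° and is tested by
Pearson chi-squared (df = 2) without continuity correction; an exact
multinomial tail is available for n < 15. Condition contrasts use the
two-sample Kolmogorov–Smirnov test with the asymptotic p by default; a
seeded permutation p (pooled-label shuffling) is offered because angle
samples are small and discrete.

### Asymmetric division and qPCR

For each marker channel, the partition percentage is
`100 · (I_prox − B)₊ / ((I_prox − B)₊ + (I_dist − B)₊)` with one background
value B per doublet and negative residuals clamped to 0 (dim distal
daughters are biologically expected; both daughters at background is an
error, not a 50 % call). Category bands are inclusive for *Distributed*
(45–55 %) and strict outside (> 55 % Proximal, < 45 % Distal). Fold changes
follow `2^−ΔΔCt` with ΔCt against the reference gene and ΔΔCt against the
mean control ΔCt; replicate folds are summarized by geometric mean and
geometric SD.

### Shared statistics

Fisher's exact test (two-sided, probability-mass ordering: the p-value sums
hypergeometric probabilities of all margin-preserving tables at most as
probable as the observed one) compares drop/retain tables between
conditions; scipy's implementation is used and was verified against exact
integer enumeration on every table with total ≤ 40. ANOVA and
multiple-comparison machinery is deliberately not re-implemented: group
means ± SEM are exported for external statistics software.

## The synthetic-data generator

The generator emulates the *output* of manual tracking, not the images.
Its stated world:

* **Radial bead dynamics** — a clamped discrete mean-reverting process,
  `r(t+1) = r(t) + k_reloc (r_eq − r(t)) + σ_r ε`, clipped to (0, 1]. No
  generative model is published for these dynamics; this is the simplest
  process producing the observed "relocate then stabilise" shape. Defaults
  `k_reloc = 0.1`, `σ_r = 0.02`, `r0 = 1` (recruitment at the membrane),
  `r_eq = 0.85` (bead held at the periphery).
* **Angular dynamics / cell motion** — wrapped Gaussian random walk of the
  bead direction (σ_θ = 0.05 rad/min) and an isotropic Gaussian walk of the
  centre (0.7 µm per axis per min, giving MSD ≈ 1 µm²/min, the order of
  magnitude of single-ESC motility); cell radius 8 µm, typical of ESCs.
* **Event times** — first cytoneme, first contact, contact loss and
  division are geometric waiting times (constant per-minute hazard), the
  simplest memoryless model at 1-min resolution.
* **Anaphase geometry** — the spindle angle is drawn from a two-component
  mixture: with probability `angle_mix_p` a normal centred at 90°,
  SD `1/√angle_kappa` degrees, truncated to [0°, 90°] (bead-oriented
  divisions); otherwise uniform on [0°, 90°] (bead-blind). Pole and bead
  coordinates are then constructed to realize the drawn angle exactly, so
  the measurement round-trips to 1e-6°.
* **Doublets** — proximal fraction p ~ Beta(α, β) (defaults 4, 2: a
  proximal-skewed partition), intensities `B + pT + ε` / `B + (1−p)T + ε`
  with T = 100, B = 10, ε ~ N(0, 2²), clamped at 0. When explicit category
  rates are requested, the category is drawn first and p uniformly within
  its band.

All randomness flows from one integer seed through `numpy.random
.SeedSequence`; identical config gives byte-identical outputs. Per-genotype
presets are illustrative — no relocation rate or hazard has been fitted to
real videos, which are not available — so a green recovery test establishes
that the *estimators* are correct on data with the assumed structure, not
that any particular genotype has these parameter values. The generator also
omits known features of real tracks: measurement noise on the tracked
points, gaps, position-dependent drop hazards, and any coupling between
bead position and division timing.

## Numerical choices

* Absent values are empty CSV fields; zeros are legal coordinates and never
  mean missing. Booleans serialize as lowercase `true`/`false`. Floats are
  written with the shortest round-tripping repr, so write→read→write is
  byte-identical.
* The radius fraction is clamped to [1e-9, 1] (the open-interval lower end
  realized as a tiny positive number).
* The partition percentage is capped at 100 to absorb float round-off in
  the fully-proximal case.
* Chi-squared p-values use the asymptotic distribution; the exact
  multinomial option enumerates all compositions (feasible for the small n
  where it matters).
* Angle folding: α = min(θ, 180° − θ) on the undirected minor axis
  guarantees [0°, 90°]; the 90° histogram edge belongs to the last bin.

## Limitations

* 2D only; no 3D spindle or bead geometry.
* No protrusion detection, segmentation or any pixel-level processing —
  tip annotations and intensities are inputs.
* No trajectory smoothing, gap interpolation or multi-τ diffusion fitting.
* Published real-data values (population percentages, MSD medians, drop
  rates per genotype) derive from unavailable videos and are not
  reproduced; the pipeline's correctness is established on synthetic
  cohorts with known ground truth.
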