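"""Seeded generator of synthetic tracking data.

Stands in for manual tracking of 1-min time-lapse videos of single embryonic
stem cells interacting with a Wnt3a-coated microbead. Each simulated cell
contributes:

* a 2D track (cell centre, bead, membrane reference point, per minute),
* geometric waiting times for first cytoneme, first bead contact, contact
  loss, and division (constant per-minute hazards),
* a bead radius fraction following a clamped discrete mean-reverting
  (Ornstein-Uhlenbeck-like) process: relocate towards ``r_eq``, then
  fluctuate around it,
* optionally, an anaphase geometry realizing a drawn spindle-to-bead angle,
* optionally, a two-daughter intensity partition of a pluripotency marker.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence``; identical config gives identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from wntbead.config import SimulationConfig
from wntbead.types import DivisionEvent, DoubletRecord, Track

_R_MIN = 1e-9  # lower clamp of the radius fraction; the interval is (0, 1]

# percent bands of the proximal share used when doublets are drawn from
# explicit category rates rather than the Beta distribution
_CATEGORY_BANDS = {
    "Proximal": (55.0, 100.0),
    "Distributed": (45.0, 55.0),
    "Distal": (0.0, 45.0),
}


def _geometric_first_event(rng: np.random.Generator, hazard: float) -> float:
    """First-success minute under a constant per-minute hazard.

    Returns inf when the hazard is 0 (the event never occurs); with
    hazard 1 the event occurs at minute 1.
    """
    if hazard == 0.0:
        return np.inf
    return float(rng.geometric(hazard))


def simulate_bead_track(
    config: SimulationConfig,
    cell_id: str,
    *,
    condition: str = "WT",
    experiment_id: str = "exp0",
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one cell's track over ``config.duration_min`` minutes.

    The bead's radial position (as a fraction of the cell radius) follows

        r[t+1] = r[t] + k_reloc * (r_eq - r[t]) + sigma_r * eps,

    clamped to (0, 1]; its angular position performs a wrapped Gaussian
    random walk with per-step SD ``sigma_theta``. The cell centre performs
    an isotropic Gaussian random walk with per-axis SD ``cell_step_sigma``.
    The membrane reference point sits on the ray from the centre through the
    bead at distance ``cell_radius_um``, and the absolute bead position is
    centre + r * cell_radius_um * (unit bead direction).

    Bead coordinates are NaN outside the contact interval; contact starts at
    a geometric waiting time with ``contact_hazard`` and is lost after a
    further geometric waiting time with ``drop_hazard``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.duration_min + 1
    t = np.arange(n)

    # fixed draw order keeps same-seed runs byte-identical
    t_contact = _geometric_first_event(rng, config.contact_hazard)
    drop_wait = _geometric_first_event(rng, config.drop_hazard)
    t_div = _geometric_first_event(rng, config.division_hazard)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dtheta = rng.normal(0.0, config.sigma_theta, size=n - 1)
    eps_r = rng.normal(0.0, 1.0, size=n - 1)
    steps = rng.normal(0.0, config.cell_step_sigma, size=(n - 1, 2))

    r = np.empty(n)
    r[0] = config.r0
    for i in range(n - 1):
        r[i + 1] = (
            r[i]
            + config.k_reloc * (config.r_eq - r[i])
            + config.sigma_r * eps_r[i]
        )
        r[i + 1] = min(max(r[i + 1], _R_MIN), 1.0)

    theta = np.concatenate([[theta0], theta0 + np.cumsum(dtheta)])
    direction = np.column_stack([np.cos(theta), np.sin(theta)])

    p_cell = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    p_membrane = p_cell + config.cell_radius_um * direction
    p_bead_full = p_cell + (r[:, None] * config.cell_radius_um) * direction

    t_loss = t_contact + drop_wait
    in_contact = (t >= t_contact) & (t < t_loss)
    p_bead = np.where(in_contact[:, None], p_bead_full, np.nan)

    divided_at = int(t_div) if t_div <= config.duration_min else None
    return Track(
        cell_id=cell_id,
        condition=condition,
        experiment_id=experiment_id,
        t=t,
        p_cell=p_cell,
        p_bead=p_bead,
        p_membrane=p_membrane,
        in_contact=in_contact,
        divided_at=divided_at,
    )


def simulate_cohort(
    config: SimulationConfig,
    *,
    condition: str = "WT",
    experiment_id: str = "exp0",
) -> list[Track]:
    """Simulate ``config.n_cells`` independent tracks (one seed stream each)."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    return [
        simulate_bead_track(
            config,
            f"cell{i:04d}",
            condition=condition,
            experiment_id=experiment_id,
            rng=np.random.default_rng(seeds[i]),
        )
        for i in range(config.n_cells)
    ]


def simulate_population(
    config: SimulationConfig,
    n_positions: int,
    *,
    experiment_id: str = "exp0",
) -> pd.DataFrame:
    """Per-minute population counts across imaging positions.

    Each position holds ``config.n_cells`` cells; per cell, the first
    cytoneme appearance and the first bead contact are geometric waiting
    times with ``cytoneme_hazard`` and ``contact_hazard``. Both events are
    irreversible at the population level (a cell that formed a cytoneme or
    touched a bead is counted from that minute on).

    Returns a tidy table with columns
    (experiment_id, position_id, t_min, n_total, n_with_cytonemes,
    n_with_beads).
    """
    config.validate()
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")

    rng = np.random.default_rng(config.seed)
    t = np.arange(config.duration_min + 1)
    rows = []
    for pos in range(n_positions):
        t_cyt = np.array(
            [_geometric_first_event(rng, config.cytoneme_hazard)
             for _ in range(config.n_cells)]
        )
        t_con = np.array(
            [_geometric_first_event(rng, config.contact_hazard)
             for _ in range(config.n_cells)]
        )
        n_cyt = (t[:, None] >= t_cyt[None, :]).sum(axis=1)
        n_con = (t[:, None] >= t_con[None, :]).sum(axis=1)
        rows.append(pd.DataFrame({
            "experiment_id": experiment_id,
            "position_id": f"pos{pos:03d}",
            "t_min": t,
            "n_total": config.n_cells,
            "n_with_cytonemes": n_cyt,
            "n_with_beads": n_con,
        }))
    return pd.concat(rows, ignore_index=True)


def draw_division_angles(
    config: SimulationConfig, n_events: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw spindle-to-bead angles (degrees in [0, 90]) from the mixture.

    With probability ``angle_mix_p`` the angle comes from a normal
    distribution centred at 90 deg, SD 1/sqrt(angle_kappa) deg, truncated to
    [0, 90] (the bead-oriented component); otherwise it is uniform on
    [0, 90] (the randomized, ligand-independent component).
    """
    oriented = rng.random(n_events) < config.angle_mix_p
    angles = rng.uniform(0.0, 90.0, size=n_events)
    n_oriented = int(oriented.sum())
    if n_oriented:
        sd = 1.0 / np.sqrt(config.angle_kappa) if config.angle_kappa > 0 else np.inf
        if np.isfinite(sd):
            a, b = (0.0 - 90.0) / sd, (90.0 - 90.0) / sd
            drawn = stats.truncnorm.rvs(
                a, b, loc=90.0, scale=sd, size=n_oriented, random_state=rng
            )
        else:
            drawn = rng.uniform(0.0, 90.0, size=n_oriented)
        angles[oriented] = drawn
    return angles


def simulate_divisions(
    config: SimulationConfig,
    n_events: int,
    *,
    condition: str = "WT",
    return_angles: bool = False,
) -> list[DivisionEvent] | tuple[list[DivisionEvent], np.ndarray]:
    """Simulate anaphase geometries realizing drawn spindle angles exactly.

    For each event a random midpoint, spindle orientation, pole separation
    and bead distance are drawn; the bead is then placed so that the acute
    angle between the minor axis (perpendicular to the pole-to-pole axis)
    and the midpoint-to-bead vector equals the drawn angle.
    """
    config.validate()
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(config.seed)
    angles = draw_division_angles(config, n_events, rng)

    mids = rng.uniform(-100.0, 100.0, size=(n_events, 2))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_events)       # spindle axis
    half_sep = rng.uniform(3.0, 6.0, size=n_events)          # um, half pole sep
    bead_dist = rng.uniform(4.0, 10.0, size=n_events)        # um
    side = rng.choice([-1.0, 1.0], size=n_events)

    major = np.column_stack([np.cos(phi), np.sin(phi)])
    events = []
    for i in range(n_events):
        pole_a = mids[i] - half_sep[i] * major[i]
        pole_b = mids[i] + half_sep[i] * major[i]
        # bead direction: minor axis (phi + 90 deg) rotated by +/- alpha
        beta = phi[i] + np.pi / 2.0 + side[i] * np.deg2rad(angles[i])
        bead = mids[i] + bead_dist[i] * np.array([np.cos(beta), np.sin(beta)])
        events.append(DivisionEvent(
            event_id=f"div{i:04d}",
            condition=condition,
            pole_a=(float(pole_a[0]), float(pole_a[1])),
            pole_b=(float(pole_b[0]), float(pole_b[1])),
            bead=(float(bead[0]), float(bead[1])),
        ))
    if return_angles:
        return events, angles
    return events


def simulate_doublets(
    config: SimulationConfig,
    n_doublets: int,
    true_category_rates: dict[str, float] | None = None,
    *,
    condition: str = "WT",
    experiment_id: str = "exp0",
    channel: str = "Nanog",
) -> list[DoubletRecord]:
    """Simulate per-channel intensities of post-division doublets.

    The proximal fraction p of the marker is drawn from
    Beta(partition_alpha, partition_beta), or — when ``true_category_rates``
    maps {'Proximal', 'Distributed', 'Distal'} to probabilities — by first
    sampling a category and then p uniformly within that category's percent
    band. Intensities are then

        I_prox = B + p * T + noise,   I_dist = B + (1 - p) * T + noise,

    with background B = ``background_mean``, total signal T =
    ``total_intensity`` and independent Gaussian noise (SD ``noise_sd``),
    clamped at 0.
    """
    config.validate()
    if n_doublets < 1:
        raise ValueError("n_doublets must be >= 1")
    rng = np.random.default_rng(config.seed)

    if true_category_rates is None:
        p = rng.beta(config.partition_alpha, config.partition_beta,
                     size=n_doublets)
    else:
        cats = list(true_category_rates)
        probs = np.array([true_category_rates[c] for c in cats], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("category rates must be non-negative and sum to 1")
        drawn = rng.choice(len(cats), size=n_doublets, p=probs)
        p = np.empty(n_doublets)
        for i, k in enumerate(drawn):
            lo, hi = _CATEGORY_BANDS[cats[k]]
            p[i] = rng.uniform(lo, hi) / 100.0

    b, total = config.background_mean, config.total_intensity
    noise = rng.normal(0.0, config.noise_sd, size=(n_doublets, 3))
    i_prox = np.maximum(b + p * total + noise[:, 0], 0.0)
    i_dist = np.maximum(b + (1.0 - p) * total + noise[:, 1], 0.0)
    i_bg = np.maximum(b + noise[:, 2], 0.0)

    return [
        DoubletRecord(
            doublet_id=f"dbl{i:04d}",
            condition=condition,
            experiment_id=experiment_id,
            channel=channel,
            i_proximal=float(i_prox[i]),
            i_distal=float(i_dist[i]),
            i_background=float(i_bg[i]),
        )
        for i in range(n_doublets)
    ]
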