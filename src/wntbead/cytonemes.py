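"""Cytoneme counts/lengths per cell and population contact kinetics.

Per-cell statistics follow the sampled-timepoint protocol: each cell is
measured at ~10 timepoints 10 min apart; the average cytoneme count and the
maximum centre-to-tip length are computed, and the mean centre-to-membrane
distance is subtracted from the length so it reports protrusion beyond the
cell body.

Population kinetics are computed per experiment by summing cell counts over
imaging positions before taking percentages (avoiding position-specific
weighting), then averaging the per-experiment curves with SEM across
experiments — experiments, not cells, are the replication unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wntbead.types import CytonemeSample

#: default evaluation grids (minutes): cytoneme formation over 0-4 h,
#: bead contact over 0-12 h, hourly
CYTONEME_GRID_MIN = tuple(range(0, 241, 60))
BEAD_GRID_MIN = tuple(range(0, 721, 60))

_EVENT_COLUMN = {"cytonemes": "n_with_cytonemes", "beads": "n_with_beads"}


@dataclass(frozen=True)
class CytonemeStats:
    """Average count and normalized maximum length for one cell."""

    avg_count: float
    max_length_normalized: float | None   # None when no cytoneme was seen
    floored: bool                         # True when max tip < mean radius


def cytoneme_stats(samples: list[CytonemeSample]) -> CytonemeStats:
    """Average cytoneme count and membrane-subtracted maximum length.

    ``max_length_normalized`` = (max centre-to-tip distance over all samples)
    minus the mean centre-to-membrane distance over samples; negative results
    are floored at 0 and flagged.
    """
    if not samples:
        raise ValueError("at least one sample required")
    counts = [len(s.tip_distances) for s in samples]
    avg_count = float(np.mean(counts))
    all_tips = [d for s in samples for d in s.tip_distances]
    if not all_tips:
        return CytonemeStats(avg_count=avg_count,
                             max_length_normalized=None, floored=False)
    mean_radius = float(np.mean([s.centre_membrane_distance for s in samples]))
    raw = max(all_tips) - mean_radius
    if raw < 0:
        return CytonemeStats(avg_count, 0.0, True)
    return CytonemeStats(avg_count, raw, False)


def population_percent(
    counts: pd.DataFrame,
    which: str,
    grid: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Percentage of cells with cytonemes (or bead contact) over time.

    Per experiment and timepoint, the percentage is computed on summed
    counts: 100 * sum_positions(n_event) / sum_positions(n_total). The
    per-experiment series are then averaged, with SEM, across experiments.

    Parameters
    ----------
    counts
        Population table (experiment_id, position_id, t_min, n_total,
        n_with_cytonemes, n_with_beads); all positions of an experiment
        must share the timepoint grid.
    which
        'cytonemes' or 'beads'.
    grid
        Optional subset of minutes to evaluate (e.g. hourly grids).

    Returns
    -------
    DataFrame with columns (t_min, mean_percent, sem_percent,
    n_experiments); timepoints with zero total cells are absent (NaN).
    """
    if which not in _EVENT_COLUMN:
        raise ValueError("which must be 'cytonemes' or 'beads'")
    event_col = _EVENT_COLUMN[which]

    df = counts
    if grid is not None:
        df = df[df["t_min"].isin(grid)]
    for exp_id, grp in df.groupby("experiment_id"):
        grids = grp.groupby("position_id")["t_min"].apply(
            lambda s: tuple(sorted(s))
        )
        if grids.nunique() > 1:
            raise ValueError(
                f"experiment {exp_id!r}: positions disagree on timepoints"
            )

    summed = (
        df.groupby(["experiment_id", "t_min"], as_index=False)
        [["n_total", event_col]].sum()
    )
    totals = summed["n_total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        summed["percent"] = np.where(
            totals > 0,
            100.0 * summed[event_col].to_numpy(dtype=float) / totals,
            np.nan,
        )

    out = (
        summed.groupby("t_min")["percent"]
        .agg(
            mean_percent="mean",
            sem_percent=lambda s: s.std(ddof=1) / np.sqrt(s.notna().sum())
            if s.notna().sum() > 1 else np.nan,
            n_experiments="count",
        )
        .reset_index()
    )
    return out
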