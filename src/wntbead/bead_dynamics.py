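"""Bead position, bead/cell motility, and retention classification.

All quantities derive from three tracked points per minute: the cell centre
``P_cell``, the bead ``P_bead`` and a membrane reference ``P_membrane``.

* ``radius_ratio`` = |P_bead - P_cell| / |P_membrane - P_cell|, the bead's
  distance from the centre as a fraction of the cell radius (0 centre,
  1 membrane). The membrane point is tracked independently, so the ratio
  can legitimately exceed 1; such values are flagged, never clamped.
* ``NP_bead(t)`` = P_bead(t) - P_cell(t), the bead position normalised to
  the cell, which removes whole-cell motion from bead movement.
* MSD at lag tau = 1 min: mean over t of |X(t+tau) - X(t)|^2, with X the
  cell centre (cell motility) or NP_bead (cell-normalised bead motility),
  using all overlapping 1-min intervals.
* Retention: after bead uptake the cell is watched for a further 180 min;
  losing contact at or before t_uptake + 180 classifies it as 'drops',
  keeping contact beyond as 'retains'; cells dividing within the window are
  excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wntbead.types import RetentionRecord, Track

#: inclusive minute windows used for per-cell bead-position averages
DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = ((0, 30), (31, 120), (121, 180))

#: post-uptake observation window of the drop/retain classifier, minutes
RETENTION_WINDOW_MIN = 180

#: radius-fraction zone edges: > PERIPHERY_EDGE is peripheral,
#: <= CENTRE_EDGE is central, in between is intermediate
PERIPHERY_EDGE = 0.7
CENTRE_EDGE = 0.3


class DegenerateGeometryError(ValueError):
    """Membrane reference coincides with the cell centre (zero radius)."""


class InsufficientDataError(ValueError):
    """Too few timepoints for the requested estimate."""


@dataclass
class BeadPositionSeries:
    """Per-minute bead position of one cell, re-indexed so uptake = 0.

    ``minutes`` counts from the first in-contact minute; ``radius_ratio``
    and ``np_bead`` are defined only on in-contact minutes.
    """

    cell_id: str
    minutes: np.ndarray       # (M,) int, 0 at uptake
    t_original: np.ndarray    # (M,) int, minutes on the track's clock
    radius_ratio: np.ndarray  # (M,) dimensionless
    np_bead: np.ndarray       # (M, 2) um, bead minus cell centre


@dataclass(frozen=True)
class WindowMean:
    """Mean radius ratio over one inclusive minute window."""

    window: tuple[int, int]
    mean: float | None        # None when the window has no covered minutes
    n_minutes: int
    partial: bool             # True when fewer minutes than the window spans


@dataclass(frozen=True)
class ZoneAssignment:
    zone: str                 # 'periphery' | 'intermediate' | 'centre'
    out_of_cell: bool         # ratio > 1: bead beyond the membrane reference


def distance(p, q) -> float:
    """Euclidean distance between two 2D points (um)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def radius_ratio(track: Track, t: int) -> float:
    """Bead distance from the centre as a fraction of the cell radius at t."""
    idx = np.flatnonzero(track.t == t)
    if idx.size == 0:
        raise ValueError(f"t={t} not in track {track.cell_id}")
    i = int(idx[0])
    if not track.in_contact[i]:
        raise ValueError(f"cell {track.cell_id} not in contact at t={t}")
    radius = distance(track.p_membrane[i], track.p_cell[i])
    if radius == 0.0:
        raise DegenerateGeometryError(
            f"cell {track.cell_id}: membrane coincides with centre at t={t}"
        )
    return distance(track.p_bead[i], track.p_cell[i]) / radius


def position_series(track: Track) -> BeadPositionSeries:
    """Radius ratio and NP_bead for every in-contact minute of one track."""
    contact_idx = np.flatnonzero(track.in_contact)
    if contact_idx.size == 0:
        raise InsufficientDataError(
            f"cell {track.cell_id} has no in-contact timepoints"
        )
    t_contact = track.t[contact_idx]
    radii = np.linalg.norm(
        track.p_membrane[contact_idx] - track.p_cell[contact_idx], axis=1
    )
    if np.any(radii == 0.0):
        raise DegenerateGeometryError(
            f"cell {track.cell_id}: membrane coincides with centre"
        )
    dist_bead = np.linalg.norm(
        track.p_bead[contact_idx] - track.p_cell[contact_idx], axis=1
    )
    return BeadPositionSeries(
        cell_id=track.cell_id,
        minutes=t_contact - t_contact[0],
        t_original=t_contact,
        radius_ratio=dist_bead / radii,
        np_bead=track.p_bead[contact_idx] - track.p_cell[contact_idx],
    )


def window_means(
    series: BeadPositionSeries,
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS,
) -> list[WindowMean]:
    """Mean radius ratio in each inclusive post-uptake minute window.

    Windows only partially covered by the series are averaged over the
    available minutes and flagged ``partial``; windows with no covered
    minutes get ``mean=None``.
    """
    out = []
    for lo, hi in windows:
        mask = (series.minutes >= lo) & (series.minutes <= hi)
        n = int(mask.sum())
        span = hi - lo + 1
        if n == 0:
            out.append(WindowMean((lo, hi), None, 0, True))
        else:
            out.append(WindowMean(
                (lo, hi), float(series.radius_ratio[mask].mean()),
                n, n < span,
            ))
    return out


def msd_cell(track: Track, tau: int = 1) -> float:
    """Mean squared displacement of the cell centre at lag tau (um^2/min).

    Averages |P_cell(t+tau) - P_cell(t)|^2 over all overlapping intervals.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 min")
    if len(track) < tau + 1:
        raise InsufficientDataError(
            f"cell {track.cell_id}: need >= {tau + 1} timepoints"
        )
    disp = track.p_cell[tau:] - track.p_cell[:-tau]
    return float(np.mean(np.sum(disp**2, axis=1)))


def msd_bead(track: Track, tau: int = 1) -> float:
    """Cell-normalised bead MSD at lag tau (um^2/min).

    Uses NP_bead = P_bead - P_cell, so rigid co-movement of bead and cell
    contributes zero; only pairs of minutes both in contact enter.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 min")
    np_bead = track.p_bead - track.p_cell
    valid = track.in_contact[tau:] & track.in_contact[:-tau] if len(track) > tau \
        else np.zeros(0, dtype=bool)
    if valid.sum() < 1:
        raise InsufficientDataError(
            f"cell {track.cell_id}: need >= {tau + 1} in-contact timepoints"
        )
    disp = np_bead[tau:][valid] - np_bead[:-tau][valid]
    return float(np.mean(np.sum(disp**2, axis=1)))


def assign_zone(ratio: float) -> ZoneAssignment:
    """Assign a radius ratio to the peripheral / intermediate / central zone.

    Peripheral: ratio > 0.7; intermediate: 0.3 < ratio <= 0.7; central:
    ratio <= 0.3. Ratios above 1 are peripheral with an out-of-cell flag
    (the bead lies beyond the membrane reference point).
    """
    if not np.isfinite(ratio):
        raise ValueError("ratio must be finite")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio > PERIPHERY_EDGE:
        return ZoneAssignment("periphery", ratio > 1.0)
    if ratio > CENTRE_EDGE:
        return ZoneAssignment("intermediate", False)
    return ZoneAssignment("centre", False)


def classify_retention(
    track: Track, window: int = RETENTION_WINDOW_MIN
) -> RetentionRecord:
    """Classify a tracked cell as dropping or retaining its bead.

    Uptake is the first in-contact minute. Contact lost at or before
    t_uptake + window -> 'drops'; contact maintained beyond -> 'retains';
    a division at or before t_uptake + window -> 'excluded'.
    """
    contact_idx = np.flatnonzero(track.in_contact)
    if contact_idx.size == 0:
        raise ValueError(f"cell {track.cell_id} has no uptake event")
    t_uptake = int(track.t[contact_idx[0]])
    deadline = t_uptake + window

    if track.divided_at is not None and track.divided_at <= deadline:
        return RetentionRecord(track.cell_id, t_uptake, "excluded")

    # first minute at/after uptake where contact is absent
    after = track.t >= t_uptake
    lost = after & ~track.in_contact
    if lost.any():
        t_loss = int(track.t[np.flatnonzero(lost)[0]])
        if t_loss <= deadline:
            return RetentionRecord(track.cell_id, t_uptake, "drops", t_loss)
        return RetentionRecord(track.cell_id, t_uptake, "retains", t_loss)
    return RetentionRecord(track.cell_id, t_uptake, "retains")
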