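"""Core record types shared across the pipeline.

Coordinates are 2D, in micrometres; time is an integer minute index starting
at 0. Absent values (bead coordinates before contact, censored loss times)
are represented as NaN / None, never as zeros: (0, 0) is a legal position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Track:
    """Per-minute 2D track of one cell: centre, bead, membrane reference.

    ``p_bead`` rows are NaN wherever ``in_contact`` is False; ``divided_at``
    is the minute of division, or None if the cell never divided in the
    observation window.
    """

    cell_id: str
    condition: str
    experiment_id: str
    t: np.ndarray            # (N,) int minutes, consecutive
    p_cell: np.ndarray       # (N, 2) um
    p_bead: np.ndarray       # (N, 2) um, NaN before contact / after loss
    p_membrane: np.ndarray   # (N, 2) um
    in_contact: np.ndarray   # (N,) bool
    divided_at: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.p_cell = np.asarray(self.p_cell, dtype=float)
        self.p_bead = np.asarray(self.p_bead, dtype=float)
        self.p_membrane = np.asarray(self.p_membrane, dtype=float)
        self.in_contact = np.asarray(self.in_contact, dtype=bool)
        n = len(self.t)
        for name in ("p_cell", "p_bead", "p_membrane"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2)")
        if n > 1 and not np.all(np.diff(self.t) == 1):
            raise ValueError(
                f"track {self.cell_id}: t must increase by exactly 1"
            )
        if np.any(np.all(self.p_membrane == self.p_cell, axis=1)):
            raise ValueError(
                f"track {self.cell_id}: membrane point coincides with centre"
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DivisionEvent:
    """Anaphase geometry: the two spindle-pole positions and the bead."""

    event_id: str
    condition: str
    pole_a: tuple[float, float]
    pole_b: tuple[float, float]
    bead: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.pole_a) == tuple(self.pole_b):
            raise ValueError(f"event {self.event_id}: coincident poles")
        mid = (
            (self.pole_a[0] + self.pole_b[0]) / 2.0,
            (self.pole_a[1] + self.pole_b[1]) / 2.0,
        )
        if tuple(self.bead) == mid:
            raise ValueError(
                f"event {self.event_id}: bead at the division midpoint"
            )


@dataclass(frozen=True)
class DoubletRecord:
    """Per-channel mean intensities of one post-division doublet."""

    doublet_id: str
    condition: str
    experiment_id: str
    channel: str
    i_proximal: float
    i_distal: float
    i_background: float

    def __post_init__(self) -> None:
        for name in ("i_proximal", "i_distal", "i_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RetentionRecord:
    """Outcome of the 180-min post-uptake retention classification."""

    cell_id: str
    t_uptake: int
    outcome: str                 # 'drops' | 'retains' | 'excluded'
    t_loss: int | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("drops", "retains", "excluded"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class CytonemeSample:
    """One sampled timepoint of cytoneme tip measurements for one cell.

    ``tip_distances`` are centre-to-tip distances (um), one per cytoneme;
    ``centre_membrane_distance`` is the centre-to-membrane distance at the
    same timepoint.
    """

    cell_id: str
    sample_index: int
    tip_distances: list[float] = field(default_factory=list)
    centre_membrane_distance: float = 0.0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.tip_distances):
            raise ValueError("tip distances must be >= 0")
        if self.centre_membrane_distance < 0:
            raise ValueError("centre-membrane distance must be >= 0")
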