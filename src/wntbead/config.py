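"""Simulation configuration: every knob of the synthetic-data generator.

The generator stands in for manual tracking of 1-min-resolution brightfield
videos, so its parameters are phrased in the units of that assay: minutes,
micrometres, per-minute hazards, and radius fractions (bead distance from the
cell centre divided by the centre-to-membrane distance).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic track / division / doublet generator.

    Parameters
    ----------
    n_cells
        Number of single-cell tracks per simulated cohort.
    duration_min
        Observation window length in minutes (1-min sampling).
    dt_min
        Sampling interval; fixed at 1 min to match acquisition.
    r0
        Initial bead radius fraction in (0, 1] at the moment of uptake.
    r_eq
        Equilibrium radius fraction the bead relaxes towards; the membrane
        is 1, the cell centre 0.
    k_reloc
        Per-minute mean-reversion rate of the radial position in [0, 1].
        0 freezes the radial dynamics; 1 jumps to ``r_eq`` in one step.
    sigma_r
        Per-step radial noise SD in radius-fraction units.
    sigma_theta
        Per-step angular noise SD in radians (wrapped random walk of the
        bead's direction around the cell centre).
    cell_step_sigma
        Per-axis, per-step SD of the cell-centre Gaussian random walk (um).
    cell_radius_um
        Cell radius, i.e. centre-to-membrane distance (um).
    contact_hazard
        Per-minute probability of first bead contact (geometric waiting time).
    cytoneme_hazard
        Per-minute probability of first cytoneme appearance.
    drop_hazard
        Per-minute probability of losing bead contact after uptake.
    division_hazard
        Per-minute probability of division.
    angle_mix_p
        Weight of the bead-oriented component of the spindle-angle mixture.
    angle_kappa
        Concentration of the oriented component; the oriented angle is
        normal at 90 deg truncated to [0, 90] with SD 1/sqrt(angle_kappa) deg.
    partition_alpha, partition_beta
        Beta shape parameters of the proximal-fraction distribution for
        daughter-cell marker partitioning.
    total_intensity
        Total partitionable signal T per doublet channel (intensity units);
        proximal cell receives p*T, distal (1-p)*T on top of background.
    background_mean
        Mean background intensity B (intensity units).
    noise_sd
        SD of additive Gaussian intensity noise.
    seed
        Seed of the generator; identical config + seed gives byte-identical
        output.
    """

    n_cells: int = 50
    duration_min: int = 180
    dt_min: int = 1
    r0: float = 1.0
    r_eq: float = 0.85
    k_reloc: float = 0.1
    sigma_r: float = 0.02
    sigma_theta: float = 0.05
    cell_step_sigma: float = 0.7
    cell_radius_um: float = 8.0
    contact_hazard: float = 0.01
    cytoneme_hazard: float = 0.02
    drop_hazard: float = 0.002
    division_hazard: float = 0.001
    angle_mix_p: float = 0.7
    angle_kappa: float = 0.01
    partition_alpha: float = 4.0
    partition_beta: float = 2.0
    total_intensity: float = 100.0
    background_mean: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "r0", "r_eq", "k_reloc", "sigma_r", "sigma_theta",
            "cell_step_sigma", "cell_radius_um", "contact_hazard",
            "cytoneme_hazard", "drop_hazard", "division_hazard",
            "angle_mix_p", "angle_kappa", "partition_alpha",
            "partition_beta", "total_intensity", "background_mean",
            "noise_sd",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"non-finite parameter {name}={value!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration_min < 1:
            raise ValueError("duration_min must be >= 1")
        if self.dt_min != 1:
            raise ValueError("dt_min is fixed at 1 min")
        if not (0.0 < self.r0 <= 1.0):
            raise ValueError("r0 must lie in (0, 1]")
        if not (0.0 < self.r_eq <= 1.0):
            raise ValueError("r_eq must lie in (0, 1]")
        for name in ("k_reloc", "contact_hazard", "cytoneme_hazard",
                     "drop_hazard", "division_hazard", "angle_mix_p"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("sigma_r", "sigma_theta", "cell_step_sigma",
                     "noise_sd", "angle_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if self.partition_alpha <= 0 or self.partition_beta <= 0:
            raise ValueError("Beta shape parameters must be > 0")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
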