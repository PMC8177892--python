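"""Stage wiring: reproducible end-to-end runs from config to report bundle.

This is the library-level entry point a user scripts against (see the
``examples/`` directory): a :class:`RunConfig` names a stage, its input
tables, an output directory and the analysis parameters, and :func:`run`
executes it, writing all outputs plus a YAML manifest under the output
directory. Defaults equal the assay's stated values: post-uptake windows
(0-30, 31-120, 121-180) min, retention window 180 min, zone edges 0.7/0.3,
ACD bands 45/55%, rose-plot bins 5 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wntbead import acd, bead_dynamics, cytonemes, io, simulate, spindle
from wntbead.config import SimulationConfig
from wntbead.stats import build_report

STAGES = ("simulate", "tracks", "population", "spindle", "acd", "report")


@dataclass
class RunConfig:
    """One pipeline stage invocation.

    ``inputs`` maps logical names ('tracks', 'population', 'divisions',
    'doublets') to CSV paths; ``sim`` configures the generator for the
    'simulate' stage. Analysis parameters default to the assay's values.
    """

    stage: str
    out_dir: str | Path
    inputs: dict[str, str] = field(default_factory=dict)
    sim: SimulationConfig | None = None
    seed: int = 0
    windows: tuple[tuple[int, int], ...] = bead_dynamics.DEFAULT_WINDOWS
    retention_window: int = bead_dynamics.RETENTION_WINDOW_MIN
    bin_width: float = spindle.DEFAULT_BIN_WIDTH
    n_positions: int = 3
    n_events: int = 50
    n_doublets: int = 60

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )


def _require_input(config: RunConfig, name: str) -> Path:
    try:
        path = Path(config.inputs[name])
    except KeyError:
        raise ValueError(f"stage {config.stage!r} needs input {name!r}") from None
    if not path.exists():
        raise FileNotFoundError(path)
    return path


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    sim = (config.sim or SimulationConfig()).replace(seed=config.seed)
    tracks = simulate.simulate_cohort(sim)
    io.write_tracks(io.tracks_to_table(tracks), out / "tracks.csv")
    pop = simulate.simulate_population(sim, config.n_positions)
    io.write_population(pop, out / "population.csv")
    events = simulate.simulate_divisions(sim, config.n_events)
    io.write_divisions(io.divisions_to_table(events), out / "divisions.csv")
    doublets = simulate.simulate_doublets(sim, config.n_doublets)
    io.write_doublets(io.doublets_to_table(doublets), out / "doublets.csv")
    return {"sim": sim, "summaries": {}}


def _stage_tracks(config: RunConfig, out: Path) -> dict:
    table = io.read_tracks(_require_input(config, "tracks"))
    tracks = io.table_to_tracks(table)

    per_cell, retention_rows = [], []
    for tr in tracks:
        row = {"cell_id": tr.cell_id, "condition": tr.condition,
               "experiment_id": tr.experiment_id}
        try:
            series = bead_dynamics.position_series(tr)
        except bead_dynamics.InsufficientDataError:
            series = None
        if series is not None:
            for wm in bead_dynamics.window_means(series, config.windows):
                lo, hi = wm.window
                row[f"mean_ratio_{lo}_{hi}"] = wm.mean
                row[f"partial_{lo}_{hi}"] = wm.partial
            row["msd_bead"] = (
                bead_dynamics.msd_bead(tr)
                if int(tr.in_contact.sum()) >= 2 else None
            )
            rec = bead_dynamics.classify_retention(tr, config.retention_window)
            retention_rows.append({
                "cell_id": rec.cell_id, "condition": tr.condition,
                "t_uptake": rec.t_uptake, "outcome": rec.outcome,
                "t_loss": rec.t_loss,
            })
        row["msd_cell"] = bead_dynamics.msd_cell(tr) if len(tr) >= 2 else None
        per_cell.append(row)

    per_cell = pd.DataFrame(per_cell)
    retention = pd.DataFrame(retention_rows)
    if not retention.empty:
        retention_counts = (
            retention[retention["outcome"] != "excluded"]
            .groupby(["condition", "outcome"]).size()
            .rename("n").reset_index()
        )
    else:
        retention_counts = pd.DataFrame(columns=["condition", "outcome", "n"])
    return {"summaries": {
        "per_cell": per_cell,
        "retention": retention if not retention.empty else None,
        "retention_counts": retention_counts,
    }}


def _stage_population(config: RunConfig, out: Path) -> dict:
    counts = io.read_population(_require_input(config, "population"))
    grids = {
        "percent_cytonemes": ("cytonemes", None),
        "percent_beads": ("beads", None),
    }
    summaries = {
        name: cytonemes.population_percent(counts, which, grid)
        for name, (which, grid) in grids.items()
    }
    return {"summaries": summaries}


def _stage_spindle(config: RunConfig, out: Path) -> dict:
    table = io.read_divisions(_require_input(config, "divisions"))
    events = io.table_to_divisions(table)
    angles = pd.DataFrame({
        "event_id": [ev.event_id for ev in events],
        "condition": [ev.condition for ev in events],
        "angle_deg": [spindle.spindle_angle(ev) for ev in events],
    })
    hist_rows, test_rows = [], []
    for cond, grp in angles.groupby("condition"):
        dist = spindle.rose_histogram(
            grp["angle_deg"].to_numpy(), config.bin_width
        )
        for lo, hi, count in zip(
            dist.bin_edges[:-1], dist.bin_edges[1:], dist.counts
        ):
            hist_rows.append({"condition": cond, "bin_low_deg": lo,
                              "bin_high_deg": hi, "count": int(count)})
        chi2, df, p = spindle.randomized_null_chisq(grp["angle_deg"])
        test_rows.append({"condition": cond, "test": "chisq_vs_randomized",
                          "statistic": chi2, "df": df, "p": p})
    conds = sorted(angles["condition"].unique())
    for i, ca in enumerate(conds):
        for cb in conds[i + 1:]:
            d, p = spindle.ks_two_sample(
                angles.loc[angles["condition"] == ca, "angle_deg"],
                angles.loc[angles["condition"] == cb, "angle_deg"],
            )
            test_rows.append({"condition": f"{ca} vs {cb}",
                              "test": "ks_two_sample",
                              "statistic": d, "df": np.nan, "p": p})
    return {"summaries": {
        "angles": angles,
        "rose_histogram": pd.DataFrame(hist_rows),
        "spindle_tests": pd.DataFrame(test_rows),
    }}


def _stage_acd(config: RunConfig, out: Path) -> dict:
    table = io.read_doublets(_require_input(config, "doublets"))
    calls = acd.call_doublets(io.table_to_doublets(table))
    return {"summaries": {
        "doublet_calls": calls,
        "category_rates": acd.category_rates(calls),
    }}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "tracks": _stage_tracks,
    "population": _stage_population,
    "spindle": _stage_spindle,
    "acd": _stage_acd,
}


def run(config: RunConfig) -> dict:
    """Execute one stage (or the full chain for stage='report').

    Returns the run manifest; all tables and the manifest are written under
    ``config.out_dir``. Identical config + seed give identical outputs
    (manifest timestamp aside).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.stage == "report":
        # full chain on simulated data: simulate, then analyse every table
        sim_result = _stage_simulate(config, out)
        chained = RunConfig(
            stage="tracks", out_dir=out, seed=config.seed,
            windows=config.windows,
            retention_window=config.retention_window,
            bin_width=config.bin_width,
            inputs={
                "tracks": str(out / "tracks.csv"),
                "population": str(out / "population.csv"),
                "divisions": str(out / "divisions.csv"),
                "doublets": str(out / "doublets.csv"),
            },
        )
        summaries: dict = {}
        for stage in ("tracks", "population", "spindle", "acd"):
            chained.stage = stage
            summaries.update(_STAGE_FNS[stage](chained, out)["summaries"])
        return build_report(
            summaries, out, config=sim_result["sim"], seed=config.seed
        )

    result = _STAGE_FNS[config.stage](config, out)
    sim = result.get("sim") or config.sim
    summaries = result["summaries"] or {"run": pd.DataFrame({
        "stage": [config.stage], "status": ["ok"]})}
    return build_report(summaries, out, config=sim, seed=config.seed)
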