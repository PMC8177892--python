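"""CSV reading/writing for the four table formats, with validation.

Formats (all plain CSV, UTF-8, comma-separated, one header row):

* tracks:      experiment_id, position_id, cell_id, condition, t_min,
               x_cell, y_cell, x_bead, y_bead, x_membrane, y_membrane,
               in_contact, divided_at
* divisions:   event_id, condition, x_pole_a, y_pole_a, x_pole_b, y_pole_b,
               x_bead, y_bead
* doublets:    doublet_id, condition, experiment_id, channel,
               i_proximal, i_distal, i_background
* population:  experiment_id, position_id, t_min, n_total,
               n_with_cytonemes, n_with_beads

Conventions: absent values are empty fields (never zeros — (0, 0) is a legal
coordinate); booleans are lowercase "true"/"false"; floats are written at
full precision (shortest round-tripping repr); row order is deterministic.
Readers never coerce silently: every rejection names the offending column,
cell or row.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
import pandas as pd

from wntbead.types import DivisionEvent, DoubletRecord, Track


class SchemaError(ValueError):
    """Header or column-type mismatch against the documented schema."""


class IntegrityError(ValueError):
    """Row content violates a table invariant (e.g. non-consecutive t_min)."""


TRACK_COLUMNS = [
    "experiment_id", "position_id", "cell_id", "condition", "t_min",
    "x_cell", "y_cell", "x_bead", "y_bead", "x_membrane", "y_membrane",
    "in_contact", "divided_at",
]
DIVISION_COLUMNS = [
    "event_id", "condition",
    "x_pole_a", "y_pole_a", "x_pole_b", "y_pole_b", "x_bead", "y_bead",
]
DOUBLET_COLUMNS = [
    "doublet_id", "condition", "experiment_id", "channel",
    "i_proximal", "i_distal", "i_background",
]
POPULATION_COLUMNS = [
    "experiment_id", "position_id", "t_min",
    "n_total", "n_with_cytonemes", "n_with_beads",
]


def _fmt(value) -> str:
    """Serialize one cell: empty for absent, 'true'/'false' for booleans."""
    if value is None or (not isinstance(value, str) and pd.isna(value)):
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _write_csv(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in df[columns].itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[],
        skip_blank_lines=True,
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    return df


def _parse_float(df: pd.DataFrame, col: str, path, allow_absent=False) -> pd.Series:
    raw = df[col]
    out = pd.Series(np.nan, index=df.index, dtype=float)
    nonempty = raw != ""
    try:
        out[nonempty] = raw[nonempty].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: column {col!r} not numeric: {exc}") from exc
    if not allow_absent and not nonempty.all():
        row = int(df.index[~nonempty][0])
        raise IntegrityError(f"{path}: column {col!r} absent at row {row}")
    bad = nonempty & ~np.isfinite(out)
    if bad.any():
        row = int(df.index[bad][0])
        raise IntegrityError(f"{path}: non-finite {col!r} at row {row}")
    return out


def _parse_int(df: pd.DataFrame, col: str, path, allow_absent=False) -> pd.Series:
    raw = df[col]
    nonempty = raw != ""
    if not allow_absent and not nonempty.all():
        row = int(df.index[~nonempty][0])
        raise IntegrityError(f"{path}: column {col!r} absent at row {row}")
    out = pd.Series(pd.NA, index=df.index, dtype="Int64")
    try:
        out[nonempty] = raw[nonempty].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: column {col!r} not integer: {exc}") from exc
    return out


def _parse_bool(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    bad = ~raw.isin(["true", "false"])
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: column {col!r} must be 'true'/'false', "
            f"got {raw[bad].iloc[0]!r} at row {row}"
        )
    return raw == "true"


# ---------------------------------------------------------------- tracks

def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read and validate a track table; rows sorted by (cell_id, t_min).

    Raises :class:`SchemaError` on header/type mismatch and
    :class:`IntegrityError` (naming the cell) when a cell's minutes are not
    consecutive integers.
    """
    df = _read_csv(path, TRACK_COLUMNS)
    if df.empty:
        return df.reindex(columns=TRACK_COLUMNS)
    out = pd.DataFrame({
        "experiment_id": df["experiment_id"],
        "position_id": df["position_id"],
        "cell_id": df["cell_id"],
        "condition": df["condition"],
        "t_min": _parse_int(df, "t_min", path),
        "x_cell": _parse_float(df, "x_cell", path),
        "y_cell": _parse_float(df, "y_cell", path),
        "x_bead": _parse_float(df, "x_bead", path, allow_absent=True),
        "y_bead": _parse_float(df, "y_bead", path, allow_absent=True),
        "x_membrane": _parse_float(df, "x_membrane", path),
        "y_membrane": _parse_float(df, "y_membrane", path),
        "in_contact": _parse_bool(df, "in_contact", path),
        "divided_at": _parse_int(df, "divided_at", path, allow_absent=True),
    })
    out = out.sort_values(["cell_id", "t_min"], kind="stable")
    out = out.reset_index(drop=True)
    for cell_id, grp in out.groupby("cell_id", sort=False):
        t = grp["t_min"].to_numpy(dtype=int)
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise IntegrityError(
                f"{path}: cell {cell_id!r} has non-consecutive t_min"
            )
    return out


def write_tracks(table, path: str | Path) -> None:
    """Write a track table (DataFrame or list of :class:`Track`) as CSV."""
    if not isinstance(table, pd.DataFrame):
        table = tracks_to_table(table)
    table = table.sort_values(["cell_id", "t_min"], kind="stable")
    _write_csv(table, TRACK_COLUMNS, path)


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Flatten Track objects into the tracks CSV schema."""
    frames = []
    for tr in tracks:
        n = len(tr)
        frames.append(pd.DataFrame({
            "experiment_id": tr.experiment_id,
            "position_id": getattr(tr, "position_id", "pos000"),
            "cell_id": tr.cell_id,
            "condition": tr.condition,
            "t_min": tr.t,
            "x_cell": tr.p_cell[:, 0],
            "y_cell": tr.p_cell[:, 1],
            "x_bead": tr.p_bead[:, 0],
            "y_bead": tr.p_bead[:, 1],
            "x_membrane": tr.p_membrane[:, 0],
            "y_membrane": tr.p_membrane[:, 1],
            "in_contact": tr.in_contact,
            "divided_at": pd.array([tr.divided_at] * n, dtype="Int64"),
        }))
    if not frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def table_to_tracks(table: pd.DataFrame) -> list[Track]:
    """Rebuild per-cell Track objects from a validated track table."""
    tracks = []
    for cell_id, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        divided = grp["divided_at"].iloc[0]
        tracks.append(Track(
            cell_id=str(cell_id),
            condition=str(grp["condition"].iloc[0]),
            experiment_id=str(grp["experiment_id"].iloc[0]),
            t=grp["t_min"].to_numpy(dtype=int),
            p_cell=grp[["x_cell", "y_cell"]].to_numpy(dtype=float),
            p_bead=grp[["x_bead", "y_bead"]].to_numpy(dtype=float),
            p_membrane=grp[["x_membrane", "y_membrane"]].to_numpy(dtype=float),
            in_contact=grp["in_contact"].to_numpy(dtype=bool),
            divided_at=None if pd.isna(divided) else int(divided),
        ))
    return tracks


# ------------------------------------------------------------- divisions

def read_divisions(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, DIVISION_COLUMNS)
    if df.empty:
        return df.reindex(columns=DIVISION_COLUMNS)
    out = pd.DataFrame({
        "event_id": df["event_id"],
        "condition": df["condition"],
    })
    for col in DIVISION_COLUMNS[2:]:
        out[col] = _parse_float(df, col, path)
    return out.sort_values("event_id", kind="stable").reset_index(drop=True)


def write_divisions(table, path: str | Path) -> None:
    if not isinstance(table, pd.DataFrame):
        table = divisions_to_table(table)
    table = table.sort_values("event_id", kind="stable")
    _write_csv(table, DIVISION_COLUMNS, path)


def divisions_to_table(events: list[DivisionEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=DIVISION_COLUMNS)
    return pd.DataFrame([
        {
            "event_id": ev.event_id,
            "condition": ev.condition,
            "x_pole_a": ev.pole_a[0], "y_pole_a": ev.pole_a[1],
            "x_pole_b": ev.pole_b[0], "y_pole_b": ev.pole_b[1],
            "x_bead": ev.bead[0], "y_bead": ev.bead[1],
        }
        for ev in events
    ])


def table_to_divisions(table: pd.DataFrame) -> list[DivisionEvent]:
    return [
        DivisionEvent(
            event_id=str(row.event_id),
            condition=str(row.condition),
            pole_a=(row.x_pole_a, row.y_pole_a),
            pole_b=(row.x_pole_b, row.y_pole_b),
            bead=(row.x_bead, row.y_bead),
        )
        for row in table.itertuples(index=False)
    ]


# -------------------------------------------------------------- doublets

def read_doublets(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, DOUBLET_COLUMNS)
    if df.empty:
        return df.reindex(columns=DOUBLET_COLUMNS)
    out = pd.DataFrame({
        "doublet_id": df["doublet_id"],
        "condition": df["condition"],
        "experiment_id": df["experiment_id"],
        "channel": df["channel"],
        "i_proximal": _parse_float(df, "i_proximal", path),
        "i_distal": _parse_float(df, "i_distal", path),
        "i_background": _parse_float(df, "i_background", path),
    })
    for col in ("i_proximal", "i_distal", "i_background"):
        bad = out[col] < 0
        if bad.any():
            row = int(out.index[bad][0])
            raise IntegrityError(f"{path}: negative {col!r} at row {row}")
    order = ["doublet_id", "channel"]
    return out.sort_values(order, kind="stable").reset_index(drop=True)


def write_doublets(table, path: str | Path) -> None:
    if not isinstance(table, pd.DataFrame):
        table = doublets_to_table(table)
    table = table.sort_values(["doublet_id", "channel"], kind="stable")
    _write_csv(table, DOUBLET_COLUMNS, path)


def doublets_to_table(records: list[DoubletRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=DOUBLET_COLUMNS)
    return pd.DataFrame([
        {
            "doublet_id": r.doublet_id, "condition": r.condition,
            "experiment_id": r.experiment_id, "channel": r.channel,
            "i_proximal": r.i_proximal, "i_distal": r.i_distal,
            "i_background": r.i_background,
        }
        for r in records
    ])


def table_to_doublets(table: pd.DataFrame) -> list[DoubletRecord]:
    return [
        DoubletRecord(
            doublet_id=str(r.doublet_id), condition=str(r.condition),
            experiment_id=str(r.experiment_id), channel=str(r.channel),
            i_proximal=r.i_proximal, i_distal=r.i_distal,
            i_background=r.i_background,
        )
        for r in table.itertuples(index=False)
    ]


# ------------------------------------------------------------ population

def read_population(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, POPULATION_COLUMNS)
    if df.empty:
        return df.reindex(columns=POPULATION_COLUMNS)
    out = pd.DataFrame({
        "experiment_id": df["experiment_id"],
        "position_id": df["position_id"],
        "t_min": _parse_int(df, "t_min", path),
        "n_total": _parse_int(df, "n_total", path),
        "n_with_cytonemes": _parse_int(df, "n_with_cytonemes", path),
        "n_with_beads": _parse_int(df, "n_with_beads", path),
    })
    for col in ("n_with_cytonemes", "n_with_beads"):
        bad = (out[col] < 0) | (out[col] > out["n_total"])
        if bad.any():
            row = int(out.index[bad][0])
            raise IntegrityError(
                f"{path}: {col!r} outside [0, n_total] at row {row}"
            )
    order = ["experiment_id", "position_id", "t_min"]
    return out.sort_values(order, kind="stable").reset_index(drop=True)


def write_population(table: pd.DataFrame, path: str | Path) -> None:
    table = table.sort_values(
        ["experiment_id", "position_id", "t_min"], kind="stable"
    )
    _write_csv(table, POPULATION_COLUMNS, path)
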