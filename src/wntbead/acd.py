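"""Asymmetric-cell-division scoring and qPCR fold changes.

After a division in bead contact, exactly one daughter (the bead-proximal
cell) keeps the bead. For each marker channel the background-subtracted mean
intensities of the proximal and distal daughters give the proximal partition
percentage

    percent = 100 * (I_prox - B)+ / ((I_prox - B)+ + (I_dist - B)+),

with negative background-subtracted values clamped to 0. Doublets are then
called 'Proximal' (> 55%), 'Distributed' (45-55%, inclusive) or 'Distal'
(< 45%).

qPCR fold changes use the standard 2^-DDCt method: DCt = Ct_target -
Ct_reference, DDCt = DCt - mean DCt of the control condition, fold =
2^-DDCt; replicate folds are summarized by geometric mean / geometric SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wntbead.types import DoubletRecord

#: Distributed band edges (percent of marker in the bead-proximal cell);
#: inclusive for Distributed, strict for Proximal (>) and Distal (<)
DISTRIBUTED_HIGH = 55.0
DISTRIBUTED_LOW = 45.0

CATEGORIES = ("Proximal", "Distributed", "Distal")


class UndefinedPartitionError(ValueError):
    """Both daughters at or below background: no partition defined."""


@dataclass(frozen=True)
class DoubletCall:
    doublet_id: str
    condition: str
    experiment_id: str
    channel: str
    percent_proximal: float
    category: str


def partition_percent(rec: DoubletRecord) -> float:
    """Percentage of background-subtracted signal in the proximal daughter."""
    prox = max(rec.i_proximal - rec.i_background, 0.0)
    dist = max(rec.i_distal - rec.i_background, 0.0)
    total = prox + dist
    if total == 0.0:
        raise UndefinedPartitionError(
            f"doublet {rec.doublet_id} channel {rec.channel}: "
            "both daughters at or below background"
        )
    # guard against float round-off pushing the share past 100
    return min(100.0 * prox / total, 100.0)


def classify_doublet(percent: float) -> str:
    """Allocate a partition percentage to Proximal / Distributed / Distal."""
    if not np.isfinite(percent) or not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    if percent > DISTRIBUTED_HIGH:
        return "Proximal"
    if percent >= DISTRIBUTED_LOW:
        return "Distributed"
    return "Distal"


def call_doublets(records: list[DoubletRecord]) -> pd.DataFrame:
    """Score a list of doublet records into a tidy call table."""
    rows = []
    for rec in records:
        pct = partition_percent(rec)
        rows.append({
            "doublet_id": rec.doublet_id,
            "condition": rec.condition,
            "experiment_id": rec.experiment_id,
            "channel": rec.channel,
            "percent_proximal": pct,
            "category": classify_doublet(pct),
        })
    return pd.DataFrame(
        rows,
        columns=["doublet_id", "condition", "experiment_id", "channel",
                 "percent_proximal", "category"],
    )


def category_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment category percentages, with cross-experiment mean/SEM.

    Groups calls by (condition, channel, experiment_id) and computes the
    percentage of doublets in each category (summing to 100 per group),
    then the mean and SEM of those percentages across experiments.

    Returns a tidy table (condition, channel, category, mean_percent,
    sem_percent, n_experiments).
    """
    if calls.empty:
        raise ValueError("no calls to summarize")
    per_exp = []
    for (cond, chan, exp), grp in calls.groupby(
        ["condition", "channel", "experiment_id"]
    ):
        n = len(grp)
        for cat in CATEGORIES:
            per_exp.append({
                "condition": cond, "channel": chan, "experiment_id": exp,
                "category": cat,
                "percent": 100.0 * (grp["category"] == cat).sum() / n,
            })
    per_exp = pd.DataFrame(per_exp)
    out = (
        per_exp.groupby(["condition", "channel", "category"])["percent"]
        .agg(
            mean_percent="mean",
            sem_percent=lambda s: s.std(ddof=1) / np.sqrt(len(s))
            if len(s) > 1 else np.nan,
            n_experiments="count",
        )
        .reset_index()
    )
    # keep the field's category order, not alphabetical
    out["category"] = pd.Categorical(out["category"], CATEGORIES, ordered=True)
    return out.sort_values(
        ["condition", "channel", "category"]
    ).reset_index(drop=True)


def qpcr_fold_change(ct_target, ct_ref, mean_dct_control: float):
    """Relative expression by the 2^-DDCt method.

    DCt = ct_target - ct_ref; DDCt = DCt - mean_dct_control;
    fold = 2^-DDCt. Accepts scalars or arrays (element-wise).
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_ref))
            and np.isfinite(mean_dct_control)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_ref) - mean_dct_control
    fold = np.power(2.0, -ddct)
    return float(fold) if fold.ndim == 0 else fold


def summarize_folds(folds) -> tuple[float, float]:
    """Geometric mean and geometric SD of replicate fold changes."""
    folds = np.asarray(folds, dtype=float)
    if folds.size == 0 or np.any(folds <= 0):
        raise ValueError("folds must be positive and non-empty")
    log_folds = np.log(folds)
    gmean = float(np.exp(log_folds.mean()))
    gsd = float(np.exp(log_folds.std(ddof=1))) if folds.size > 1 else float("nan")
    return gmean, gsd
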