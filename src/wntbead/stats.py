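"""Shared exact/asymptotic tests and report assembly.

Fisher's exact test (two-sided, probability-mass ordering) compares
drop/retain contingency tables between conditions; the chi-squared
goodness-of-fit test backs the spindle module's randomized-null comparison.
``build_report`` bundles summary tables with a YAML run manifest (config,
seed, software version) so a run can be reproduced from its output alone.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from wntbead.config import SimulationConfig


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = conditions, columns = drops/retains."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table total must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the conventional probability-mass ordering: the p-value sums the
    hypergeometric probabilities of every margin-preserving table whose
    probability does not exceed that of the observed table.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2x2")
        ContingencyTable2x2(*arr.ravel().tolist())  # validates
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def chisq_gof(observed, expected) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit; returns (chi2, df, p).

    ``expected`` must be strictly positive in every cell and sum to the
    observed total (no silent rescaling); df = number of cells - 1.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1:
        raise ValueError("observed and expected must be 1D of equal length")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be > 0 in every cell")
    if not np.isclose(observed.sum(), expected.sum(), rtol=1e-8):
        raise ValueError("observed and expected totals differ")
    chi2, p = sps.chisquare(observed, expected)
    return float(chi2), observed.size - 1, float(p)


def build_report(
    summaries: dict[str, pd.DataFrame | None],
    out_dir: str | Path,
    *,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    timestamp: str | None = None,
) -> dict:
    """Write summary tables plus a YAML run manifest; returns the manifest.

    Each (name -> DataFrame) entry becomes ``<name>.csv`` under ``out_dir``;
    entries mapped to None are omitted and listed in the manifest. The
    manifest records the config (round-trippable through
    :meth:`SimulationConfig.from_yaml`), the seed, the package version and a
    timestamp; tables are written deterministically so identical inputs give
    byte-identical files, timestamp aside.
    """
    from wntbead import __version__

    if not summaries:
        raise ValueError("at least one summary table required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written, omitted = [], []
    for name, df in sorted(summaries.items()):
        if df is None:
            omitted.append(name)
            continue
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(f"{name}.csv")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "tables": written,
        "omitted_sections": omitted,
        "timestamp": timestamp or datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat(),
    }
    (out_dir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return manifest
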