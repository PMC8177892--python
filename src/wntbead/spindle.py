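"""Spindle orientation relative to the bead, with distributional tests.

At anaphase the spindle (major) axis joins the two separating pole masses;
the minor axis is its perpendicular through the division midpoint. The
orientation angle alpha is the acute angle between the minor axis (as an
undirected line) and the vector from the midpoint to the bead, folded into
[0, 90] degrees: 90 deg is a fully bead-oriented division (bead on the
pole-to-pole axis), 0 deg a division parallel to the bead.

Distributions of alpha are summarized as rose-plot histograms (5-degree
bins by default) and compared (a) against a randomized, ligand-independent
null that spreads divisions equally over 0-30 / 30-60 / 60-90 degrees, by
Pearson chi-squared, and (b) between conditions by two-sample
Kolmogorov-Smirnov.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from wntbead.types import DivisionEvent

DEFAULT_BIN_WIDTH = 5.0
_NULL_EDGES = np.array([0.0, 30.0, 60.0, 90.0])


@dataclass(frozen=True)
class AngleDistribution:
    """Binned angle histogram (rose-plot-ready)."""

    angles: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray


def spindle_angle(event: DivisionEvent) -> float:
    """Spindle-to-bead angle alpha in degrees, folded into [0, 90].

    Computed as 90 deg minus the acute angle between the midpoint-to-bead
    vector and the major (pole-to-pole) axis; invariant under pole swap,
    rigid motions and reflections.
    """
    pole_a = np.asarray(event.pole_a, dtype=float)
    pole_b = np.asarray(event.pole_b, dtype=float)
    bead = np.asarray(event.bead, dtype=float)
    for arr, name in ((pole_a, "pole_a"), (pole_b, "pole_b"), (bead, "bead")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} coordinates")

    major = pole_b - pole_a
    norm_major = np.linalg.norm(major)
    if norm_major == 0.0:
        raise ValueError(f"event {event.event_id}: coincident poles")
    mid = (pole_a + pole_b) / 2.0
    v = bead - mid
    norm_v = np.linalg.norm(v)
    if norm_v == 0.0:
        raise ValueError(f"event {event.event_id}: bead at division midpoint")

    # angle between v and the undirected major axis, in [0, 90]
    cos_major = abs(float(np.dot(v, major))) / (norm_v * norm_major)
    cos_major = min(cos_major, 1.0)
    theta_major = math.degrees(math.acos(cos_major))
    return 90.0 - theta_major


def rose_histogram(
    angles, bin_width: float = DEFAULT_BIN_WIDTH
) -> AngleDistribution:
    """Histogram of angles over [0, 90] with the last bin inclusive at 90."""
    angles = np.asarray(angles, dtype=float)
    if angles.size and (np.any(angles < 0) | np.any(angles > 90)):
        bad = angles[(angles < 0) | (angles > 90)][0]
        raise ValueError(f"angle {bad} outside [0, 90]")
    if not (0 < bin_width <= 90):
        raise ValueError("bin_width must lie in (0, 90]")
    edges = np.arange(0.0, 90.0, bin_width)
    edges = np.append(edges, 90.0)
    counts, _ = np.histogram(angles, bins=edges)
    return AngleDistribution(
        angles=angles, bin_width=bin_width, bin_edges=edges, counts=counts
    )


def randomized_null_chisq(
    angles, *, exact: bool = False
) -> tuple[float, int, float]:
    """Chi-squared test of angles against the randomized three-bin null.

    The null assumes divisions equally distributed over 0-30, 30-60 and
    60-90 degrees (bead-independent orientation); returns (chi2, df=2, p).
    With ``exact=True`` the p-value is the exact multinomial tail
    (probability of a chi-squared statistic at least as large under the
    null), recommended for n < 15.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 1:
        raise ValueError("at least one angle required")
    if np.any(angles < 0) or np.any(angles > 90):
        raise ValueError("angles must lie in [0, 90]")
    observed, _ = np.histogram(angles, bins=_NULL_EDGES)
    n = observed.sum()
    expected = np.full(3, n / 3.0)
    chi2, p = stats.chisquare(observed, expected)
    if exact:
        p = _exact_multinomial_p(observed)
    return float(chi2), 2, float(p)


def _exact_multinomial_p(observed: np.ndarray) -> float:
    """Exact multinomial tail P(chi2 >= observed chi2) under equal thirds."""
    n = int(observed.sum())
    expected = n / 3.0
    stat_obs = float(np.sum((observed - expected) ** 2 / expected))
    p = 0.0
    for a, b in itertools.product(range(n + 1), repeat=2):
        c = n - a - b
        if c < 0:
            continue
        stat = ((a - expected) ** 2 + (b - expected) ** 2
                + (c - expected) ** 2) / expected
        if stat >= stat_obs - 1e-12:
            p += math.exp(
                math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(b + 1)
                - math.lgamma(c + 1) - n * math.log(3.0)
            )
    return min(p, 1.0)


def ks_two_sample(
    angles_a,
    angles_b,
    *,
    method: str = "asymp",
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of angle distributions.

    Returns (D, p) with D = sup |ECDF_A - ECDF_B|. ``method='asymp'`` uses
    the asymptotic two-sample formula; ``method='permutation'`` estimates p
    by pooled-label shuffling (seeded), preferable for the small, discrete
    angle samples this assay yields.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d, p = stats.ks_2samp(a, b, method="asymp")
    if method == "asymp":
        return float(d), float(p)
    if method != "permutation":
        raise ValueError("method must be 'asymp' or 'permutation'")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    exceed = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        d_perm = stats.ks_2samp(pooled[:n_a], pooled[n_a:], method="asymp")[0]
        if d_perm >= d - 1e-12:
            exceed += 1
    return float(d), (exceed + 1) / (n_permutations + 1)
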