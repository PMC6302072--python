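"""Angle conventions and the rank statistics used throughout the analysis.

All division and shape orientations are acute angles relative to the AP
axis, in [0, 90]. Measurements made against the (DV-parallel) boundary
are converted via α_division = 90° − α_boundary. Orientation differences
are folded under the nematic convention (axes, not vectors), so a
difference is also always in [0, 90].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DivisionEvent",
    "fold_to_ap",
    "division_angle",
    "angular_difference",
    "stratify_by_elongation",
    "compare_angle_distributions",
    "rank_correlation",
    "angle_histogram",
    "StatResult",
]


@dataclass
class DivisionEvent:
    """One accepted division with its pre-division shape descriptors."""

    mother_id: str
    daughter_ids: tuple[str, str]
    t_abscission_min: float
    alpha_division: float  # deg in [0, 90] vs AP
    alpha_shape: Optional[float] = None  # principal shape axis at t − 12 min
    alpha_vertex: Optional[float] = None  # vertex-cluster axis at t − 12 min
    elongation: Optional[float] = None  # log10(long/short)
    cell_class: Literal["BC", "NBC"] = "NBC"
    boundary_side_angle: float = 90.0  # local PSB orientation, deg vs AP


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int


def fold_to_ap(alpha_boundary: float) -> float:
    """Convert an acute angle measured against the boundary to one
    measured against the AP axis: 90° − α. The boundary is perpendicular
    to AP, so the two descriptions are complementary."""
    if not 0.0 <= alpha_boundary <= 90.0:
        raise ValueError("alpha_boundary must be an acute angle in [0, 90]")
    return 90.0 - alpha_boundary


def division_angle(axis: Sequence[float], local_boundary_orientation_deg: float) -> float:
    """Division angle relative to AP from a spindle/centrosome axis vector.

    The acute angle between the axis and the local boundary direction is
    measured first, then converted with :func:`fold_to_ap`.
    """
    v = np.asarray(axis, dtype=float)
    if np.allclose(v, 0.0):
        raise ValueError("zero-length axis vector")
    axis_deg = np.degrees(np.arctan2(v[1], v[0]))
    diff = (axis_deg - local_boundary_orientation_deg) % 180.0
    acute_to_boundary = min(diff, 180.0 - diff)
    return fold_to_ap(acute_to_boundary)


def angular_difference(a: float, b: float) -> float:
    """|a − b| between two axis orientations, folded into [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def stratify_by_elongation(
    events: Iterable[DivisionEvent], cutoff: float = 0.3
) -> tuple[list[DivisionEvent], list[DivisionEvent]]:
    """Partition events at the elongation cutoff (default 0.3, axis ratio 2).

    Returns (moderate, elongated); an event exactly at the cutoff goes to
    the moderate (≤) group.
    """
    moderate, elongated = [], []
    for e in events:
        if e.elongation is None:
            raise ValueError(f"event {e.mother_id} has no elongation")
        (moderate if e.elongation <= cutoff else elongated).append(e)
    return moderate, elongated


def compare_angle_distributions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    test: Literal["mann_whitney", "ks", "kruskal"] = "mann_whitney",
    exact_threshold: int = 8,
) -> StatResult:
    """Two-sample comparison of (unbinned) angle samples.

    Mann-Whitney is two-tailed; the exact null distribution is used for
    small samples (both n ≤ ``exact_threshold``), the normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        method = "exact" if max(len(a), len(b)) <= exact_threshold else "asymptotic"
        try:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return StatResult("mann_whitney", float(res.statistic), float(res.pvalue),
                          len(a), len(b))
    if test == "ks":
        res = stats.ks_2samp(a, b, method="asymp")
        return StatResult("ks", float(res.statistic), float(res.pvalue), len(a), len(b))
    if test == "kruskal":
        res = stats.kruskal(a, b)
        return StatResult("kruskal", float(res.statistic), float(res.pvalue),
                          len(a), len(b))
    raise ValueError(f"unknown test {test!r}")


def rank_correlation(
    alpha_shape: Sequence[float], alpha_division: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) with mid-ranked ties."""
    a = np.asarray(alpha_shape, dtype=float)
    b = np.asarray(alpha_division, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired samples, n >= 3")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def angle_histogram(
    angles: Sequence[float], bin_width: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of [0, 90] angles for report output (default 15° bins).

    Statistics are always computed on unbinned angles; this is plotting /
    report plumbing only.
    """
    edges = np.arange(0.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.asarray(angles, dtype=float), bins=edges)
    return counts, edges
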