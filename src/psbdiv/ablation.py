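"""Laser-ablation recoil velocimetry and intensity normalisations.

After a junction is cut, the separation of the two cut ends relaxes
toward a plateau; the initial recoil speed — the slope of an ordinary
least-squares line through the first few post-cut timepoints — serves as
a proxy for the tension the junction carried (assuming equal friction
across conditions). The default fit window is the first 5 samples
strictly after the cut frame, using actual timestamps, since frame
delays differ across experiments (0.731 s, 1 s, 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Kymograph",
    "IntensitySeries",
    "RecoilFit",
    "CutPairResult",
    "recoil_fit",
    "recoil_velocity",
    "compare_consecutive_cuts",
    "junction_intensity",
    "wound_intensity_series",
    "peak_time",
]


@dataclass
class Kymograph:
    """Cut-end separation distance vs time after an ablation."""

    times_s: np.ndarray
    separation_um: np.ndarray
    frame_interval_s: float
    cut_index: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.separation_um = np.asarray(self.separation_um, dtype=float)
        if len(self.times_s) != len(self.separation_um):
            raise ValueError("times and separations must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.cut_index < len(self.times_s) - 1:
            raise ValueError("cut_index must leave at least one post-cut sample")


@dataclass
class IntensitySeries:
    times_s: np.ndarray
    roi_mean: np.ndarray
    reference_mean: np.ndarray
    normalized: np.ndarray


@dataclass(frozen=True)
class RecoilFit:
    velocity_um_s: float
    intercept_um: float
    r_squared: float
    n_fit: int


@dataclass(frozen=True)
class CutPairResult:
    v_first_um_s: float
    v_second_um_s: float
    ratio: float


def recoil_fit(k: Kymograph, n_fit: int = 5) -> RecoilFit:
    """OLS line through the first ``n_fit`` timepoints strictly after the
    cut frame; the slope is the recoil velocity (µm/s).

    The pre-cut (t = cut) point is excluded; include it by lowering
    ``cut_index`` if a sensitivity check is wanted.
    """
    start = k.cut_index + 1
    if len(k.times_s) - start < n_fit:
        raise ValueError(
            f"need {n_fit} post-cut samples, have {len(k.times_s) - start}"
        )
    t = k.times_s[start : start + n_fit]
    d = k.separation_um[start : start + n_fit]
    res = stats.linregress(t, d)
    return RecoilFit(
        velocity_um_s=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_fit=n_fit,
    )


def recoil_velocity(k: Kymograph, n_fit: int = 5) -> float:
    return recoil_fit(k, n_fit=n_fit).velocity_um_s


def compare_consecutive_cuts(
    first: Kymograph, second: Kymograph, n_fit: int = 5
) -> CutPairResult:
    """Paired recoil velocities and their ratio v_second / v_first.

    A second cut on an already-released cable recoils more slowly; the
    ratio quantifies the drop.
    """
    v1 = recoil_velocity(first, n_fit=n_fit)
    v2 = recoil_velocity(second, n_fit=n_fit)
    if v1 == 0:
        raise ZeroDivisionError("first cut has zero recoil velocity")
    return CutPairResult(v_first_um_s=v1, v_second_um_s=v2, ratio=v2 / v1)


def junction_intensity(roi_mean: float, cytoplasm_mean: float) -> float:
    """Junctional signal normalised by the cytoplasmic signal of the same
    cell (ratio)."""
    if cytoplasm_mean <= 0:
        raise ValueError("cytoplasm reference must be positive")
    return roi_mean / cytoplasm_mean


def wound_intensity_series(
    times_s, roi_means, frame_means
) -> IntensitySeries:
    """Bleaching-corrected wound signal: ROI mean minus the whole-frame
    mean at each timepoint."""
    t = np.asarray(times_s, dtype=float)
    roi = np.asarray(roi_means, dtype=float)
    ref = np.asarray(frame_means, dtype=float)
    if not (len(t) == len(roi) == len(ref)):
        raise ValueError("series must have equal lengths")
    return IntensitySeries(times_s=t, roi_mean=roi, reference_mean=ref,
                           normalized=roi - ref)


def peak_time(series: IntensitySeries) -> float:
    """Time of the (first) maximum of the normalised series, seconds."""
    idx = int(np.argmax(series.normalized))  # argmax takes the first maximum
    return float(series.times_s[idx])
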