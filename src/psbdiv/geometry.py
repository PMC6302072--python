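"""Planar polygon primitives shared across the package.

All polygons are (N, 2) float arrays of vertices in µm, ordered
counter-clockwise (positive signed area). Moments are computed in closed
form from the vertex list (Green's theorem / signed fan triangulation),
so they are exact for simple polygons, convex or not.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "signed_area",
    "ensure_ccw",
    "area_centroid",
    "perimeter_length",
    "resample_perimeter",
    "second_moment_area",
    "principal_angle_deg",
    "eig2x2_sym",
]


def signed_area(polygon: np.ndarray) -> float:
    """Signed area; positive for counter-clockwise vertex order."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y2 - x2 * y))


def ensure_ccw(polygon: np.ndarray) -> np.ndarray:
    p = np.asarray(polygon, dtype=float)
    if signed_area(p) < 0:
        return p[::-1].copy()
    return p


def area_centroid(polygon: np.ndarray) -> np.ndarray:
    """Centroid of the enclosed area (not the vertex mean)."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-15:
        raise ValueError("degenerate polygon: zero area")
    cx = float(((x + x2) * cross).sum() / (6.0 * a))
    cy = float(((y + y2) * cross).sum() / (6.0 * a))
    return np.array([cx, cy])


def perimeter_length(polygon: np.ndarray) -> float:
    p = np.asarray(polygon, dtype=float)
    seg = np.roll(p, -1, axis=0) - p
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def resample_perimeter(polygon: np.ndarray, n: int) -> np.ndarray:
    """``n`` points spaced uniformly in arc length along the closed outline.

    The first sample sits on vertex 0; spacing is perimeter / n, so the
    sample set is independent of which vertex is first only up to a phase.
    """
    p = np.asarray(polygon, dtype=float)
    seg = np.roll(p, -1, axis=0) - p
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seglen == 0):
        keep = seglen > 0
        p, seg, seglen = p[keep], seg[keep], seglen[keep]
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polygon: zero perimeter")
    s = np.linspace(0.0, total, n, endpoint=False)
    i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(p) - 1)
    frac = (s - cum[i]) / seglen[i]
    return p[i] + frac[:, None] * seg[i]


def second_moment_area(polygon: np.ndarray, about: np.ndarray | None = None) -> np.ndarray:
    """Central 2x2 second moment of the enclosed area, ∫∫ r rᵀ dA.

    Computed by signed fan triangulation from ``about`` (default: the area
    centroid), which is exact for any simple polygon.
    """
    p = ensure_ccw(polygon)
    c = area_centroid(p) if about is None else np.asarray(about, dtype=float)
    q = p - c
    m = np.zeros((2, 2))
    for i in range(len(q)):
        a = q[i]
        b = q[(i + 1) % len(q)]
        cr = a[0] * b[1] - a[1] * b[0]  # 2 * signed triangle area
        m += (cr / 12.0) * (
            np.outer(a, a) + np.outer(b, b) + 0.5 * (np.outer(a, b) + np.outer(b, a))
        )
    return m


def eig2x2_sym(m: np.ndarray) -> tuple[float, float]:
    """(lambda_min, lambda_max) of a symmetric 2x2 matrix, closed form.

    The eigenvalue half-gap is evaluated as hypot((mxx−myy)/2, mxy) —
    never via sqrt(trace²/4 − det), which cancels catastrophically for
    near-isotropic matrices and would put a ~1e-8 floor on eta.
    """
    t = 0.5 * (m[0, 0] + m[1, 1])
    off = 0.5 * (m[0, 1] + m[1, 0])
    s = float(np.hypot(0.5 * (m[0, 0] - m[1, 1]), off))
    return float(t - s), float(t + s)


def principal_angle_deg(m: np.ndarray) -> float:
    """Orientation of the major eigenvector, degrees in [0, 180).

    Uses the closed form θ = ½·atan2(2·mxy, mxx − myy), which is exact for
    symmetric 2x2 matrices and avoids eigenvector sign ambiguity.
    """
    theta = 0.5 * np.degrees(np.arctan2(2.0 * m[0, 1], m[0, 0] - m[1, 1]))
    theta = float(theta % 180.0)
    # a tiny negative angle can round to exactly 180.0 after the modulo
    return 0.0 if theta >= 180.0 else theta
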