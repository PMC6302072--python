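"""Cell-shape and tricellular-vertex polarity tensors.

An epithelial cell carries two nematic descriptors, each derived from a
symmetric 2x2 second-moment ("inertia") matrix built from vectors rooted
at the cell's area centroid:

* the **shape tensor** summarises the anisotropy of the cell outline —
  by default the second moment of the enclosed area, ∫∫ r rᵀ dA, the
  standard inertia matrix of a pixel mask;
* the **vertex tensor** summarises the angular distribution of the cell's
  tricellular vertices (points where three cells meet) — the sum of
  outer products of *unit* centroid→vertex vectors, so only the angular
  positions of the vertices matter, not their distances.

Both are reported as an orientation θ (degrees relative to the AP axis,
nematic, [0, 180)) and a magnitude η = 1 − λmin/λmax ∈ [0, 1]: 0 for an
isotropic cell (e.g. a regular hexagon), 1 for an infinitely stretched
outline or for vertices split into two diametrically opposed groups.

The unit-vector convention for the vertex tensor and the area-moment
convention for the shape tensor are calibrated against the worked
straight-boundary hexagon example (η_vertex ≈ 0.21 perpendicular to the
boundary, η_shape ≈ 0.13 parallel to it); see docs/methods.md. A
perimeter-sampling variant of the shape tensor is available via
``method="perimeter"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .geometry import (
    area_centroid,
    eig2x2_sym,
    ensure_ccw,
    principal_angle_deg,
    resample_perimeter,
    second_moment_area,
    signed_area,
)

__all__ = [
    "CellSnapshot",
    "PolarityTensor",
    "EllipseFit",
    "shape_tensor",
    "vertex_tensor",
    "fit_ellipse",
    "build_fig4a_configuration",
    "boundary_example_cell",
    "ISOTROPY_RTOL",
]

#: Relative eigenvalue gap below which a tensor is treated as isotropic
#: and its orientation reported as undefined (``theta=None``).
ISOTROPY_RTOL = 1e-9


@dataclass
class CellSnapshot:
    """One segmented cell at one movie frame.

    ``polygon`` is an ordered (N, 2) array of vertex positions in µm,
    counter-clockwise. ``tricellular`` holds the indices of the polygon
    vertices that are tricellular (shared by three cells).
    """

    cell_id: str
    frame: int
    time_min: float
    polygon: np.ndarray
    tricellular: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    is_boundary_cell: bool = False
    parent_id: Optional[str] = None
    myosin_proxy: Optional[float] = None

    def __post_init__(self) -> None:
        self.polygon = ensure_ccw(np.asarray(self.polygon, dtype=float))
        self.tricellular = np.asarray(self.tricellular, dtype=int)
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    @property
    def centroid(self) -> np.ndarray:
        return area_centroid(self.polygon)

    @property
    def area(self) -> float:
        return abs(signed_area(self.polygon))

    @property
    def tricellular_points(self) -> np.ndarray:
        return self.polygon[self.tricellular]


@dataclass(frozen=True)
class PolarityTensor:
    """Orientation + magnitude of a 2x2 polarity (inertia) tensor.

    ``theta`` is None when the tensor is isotropic to within
    :data:`ISOTROPY_RTOL` — an η ≈ 0 tensor has no meaningful axis.
    """

    theta: Optional[float]
    eta: float
    lambda_max: float
    lambda_min: float
    kind: Literal["shape", "vertex"]

    @classmethod
    def from_matrix(cls, m: np.ndarray, kind: Literal["shape", "vertex"]) -> "PolarityTensor":
        lmin, lmax = eig2x2_sym(m)
        if lmax <= 0:
            raise ValueError("polarity tensor is not positive semidefinite")
        eta = 1.0 - lmin / lmax
        theta = None if (lmax - lmin) < ISOTROPY_RTOL * lmax else principal_angle_deg(m)
        return cls(theta=theta, eta=float(eta), lambda_max=lmax, lambda_min=lmin, kind=kind)

    @property
    def is_isotropic(self) -> bool:
        return self.theta is None


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a polygon (Fiji best-fit style).

    Axes are full lengths (diameters), µm. ``elongation`` is
    log10(long/short); 0.3 corresponds to an axis ratio of 2.
    """

    long_axis: float
    short_axis: float
    orientation: float  # deg in [0, 180)
    elongation: float


def shape_tensor(
    cell: CellSnapshot,
    n_samples: int = 360,
    method: Literal["area", "perimeter"] = "area",
) -> PolarityTensor:
    """Shape polarity tensor of a cell outline.

    ``method="area"`` (default, calibrated): closed-form second moment of
    the enclosed area about the centroid. ``method="perimeter"``: second
    moment Σ r rᵀ of centroid-to-perimeter vectors at ``n_samples`` points
    uniform in arc length (requires n_samples ≥ 36).
    """
    if method == "area":
        m = second_moment_area(cell.polygon)
    elif method == "perimeter":
        if n_samples < 36:
            raise ValueError("n_samples must be >= 36 for perimeter sampling")
        c = cell.centroid
        pts = resample_perimeter(cell.polygon, n_samples) - c
        m = pts.T @ pts
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown method {method!r}")
    return PolarityTensor.from_matrix(m, kind="shape")


def vertex_tensor(cell: CellSnapshot) -> PolarityTensor:
    """Tricellular-vertex polarity tensor.

    Sum of outer products of unit centroid→tricellular-vertex vectors:
    η = 0 for uniformly distributed vertices, 1 when the vertices fall
    into two diametrically opposed groups.
    """
    pts = cell.tricellular_points
    if len(pts) < 2:
        raise ValueError("vertex tensor needs at least 2 tricellular vertices")
    v = pts - cell.centroid
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(norms == 0):
        raise ValueError("tricellular vertex coincides with centroid")
    u = v / norms[:, None]
    m = u.T @ u
    return PolarityTensor.from_matrix(m, kind="vertex")


def fit_ellipse(cell: CellSnapshot) -> EllipseFit:
    """Moment-equivalent ellipse: same area and second area moments.

    For covariance eigenvalues λ (second moments / area) the semi-axes
    are 2·sqrt(λ), hence full axes 4·sqrt(λ).
    """
    a = cell.area
    if a <= 0:
        raise ValueError("degenerate polygon: zero area")
    m = second_moment_area(cell.polygon) / a
    lmin, lmax = eig2x2_sym(m)
    if lmin <= 0:
        raise ValueError("degenerate polygon: collapsed ellipse")
    long_axis = 4.0 * float(np.sqrt(lmax))
    short_axis = 4.0 * float(np.sqrt(lmin))
    orientation = principal_angle_deg(m)
    return EllipseFit(
        long_axis=long_axis,
        short_axis=short_axis,
        orientation=orientation,
        elongation=float(np.log10(long_axis / short_axis)),
    )


def build_fig4a_configuration(straightening: float) -> list[CellSnapshot]:
    """Hexagonal packing with a (partially) straightened column boundary.

    Deterministic worked-example construction: a noise-free hexagonal
    epithelium whose central column interface — natively a zig-zag — has
    its vertices displaced toward the straight boundary line (the mean
    line of the zig-zag) by fraction ``straightening``. At 0 every cell
    is a regular hexagon and both polarity tensors vanish; at 1 the
    boundary cells acquire vertex clustering perpendicular to the
    boundary and a small shape elongation parallel to it.
    """
    if not 0.0 <= straightening <= 1.0:
        raise ValueError("straightening must lie in [0, 1]")
    from .synthetic import EpitheliumSpec, gen_epithelium

    spec = EpitheliumSpec(
        n_columns=4,
        n_rows=5,
        cell_circumradius=1.0,
        boundary_column=1,
        boundary_straightening=straightening,
        shape_noise_sd=0.0,
        seed=0,
    )
    return gen_epithelium(spec).cells


def boundary_example_cell(cells: Sequence[CellSnapshot]) -> CellSnapshot:
    """The worked-example boundary cell: interior BC with all six vertices
    tricellular (mid-row cell of the column left of the boundary)."""
    candidates = [c for c in cells if c.is_boundary_cell and len(c.tricellular) == 6]
    if not candidates:
        raise ValueError("no interior boundary cell in configuration")
    # mid-row, left-flank cell: smallest centroid x among candidates whose
    # centroid y is closest to the tissue median
    ys = np.array([c.centroid[1] for c in candidates])
    med = np.median(ys)
    best = sorted(candidates, key=lambda c: (abs(c.centroid[1] - med), c.centroid[0]))
    return best[0]
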