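"""Centrosome trajectory metrics and proximal/distal role assignment.

A centrosome track is a timed sequence of 3D positions (2D accepted with
z = 0) from nuclear-envelope breakdown to cytokinesis, assumed drift
corrected. Motility is summarised by total distance travelled, net
displacement, the DV (y) component of displacement, average speed and
persistence = displacement / distance ∈ [0, 1].

Within a dividing boundary cell the two centrosomes are labelled pCen
(proximal to the boundary) and dCen (distal) by their mean perpendicular
distance to the boundary polyline in the xy plane — the boundary cable
is an apical structure, so z is ignored for proximity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "CentrosomeTrack",
    "TrackMetrics",
    "track_metrics",
    "assign_roles",
    "classify_division_orientation",
]


@dataclass
class CentrosomeTrack:
    centrosome_id: str
    cell_id: str
    times_s: np.ndarray  # strictly increasing, seconds
    positions: np.ndarray  # (N, 3) µm; (N, 2) accepted, z = 0
    role: Literal["pCen", "dCen", "unassigned"] = "unassigned"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[0] != len(self.times_s):
            raise ValueError("positions must be (N, 2|3) matching times")
        if pos.shape[1] == 2:
            pos = np.column_stack([pos, np.zeros(len(pos))])
        self.positions = pos
        if len(self.times_s) < 2:
            raise ValueError("track needs at least 2 timepoints")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class TrackMetrics:
    mean_speed_um_min: float
    total_distance_um: float
    displacement_um: float
    dv_displacement_um: float
    persistence: float
    instantaneous_speeds_um_min: np.ndarray  # per interval, for time curves


def track_metrics(track: CentrosomeTrack) -> TrackMetrics:
    """Path metrics; persistence is 0 by convention for a zero-length path."""
    steps = np.diff(track.positions, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    total = float(step_len.sum())
    disp = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    dv = float(abs(track.positions[-1, 1] - track.positions[0, 1]))
    elapsed_min = (track.times_s[-1] - track.times_s[0]) / 60.0
    dt_min = np.diff(track.times_s) / 60.0
    return TrackMetrics(
        mean_speed_um_min=total / elapsed_min,
        total_distance_um=total,
        displacement_um=disp,
        dv_displacement_um=dv,
        persistence=disp / total if total > 0 else 0.0,
        instantaneous_speeds_um_min=step_len / dt_min,
    )


def _mean_boundary_distance(track: CentrosomeTrack, boundary: LineString) -> float:
    return float(
        np.mean([boundary.distance(Point(p[0], p[1])) for p in track.positions])
    )


def assign_roles(
    tracks_by_cell: Mapping[str, Sequence[CentrosomeTrack]],
    boundary_polyline: np.ndarray,
    boundary_cells: Optional[set[str]] = None,
) -> dict[str, str]:
    """Label the two centrosomes of each dividing boundary cell.

    The centrosome with the smaller whole-track mean xy distance to the
    boundary is pCen, the other dCen; ties are broken by first-frame
    distance, then by centrosome id (deterministic). Cells not in
    ``boundary_cells`` (when given) are left unassigned, as proximity to
    a boundary is meaningless for NBC divisions.
    """
    line = LineString(np.asarray(boundary_polyline, dtype=float))
    roles: dict[str, str] = {}
    for cell_id, tracks in tracks_by_cell.items():
        if boundary_cells is not None and cell_id not in boundary_cells:
            for t in tracks:
                t.role = "unassigned"
                roles[t.centrosome_id] = "unassigned"
            continue
        if len(tracks) != 2:
            raise ValueError(f"cell {cell_id}: expected 2 centrosomes, got {len(tracks)}")
        keyed = sorted(
            tracks,
            key=lambda t: (
                round(_mean_boundary_distance(t, line), 12),
                round(float(line.distance(Point(t.positions[0, 0], t.positions[0, 1]))), 12),
                t.centrosome_id,
            ),
        )
        keyed[0].role = "pCen"
        keyed[1].role = "dCen"
        roles[keyed[0].centrosome_id] = "pCen"
        roles[keyed[1].centrosome_id] = "dCen"
    return roles


def classify_division_orientation(alpha_division: float) -> Literal["AP", "DV"]:
    """AP-oriented iff α < 45°, DV-oriented otherwise (45° counts as DV)."""
    if not 0.0 <= alpha_division <= 90.0:
        raise ValueError("alpha_division must lie in [0, 90]")
    return "AP" if alpha_division < 45.0 else "DV"
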