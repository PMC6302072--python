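"""Automated division-event detection from tracked-cell tables.

A lineage split (one mother linked to two daughters) is accepted as a
cell division only if it carries the full morphological signature of
mitosis, mirroring how dividing cells are vetted in tracked epithelia:

1. each daughter's area at abscission is an approximate half of the
   mother's area at the prior frame (within ``halving_band``);
2. the mother's area increases over the preceding 10 minutes
   (least-squares slope > 0, robust to single-frame noise);
3. the mother's elongation AND perimeter²/area both increase over the
   preceding 3 minutes (anaphase cell elongation);
4. the mother forms a dumbbell within the last minute: the minimum neck
   width along its principal axis drops below ``dumbbell_neck_ratio``
   times the maximum width (a geometric stand-in for the Myosin
   cytokinesis ring — tracker output, not pixels, is the interface).

Accepted events get their division angle from the daughter-centroid axis
at abscission and their shape/vertex descriptors from the mother's
snapshot 12 minutes earlier (≈ NEBD). Splits that cannot be evaluated
because frames are missing are reported as unevaluable, never silently
rejected. An explicit ``exclude`` list replaces manual curation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.geometry import Polygon as ShapelyPolygon

from .angles import DivisionEvent
from .geometry import perimeter_length, principal_angle_deg, second_moment_area
from .polarity import CellSnapshot, fit_ellipse, shape_tensor, vertex_tensor
from .synthetic import fold_axis_angle

__all__ = [
    "DetectionConfig",
    "DetectionResult",
    "detect_divisions",
    "neck_width_ratio",
    "classify_cells",
]


@dataclass(frozen=True)
class DetectionConfig:
    halving_band: tuple[float, float] = (0.35, 0.65)
    growth_window_min: float = 10.0
    rounding_window_min: float = 3.0
    dumbbell_window_min: float = 1.0
    dumbbell_neck_ratio: float = 0.6
    frame_interval_s: float = 30.0
    reference_offset_min: float = 12.0  # NEBD reference before abscission
    reference_tolerance_min: float = 1.0
    min_window_points: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.halving_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("halving_band must be an interval inside (0, 1)")
        if min(self.growth_window_min, self.rounding_window_min,
               self.dumbbell_window_min) <= 0:
            raise ValueError("windows must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class DetectionResult:
    events: list[DivisionEvent]
    audit: pd.DataFrame  # one row per candidate split with per-criterion flags

    @property
    def accepted_ids(self) -> set[str]:
        return {e.mother_id for e in self.events}


def neck_width_ratio(polygon: np.ndarray, n_stations: int = 41) -> float:
    """Minimum/maximum width of the outline measured along its principal axis.

    The polygon is rotated so its principal (area-inertia) axis is
    horizontal; widths are the lengths of vertical chords at stations
    across the long axis. The minimum is taken between the widest
    stations of the left and right halves, so tapering ends (an ellipse's
    tips) do not register as a neck: a convex outline scores ≈ 1, a
    dumbbell scores the waist/lobe ratio.
    """
    p = np.asarray(polygon, dtype=float)
    ang = np.radians(principal_angle_deg(second_moment_area(p)))
    rot = np.array([[np.cos(-ang), -np.sin(-ang)], [np.sin(-ang), np.cos(-ang)]])
    q = p @ rot.T
    shp = ShapelyPolygon(q)
    if not shp.is_valid:
        shp = shp.buffer(0)
    xmin, ymin, xmax, ymax = shp.bounds
    margin = 0.01 * (xmax - xmin)
    xs = np.linspace(xmin + margin, xmax - margin, n_stations)
    widths = np.empty(n_stations)
    for i, x in enumerate(xs):
        chord = LineString([(x, ymin - 1.0), (x, ymax + 1.0)])
        widths[i] = chord.intersection(shp).length
    half = n_stations // 2
    i_left = int(np.argmax(widths[:half]))
    i_right = half + int(np.argmax(widths[half:]))
    w_max = float(widths.max())
    if w_max <= 0:
        raise ValueError("degenerate polygon: zero width")
    w_neck = float(widths[i_left : i_right + 1].min())
    return min(w_neck / w_max, 1.0)


def classify_cells(
    cells: Sequence[CellSnapshot],
    boundary_polyline: np.ndarray,
    tol_um: float = 0.1,
) -> dict[str, str]:
    """BC/NBC labels: a cell is BC iff at least one polygon edge lies
    within ``tol_um`` of the boundary polyline.

    An edge counts as on-boundary when both endpoints and the midpoint
    are within tolerance — a single touching vertex does not make a
    boundary cell (documented convention).
    """
    line = LineString(np.asarray(boundary_polyline, dtype=float))
    labels: dict[str, str] = {}
    for cell in cells:
        poly = cell.polygon
        is_bc = False
        for i in range(len(poly)):
            a, b = poly[i], poly[(i + 1) % len(poly)]
            probe = (a, 0.5 * (a + b), b)
            if all(line.distance(Point(p)) <= tol_um for p in probe):
                is_bc = True
                break
        labels[cell.cell_id] = "BC" if is_bc else "NBC"
    return labels


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    denom = float((t * t).sum())
    if denom == 0:
        return 0.0
    return float((t * (y - y.mean())).sum() / denom)


def detect_divisions(
    cells: Sequence[CellSnapshot],
    config: DetectionConfig = DetectionConfig(),
    boundary_polyline: Optional[np.ndarray] = None,
    exclude: Optional[set[str]] = None,
) -> DetectionResult:
    """Run the four-criterion filter chain over all lineage splits.

    ``cells`` is the full per-frame snapshot list (every cell at every
    frame, with ``parent_id`` links on daughters). ``exclude`` removes
    listed mother ids after detection — the auditable replacement for
    manual false-positive curation.
    """
    exclude = exclude or set()
    by_cell: dict[str, list[CellSnapshot]] = {}
    for s in cells:
        by_cell.setdefault(s.cell_id, []).append(s)
    for tr in by_cell.values():
        tr.sort(key=lambda s: s.frame)

    daughters_of: dict[str, list[str]] = {}
    for cid, tr in by_cell.items():
        parent = tr[0].parent_id
        if parent is not None:
            daughters_of.setdefault(parent, []).append(cid)

    events: list[DivisionEvent] = []
    audit_rows: list[dict] = []

    for mother_id, dlist in sorted(daughters_of.items()):
        if len(dlist) != 2 or mother_id not in by_cell:
            continue
        mtrack = by_cell[mother_id]
        d1, d2 = (by_cell[d][0] for d in sorted(dlist))
        t_absc = d1.time_min
        prior = [s for s in mtrack if s.time_min < t_absc]
        if not prior:
            continue
        row = dict(mother_id=mother_id, t_abscission_min=t_absc,
                   halving=None, growth=None, rounding=None, dumbbell=None,
                   unevaluable=False, accepted=False)

        # (1) approximate halving
        a_mother = prior[-1].area
        lo, hi = config.halving_band
        row["halving"] = bool(
            lo <= d1.area / a_mother <= hi and lo <= d2.area / a_mother <= hi
        )

        dt_min = config.frame_interval_s / 60.0

        def window(width_min: float) -> Optional[list[CellSnapshot]]:
            """Frames in the pre-abscission window; None when the track
            does not actually span it (missing history)."""
            win = [s for s in prior if s.time_min >= t_absc - width_min - 1e-9]
            if len(win) < config.min_window_points:
                return None
            if win[0].time_min > t_absc - width_min + 2.0 * dt_min:
                return None
            return win

        # (2) area growth over the 10 min window
        win = window(config.growth_window_min)
        if win is None:
            row["unevaluable"] = True
        else:
            t = np.array([s.time_min for s in win])
            a = np.array([s.area for s in win])
            row["growth"] = bool(_slope(t, a) > 0)

        # (3) elongation and perimeter^2/area both increasing over 3 min
        win = window(config.rounding_window_min)
        if win is None:
            row["unevaluable"] = True
        else:
            t = np.array([s.time_min for s in win])
            elong = np.array([fit_ellipse(s).elongation for s in win])
            p2a = np.array([perimeter_length(s.polygon) ** 2 / s.area for s in win])
            row["rounding"] = bool(_slope(t, elong) > 0 and _slope(t, p2a) > 0)

        # (4) dumbbell neck within the last minute
        win = window(config.dumbbell_window_min)
        if win is None:
            row["unevaluable"] = True
        else:
            necks = [neck_width_ratio(s.polygon) for s in win]
            row["dumbbell"] = bool(min(necks) < config.dumbbell_neck_ratio)

        passed = (
            not row["unevaluable"]
            and all(row[k] for k in ("halving", "growth", "rounding", "dumbbell"))
        )
        if passed and mother_id not in exclude:
            axis = d1.centroid - d2.centroid
            alpha_div = fold_axis_angle(float(np.degrees(np.arctan2(axis[1], axis[0]))))
            ref = _reference_snapshot(mtrack, t_absc, config)
            alpha_shape = alpha_vertex = elong_ref = None
            cell_class = "NBC"
            if ref is not None:
                st = shape_tensor(ref)
                alpha_shape = (
                    None if st.theta is None else fold_axis_angle(st.theta)
                )
                if len(ref.tricellular) >= 2:
                    vt = vertex_tensor(ref)
                    alpha_vertex = (
                        None if vt.theta is None else fold_axis_angle(vt.theta)
                    )
                elong_ref = fit_ellipse(ref).elongation
                if boundary_polyline is not None:
                    cell_class = classify_cells([ref], boundary_polyline)[ref.cell_id]
                else:
                    cell_class = "BC" if ref.is_boundary_cell else "NBC"
            events.append(
                DivisionEvent(
                    mother_id=mother_id,
                    daughter_ids=(d1.cell_id, d2.cell_id),
                    t_abscission_min=t_absc,
                    alpha_division=alpha_div,
                    alpha_shape=alpha_shape,
                    alpha_vertex=alpha_vertex,
                    elongation=elong_ref,
                    cell_class=cell_class,
                )
            )
            row["accepted"] = True
        audit_rows.append(row)

    audit = pd.DataFrame(
        audit_rows,
        columns=["mother_id", "t_abscission_min", "halving", "growth",
                 "rounding", "dumbbell", "unevaluable", "accepted"],
    )
    return DetectionResult(events=events, audit=audit)


def _reference_snapshot(
    mtrack: list[CellSnapshot], t_absc: float, config: DetectionConfig
) -> Optional[CellSnapshot]:
    """Mother snapshot nearest to 12 min before abscission (≈ NEBD)."""
    target = t_absc - config.reference_offset_min
    best = min(mtrack, key=lambda s: abs(s.time_min - target))
    if abs(best.time_min - target) > config.reference_tolerance_min:
        return None
    return best
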