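"""Synthetic epithelium, division-track, centrosome-walk and kymograph
generators with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes, not pixel data:

* a hexagonally packed epithelium whose cells are "pointy" toward a
  vertical compartment boundary, so the native inter-column interface is
  a zig-zag that a tension-bearing cable would straighten;
* division events whose orientation is drawn from a mixture of a
  long-axis-following component and a boundary-perpendicular component,
  with the full morphological signature of a division (area growth,
  anaphase elongation, cytokinetic dumbbell, halving into daughters) and
  configurable distractor tracks carrying only partial signatures;
* centrosome random walks with tunable drift and tethering;
* post-ablation recoil curves d(t) = d0 + v0·τ·(1 − exp(−t/τ)) + noise.

Axis convention: x = AP (anterior→posterior), y = DV, units µm; the
boundary line is vertical (parallel to DV). All generators are
deterministic given spec + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ablation import Kymograph
from .centrosomes import CentrosomeTrack
from .polarity import CellSnapshot

__all__ = [
    "EpitheliumSpec",
    "Epithelium",
    "DivisionMixtureSpec",
    "TrackTimingConfig",
    "DivisionTracks",
    "WalkSpec",
    "RecoilSpec",
    "gen_epithelium",
    "gen_division_tracks",
    "gen_centrosome_walk",
    "gen_kymograph",
    "tracks_to_frame",
    "frame_to_snapshots",
    "fold_axis_angle",
]

_KEY_DECIMALS = 9  # lattice-vertex identity is keyed on rounded coordinates


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EpitheliumSpec:
    """Hexagonal packing with an optional straightened column boundary.

    ``boundary_column`` = j places the boundary on the interface between
    columns j and j+1; ``boundary_straightening`` ∈ [0, 1] moves the
    interface vertices from the native zig-zag (0) onto the straight
    boundary line (1), the mean line of the zig-zag.
    """

    n_columns: int = 4
    n_rows: int = 5
    cell_circumradius: float = 2.5
    boundary_column: Optional[int] = None
    boundary_straightening: float = 0.0
    shape_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_columns < 2 or self.n_rows < 2:
            raise ValueError("n_columns and n_rows must both be >= 2")
        if self.cell_circumradius <= 0:
            raise ValueError("cell_circumradius must be positive")
        if not 0.0 <= self.boundary_straightening <= 1.0:
            raise ValueError("boundary_straightening must lie in [0, 1]")
        if self.boundary_column is not None and not (
            0 <= self.boundary_column <= self.n_columns - 2
        ):
            raise ValueError("boundary_column must index an interior interface")


@dataclass
class Epithelium:
    cells: list[CellSnapshot]
    boundary_polyline: Optional[np.ndarray]  # (M, 2), sorted by y, or None
    spec: EpitheliumSpec


@dataclass(frozen=True)
class DivisionMixtureSpec:
    """Two-component division-orientation mixture.

    A boundary cell divides perpendicular to the boundary (angle ≈ 0°
    relative to AP) with probability ``p_boundary_bias``; otherwise — and
    always for non-boundary cells — the division follows the cell's own
    interphase long axis. Angular scatter is Gaussian with the given SDs
    (degrees). ``elongation_distribution`` gives (mean, sd) of the
    truncated-normal log10 axis-ratio draw.
    """

    p_boundary_bias: float = 0.7
    shape_angle_sd_deg: float = 15.0
    boundary_angle_sd_deg: float = 15.0
    elongation_distribution: tuple[float, float] = (0.25, 0.12)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_boundary_bias <= 1.0:
            raise ValueError("p_boundary_bias must lie in [0, 1]")
        if self.shape_angle_sd_deg <= 0 or self.boundary_angle_sd_deg <= 0:
            raise ValueError("angular SDs must be positive")


@dataclass(frozen=True)
class TrackTimingConfig:
    """Frame timing and event counts for the division-track generator."""

    frame_interval_s: float = 30.0
    history_min: float = 16.0  # mother track length before abscission
    post_min: float = 1.0  # daughter frames after abscission
    n_events: int = 20
    n_distractors: int = 0
    distractor_kinds: tuple[str, ...] = (
        "uneven_split",
        "no_growth",
        "no_rounding",
        "no_neck",
    )
    include_static_cells: bool = False

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.history_min < 13.0:
            raise ValueError("history_min must cover the 12 min pre-division window")


@dataclass
class DivisionTracks:
    """Track table (tidy long format) plus the latent ground truth."""

    table: pd.DataFrame
    truth: list[dict]
    boundary_polyline: Optional[np.ndarray]


@dataclass(frozen=True)
class WalkSpec:
    """Tethered random walk emulating centrosome motility.

    ``tether_strength`` ∈ [0, 1] pulls each step back toward
    ``tether_point``: 0 = free walk, 1 = pinned at the tether.
    """

    n_steps: int = 40
    dt: float = 20.0  # s
    step_sd: float = 0.25  # µm
    drift: tuple[float, ...] = (0.0, 0.0, 0.0)
    tether_point: Optional[tuple[float, ...]] = None
    tether_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0.0 <= self.tether_strength <= 1.0:
            raise ValueError("tether_strength must lie in [0, 1]")


@dataclass(frozen=True)
class RecoilSpec:
    """Post-ablation cut-end separation curve.

    d(t) = d0 + v0·τ·(1 − exp(−t/τ)) + N(0, noise_sd); the derivative at
    t = 0 equals v0. ``d0`` is the separation right after the cut.
    """

    v0: float = 0.5  # µm/s
    tau: float = 10.0  # s
    dt: float = 1.0  # s
    n_frames: int = 21
    noise_sd: float = 0.0  # µm
    d0: float = 0.5  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


# --------------------------------------------------------------------------
# epithelium
# --------------------------------------------------------------------------

def _hex_vertices(cx: float, cy: float, r: float) -> np.ndarray:
    ang = np.radians([0.0, 60.0, 120.0, 180.0, 240.0, 300.0])
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _vkey(pt: np.ndarray) -> tuple[float, float]:
    return (round(float(pt[0]), _KEY_DECIMALS), round(float(pt[1]), _KEY_DECIMALS))


def gen_epithelium(spec: EpitheliumSpec) -> Epithelium:
    """Hexagonal lattice of simple, counter-clockwise cell polygons.

    Cells point toward the boundary (vertices on the AP axis), so each
    inter-column interface is a zig-zag through tricellular vertices at
    two alternating x positions. If ``boundary_column`` is set, that
    interface's vertices are displaced toward their projection on the
    straight boundary line by ``boundary_straightening``; the flanking
    cells are flagged as boundary cells (BC).
    """
    r = spec.cell_circumradius
    dx, dy = 1.5 * r, np.sqrt(3.0) * r
    rng = np.random.default_rng(spec.seed)

    # lattice polygons keyed by (column, row); shared-vertex identity via
    # rounded keys, but geometry keeps the first-encountered exact position
    # so shared vertices are bit-identical across cells
    raw: dict[tuple[int, int], np.ndarray] = {}
    usage: dict[tuple[float, float], set[tuple[int, int]]] = {}
    exact: dict[tuple[float, float], np.ndarray] = {}
    for j in range(spec.n_columns):
        for i in range(spec.n_rows):
            cy = dy * i + (dy / 2.0 if j % 2 else 0.0)
            poly = _hex_vertices(dx * j, cy, r)
            raw[(j, i)] = poly
            for v in poly:
                key = _vkey(v)
                usage.setdefault(key, set()).add((j, i))
                exact.setdefault(key, v.copy())

    # one displacement per unique lattice vertex, in sorted-key order for
    # seed-stable output
    keys = sorted(usage)
    displaced: dict[tuple[float, float], np.ndarray] = {}
    for k in keys:
        pos = exact[k]
        if spec.shape_noise_sd > 0:
            pos = pos + rng.normal(0.0, spec.shape_noise_sd, size=2)
        displaced[k] = pos

    boundary_keys: list[tuple[float, float]] = []
    if spec.boundary_column is not None:
        jb = spec.boundary_column
        xb = dx * jb + 0.75 * r  # mean line of the zig-zag
        s = spec.boundary_straightening
        for k in keys:
            cols = {j for (j, _) in usage[k]}
            if jb in cols and (jb + 1) in cols:
                boundary_keys.append(k)
                p = displaced[k]
                displaced[k] = np.array([p[0] + s * (xb - p[0]), p[1]])

    cells: list[CellSnapshot] = []
    bc_cols = (
        {spec.boundary_column, spec.boundary_column + 1}
        if spec.boundary_column is not None
        else set()
    )
    for (j, i), poly in raw.items():
        verts = np.array([displaced[_vkey(v)] for v in poly])
        tric = np.array(
            [idx for idx, v in enumerate(poly) if len(usage[_vkey(v)]) == 3],
            dtype=int,
        )
        cells.append(
            CellSnapshot(
                cell_id=f"c{j}_{i}",
                frame=0,
                time_min=0.0,
                polygon=verts,
                tricellular=tric,
                is_boundary_cell=j in bc_cols,
            )
        )

    polyline = None
    if boundary_keys:
        pts = np.array([displaced[k] for k in boundary_keys])
        polyline = pts[np.argsort(pts[:, 1])]
    return Epithelium(cells=cells, boundary_polyline=polyline, spec=spec)


# --------------------------------------------------------------------------
# division tracks
# --------------------------------------------------------------------------

def fold_axis_angle(angle_deg: float) -> float:
    """Fold an axis angle to the acute angle vs the AP axis, [0, 90]."""
    a = angle_deg % 180.0
    return min(a, 180.0 - a)


def _mother_polygon(
    center: np.ndarray,
    area: float,
    axis_ratio: float,
    axis_deg: float,
    neck: float,
    n_pts: int = 48,
) -> np.ndarray:
    """Ellipse-like outline, optionally pinched at the waist (dumbbell).

    ``neck`` = 1 gives a plain ellipse; smaller values scale the width at
    the center of the long axis down to ``neck`` times the full width.
    The outline is rescaled so its enclosed area equals ``area`` exactly,
    pinched or not.
    """
    a = np.sqrt(area * axis_ratio / np.pi)
    b = np.sqrt(area / (np.pi * axis_ratio))
    psi = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    x = a * np.cos(psi)
    y = b * np.sin(psi)
    if neck < 1.0:
        pinch = neck + (1.0 - neck) * np.minimum(1.0, (np.abs(x) / (0.6 * a)) ** 2)
        y = y * pinch
    pts = np.column_stack([x, y])
    from .geometry import signed_area as _sa

    pts = pts * np.sqrt(area / abs(_sa(pts)))
    th = np.radians(axis_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T + center


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(64):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


def gen_division_tracks(
    epithelium: Epithelium,
    mixture: DivisionMixtureSpec,
    timing: TrackTimingConfig = TrackTimingConfig(),
) -> DivisionTracks:
    """Per-frame polygons for dividing mother cells plus latent truth.

    Each true event carries the full division signature: area growth over
    the 10 min before abscission, elongation and perimeter²/area increase
    over the last 3 min, a dumbbell (necked) outline in the last minute,
    and a split into daughters of near-half area whose centroid axis lies
    exactly along the latent division angle. Distractor tracks replicate
    the signature minus one criterion each.
    """
    dt_min = timing.frame_interval_s / 60.0
    rng = np.random.default_rng(mixture.seed)
    cells = list(epithelium.cells)
    n_tracks = timing.n_events + timing.n_distractors
    if n_tracks > len(cells):
        raise ValueError(
            f"{n_tracks} tracks requested but epithelium has {len(cells)} cells"
        )
    order = rng.permutation(len(cells))[:n_tracks]
    chosen = [cells[k] for k in order]

    times = np.arange(-timing.history_min, timing.post_min + 1e-9, dt_min)
    frames = np.arange(len(times))
    absc_idx = int(np.argmin(np.abs(times)))  # frame at t = 0

    rows: list[tuple] = []
    truth: list[dict] = []

    # synthetic mothers carry six pseudo-tricellular vertices at roughly
    # hexagonal outline positions so the vertex tensor is computable
    _tric48 = frozenset(range(0, 48, 8))

    def emit(frame: int, t_min: float, cid: str, parent: Optional[str],
             poly: np.ndarray, is_bc: bool, myosin: float,
             tric: frozenset = _tric48) -> None:
        for vi, (x, y) in enumerate(poly):
            rows.append(
                (frame, t_min * 60.0, cid, parent, vi, x, y, vi in tric,
                 is_bc, myosin)
            )

    for k, cell in enumerate(chosen):
        kind = "event" if k < timing.n_events else timing.distractor_kinds[
            (k - timing.n_events) % len(timing.distractor_kinds)
        ]
        is_bc = cell.is_boundary_cell
        center = cell.centroid
        area0 = cell.area

        phi = float(rng.uniform(0.0, 180.0))  # interphase long-axis orientation
        elong = _truncnorm(rng, *mixture.elongation_distribution, lo=0.02)
        ratio0 = 10.0 ** elong
        if is_bc and rng.uniform() < mixture.p_boundary_bias:
            component = "boundary"
            alpha_raw = rng.normal(0.0, mixture.boundary_angle_sd_deg)
        else:
            component = "shape"
            alpha_raw = phi + rng.normal(0.0, mixture.shape_angle_sd_deg)
        alpha_true = fold_axis_angle(alpha_raw)

        growth = -0.15 if kind == "no_growth" else 0.35
        split_frac = 0.2 if kind == "uneven_split" else float(rng.uniform(0.45, 0.55))
        has_neck = kind not in ("no_neck", "no_rounding")
        has_round = kind != "no_rounding"

        mother_id = cell.cell_id
        area_last = area0
        for f, t in zip(frames, times):
            if t < -1e-9:  # mother frames
                area = area0 * (1.0 + growth * (t + 10.0) / 10.0) if t > -10.0 else area0
                if has_round and t > -3.0:
                    ratio = ratio0 * (1.0 + 0.6 * (t + 3.0) / 3.0)
                    axis = alpha_raw % 180.0
                elif (not has_round) and t > -3.0:
                    ratio = max(1.02, ratio0 * (1.0 - 0.3 * (t + 3.0) / 3.0))
                    axis = phi
                else:
                    ratio, axis = ratio0, phi
                if has_neck and t > -1.0:
                    neck = 0.35 if t >= -0.75 else 1.0 - 0.65 * (t + 1.0) / 0.25
                else:
                    neck = 1.0
                myosin = 2.5 if neck < 1.0 else 1.0
                poly = _mother_polygon(center, area, ratio, axis, neck)
                emit(int(f), float(t), mother_id, None, poly, is_bc, myosin)
                area_last = area
            else:  # daughters from abscission on
                if f == absc_idx:
                    a_m = area0 * (1.0 + growth) if growth > 0 else area_last
                th = np.radians(alpha_raw)
                u = np.array([np.cos(th), np.sin(th)])
                sep = 0.8 * np.sqrt(a_m * ratio0 / np.pi)
                for d, (sign, fr) in enumerate(
                    [(+1.0, split_frac), (-1.0, 1.0 - split_frac)]
                ):
                    poly = _mother_polygon(
                        center + sign * sep * 0.5 * u,
                        a_m * fr,
                        1.3,
                        alpha_raw % 180.0,
                        1.0,
                    )
                    emit(int(f), float(t), f"{mother_id}_d{d}", mother_id,
                         poly, is_bc, 1.0)

        truth.append(
            dict(
                cell_id=mother_id,
                is_true_event=kind == "event",
                kind=kind,
                component=component,
                alpha_true_deg=alpha_true,
                phi_shape_deg=fold_axis_angle(phi),
                elongation=elong,
                is_boundary_cell=bool(is_bc),
                t_abscission_min=0.0,
            )
        )

    if timing.include_static_cells:
        rest = [c for idx, c in enumerate(cells) if idx not in set(order)]
        for cell in rest:
            tric = frozenset(cell.tricellular.tolist())
            for f, t in zip(frames, times):
                emit(int(f), float(t), cell.cell_id, None, cell.polygon,
                     cell.is_boundary_cell, 1.0, tric)

    table = pd.DataFrame(
        rows,
        columns=[
            "frame", "time_s", "cell_id", "parent_id", "vertex_index",
            "x_um", "y_um", "is_tricellular", "is_boundary_cell", "myosin_proxy",
        ],
    )
    return DivisionTracks(
        table=table, truth=truth, boundary_polyline=epithelium.boundary_polyline
    )


# --------------------------------------------------------------------------
# centrosome walks and kymographs
# --------------------------------------------------------------------------

def gen_centrosome_walk(
    spec: WalkSpec,
    seed: int | np.random.Generator = 0,
    centrosome_id: str = "cen0",
    cell_id: str = "cell0",
    start: Optional[Sequence[float]] = None,
) -> CentrosomeTrack:
    """Tethered random walk sampled step by step.

    Each step adds drift plus isotropic Gaussian noise, then relaxes
    toward the tether point by ``tether_strength`` (1 = pinned)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drift = np.zeros(3)
    drift[: len(spec.drift)] = spec.drift
    tether = None
    if spec.tether_point is not None:
        tether = np.zeros(3)
        tether[: len(spec.tether_point)] = spec.tether_point
    if start is not None:
        pos = np.zeros(3)
        pos[: len(start)] = start
    else:
        pos = tether.copy() if tether is not None else np.zeros(3)

    positions = [pos.copy()]
    for _ in range(spec.n_steps - 1):
        step = drift + (
            rng.normal(0.0, spec.step_sd, size=3) if spec.step_sd > 0 else 0.0
        )
        nxt = positions[-1] + step
        if tether is not None and spec.tether_strength > 0:
            nxt = nxt + spec.tether_strength * (tether - nxt)
        positions.append(np.asarray(nxt))
    times = np.arange(spec.n_steps) * spec.dt
    return CentrosomeTrack(
        centrosome_id=centrosome_id,
        cell_id=cell_id,
        times_s=times,
        positions=np.vstack(positions),
    )


def gen_kymograph(spec: RecoilSpec) -> Kymograph:
    """Cut-end separation vs time with a known initial recoil speed."""
    t = np.arange(spec.n_frames) * spec.dt
    d = spec.d0 + spec.v0 * spec.tau * (1.0 - np.exp(-t / spec.tau))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        d = d + rng.normal(0.0, spec.noise_sd, size=len(t))
    return Kymograph(
        times_s=t, separation_um=d, frame_interval_s=spec.dt, cut_index=0
    )


# --------------------------------------------------------------------------
# track-table I/O helpers
# --------------------------------------------------------------------------

def tracks_to_frame(cells: Sequence[CellSnapshot]) -> pd.DataFrame:
    """Flatten snapshots into the tidy long track-table format."""
    rows = []
    for c in cells:
        tric = set(c.tricellular.tolist())
        for vi, (x, y) in enumerate(c.polygon):
            rows.append(
                (c.frame, c.time_min * 60.0, c.cell_id, c.parent_id, vi,
                 x, y, vi in tric, c.is_boundary_cell, c.myosin_proxy)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "time_s", "cell_id", "parent_id", "vertex_index",
            "x_um", "y_um", "is_tricellular", "is_boundary_cell", "myosin_proxy",
        ],
    )


def frame_to_snapshots(table: pd.DataFrame) -> list[CellSnapshot]:
    """Rebuild per-frame CellSnapshots from the tidy track table."""
    out: list[CellSnapshot] = []
    for (frame, cid), grp in table.groupby(["frame", "cell_id"], sort=True):
        grp = grp.sort_values("vertex_index")
        parent = grp["parent_id"].iloc[0]
        if pd.isna(parent):
            parent = None
        myo = grp["myosin_proxy"].iloc[0]
        out.append(
            CellSnapshot(
                cell_id=str(cid),
                frame=int(frame),
                time_min=float(grp["time_s"].iloc[0]) / 60.0,
                polygon=grp[["x_um", "y_um"]].to_numpy(),
                tricellular=np.flatnonzero(grp["is_tricellular"].to_numpy()),
                is_boundary_cell=bool(grp["is_boundary_cell"].iloc[0]),
                parent_id=None if parent is None else str(parent),
                myosin_proxy=None if pd.isna(myo) else float(myo),
            )
        )
    return out


def save_truth(truth: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def spec_to_dict(spec) -> dict:
    return dataclasses.asdict(spec)
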