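"""End-to-end orchestration over the synthetic inputs.

Generates (or loads) the tracked-cell table, runs division detection,
polarity tensors, angle statistics, centrosome kinematics and recoil
analysis, and writes per-stage CSV/JSON outputs plus a summary. All
randomness flows from one root seed split per stage; rerunning with the
same config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ablation, angles, centrosomes, detection, polarity, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fig4a_demo"]

_STAGE_ORDER = ("generate", "detect", "angles", "centrosomes", "recoil")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    epithelium: synthetic.EpitheliumSpec = field(
        default_factory=lambda: synthetic.EpitheliumSpec(
            n_columns=8, n_rows=8, boundary_column=3, boundary_straightening=1.0
        )
    )
    mixture: synthetic.DivisionMixtureSpec = field(
        default_factory=synthetic.DivisionMixtureSpec
    )
    timing: synthetic.TrackTimingConfig = field(
        default_factory=lambda: synthetic.TrackTimingConfig(n_events=30)
    )
    detection: detection.DetectionConfig = field(
        default_factory=detection.DetectionConfig
    )
    walk: synthetic.WalkSpec = field(default_factory=synthetic.WalkSpec)
    tether_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    n_walks_per_level: int = 50
    recoil: synthetic.RecoilSpec = field(
        default_factory=lambda: synthetic.RecoilSpec(noise_sd=0.05)
    )
    n_kymographs: int = 50
    second_cut_v0_factor: float = 0.5
    histogram_bin_deg: float = 15.0
    stages: tuple[str, ...] = _STAGE_ORDER

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        return cls(
            seed=d["seed"],
            epithelium=synthetic.EpitheliumSpec(**d["epithelium"]),
            mixture=_mk(synthetic.DivisionMixtureSpec, d["mixture"],
                        tuples=("elongation_distribution",)),
            timing=_mk(synthetic.TrackTimingConfig, d["timing"],
                       tuples=("distractor_kinds",)),
            detection=_mk(detection.DetectionConfig, d["detection"],
                          tuples=("halving_band",)),
            walk=_mk(synthetic.WalkSpec, d["walk"],
                     tuples=("drift", "tether_point")),
            tether_levels=tuple(d["tether_levels"]),
            n_walks_per_level=d["n_walks_per_level"],
            recoil=synthetic.RecoilSpec(**d["recoil"]),
            n_kymographs=d["n_kymographs"],
            second_cut_v0_factor=d["second_cut_v0_factor"],
            histogram_bin_deg=d["histogram_bin_deg"],
            stages=tuple(d["stages"]),
        )


def _mk(cls, d: dict, tuples: tuple[str, ...] = ()):
    d = dict(d)
    for k in tuples:
        if d.get(k) is not None:
            d[k] = tuple(d[k])
    return cls(**d)


def _stage_seeds(root: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    children = ss.spawn(len(_STAGE_ORDER))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_ORDER, children)
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages and write their tables under ``outdir``.

    Downstream stages read in-memory results when their producer ran in
    this invocation, else fall back to cached CSV outputs in ``outdir``;
    if neither exists they raise :class:`PipelineError`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    enabled = set(config.stages)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds,
                     "stages_run": sorted(enabled)}
    (out / "config.yaml").write_text(config.to_yaml())

    tracks: Optional[synthetic.DivisionTracks] = None
    events_df: Optional[pd.DataFrame] = None

    if "generate" in enabled:
        epi_spec = dataclasses.replace(config.epithelium, seed=seeds["generate"])
        mix = dataclasses.replace(config.mixture, seed=seeds["generate"])
        epithelium = synthetic.gen_epithelium(epi_spec)
        tracks = synthetic.gen_division_tracks(epithelium, mix, config.timing)
        tracks.table.to_csv(out / "tracks.csv", index=False)
        synthetic.save_truth(tracks.truth, out / "truth.json")
        if tracks.boundary_polyline is not None:
            pd.DataFrame(tracks.boundary_polyline, columns=["x_um", "y_um"]).to_csv(
                out / "boundary.csv", index=False
            )
        summary["generate"] = {
            "n_cells": len(epithelium.cells),
            "n_tracks": int(tracks.table["cell_id"].nunique()),
            "n_true_events": sum(t["is_true_event"] for t in tracks.truth),
        }

    if "detect" in enabled:
        if tracks is None:
            table = _load_csv(out / "tracks.csv", "generate")
            snapshots = synthetic.frame_to_snapshots(table)
        else:
            snapshots = synthetic.frame_to_snapshots(tracks.table)
        # synthetic mother outlines carry the generator's BC flag; geometric
        # classification via classify_cells is for tissue-topology tracks
        result = detection.detect_divisions(snapshots, config.detection)
        events_df = _events_frame(result.events)
        events_df.to_csv(out / "events.csv", index=False)
        result.audit.to_csv(out / "rejects.csv", index=False)
        summary["detect"] = {
            "n_candidates": len(result.audit),
            "n_accepted": len(result.events),
        }

    if "angles" in enabled:
        if events_df is None:
            events_df = _load_csv(out / "events.csv", "detect")
        summary["angles"] = _angle_stage(events_df, config, out)

    if "centrosomes" in enabled:
        summary["centrosomes"] = _centrosome_stage(config, seeds["centrosomes"], out)

    if "recoil" in enabled:
        summary["recoil"] = _recoil_stage(config, seeds["recoil"], out)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _load_csv(path: Path, producer: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(
            f"stage '{producer}' is disabled and no cached output {path.name} exists"
        )
    return pd.read_csv(path)


def _events_frame(events: list[angles.DivisionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                mother_id=e.mother_id,
                t_abscission_min=e.t_abscission_min,
                alpha_division_deg=e.alpha_division,
                alpha_shape_deg=e.alpha_shape,
                alpha_vertex_deg=e.alpha_vertex,
                elongation=e.elongation,
                cell_class=e.cell_class,
            )
            for e in events
        ]
    )


def _angle_stage(events: pd.DataFrame, config: PipelineConfig, out: Path) -> dict:
    if events.empty:
        raise PipelineError("angle statistics need at least one detected event")
    stats: dict = {}
    hist_rows = []
    for klass, grp in events.groupby("cell_class"):
        counts, edges = angles.angle_histogram(
            grp["alpha_division_deg"], config.histogram_bin_deg
        )
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append(dict(cell_class=klass, bin_lo_deg=lo,
                                  bin_hi_deg=hi, count=int(c)))
        stats[f"n_{klass}"] = int(len(grp))
    pd.DataFrame(hist_rows).to_csv(out / "angle_histograms.csv", index=False)

    bc = events.query("cell_class == 'BC'")["alpha_division_deg"]
    nbc = events.query("cell_class == 'NBC'")["alpha_division_deg"]
    if len(bc) > 0 and len(nbc) > 0:
        r = angles.compare_angle_distributions(bc, nbc, test="mann_whitney")
        stats["bc_vs_nbc"] = dataclasses.asdict(r)

    for klass, grp in events.dropna(subset=["alpha_shape_deg"]).groupby("cell_class"):
        if len(grp) >= 3:
            rho, p = angles.rank_correlation(
                grp["alpha_shape_deg"], grp["alpha_division_deg"]
            )
            stats[f"spearman_{klass}"] = {"rho": rho, "p": p, "n": int(len(grp))}

    evs = [
        angles.DivisionEvent(
            mother_id=str(r.mother_id), daughter_ids=("", ""),
            t_abscission_min=r.t_abscission_min,
            alpha_division=r.alpha_division_deg,
            alpha_shape=r.alpha_shape_deg, elongation=r.elongation,
            cell_class=r.cell_class,
        )
        for r in events.dropna(subset=["elongation"]).itertuples()
    ]
    moderate, elongated = angles.stratify_by_elongation(evs)
    for name, grp_evs in (("moderate", moderate), ("elongated", elongated)):
        diffs = [
            angles.angular_difference(e.alpha_shape, e.alpha_division)
            for e in grp_evs
            if e.alpha_shape is not None
        ]
        stats[f"shape_division_diff_{name}"] = {
            "n": len(diffs),
            "median_deg": float(np.median(diffs)) if diffs else None,
        }

    both = events.dropna(subset=["alpha_shape_deg", "alpha_vertex_deg"])
    if len(both) >= 3:
        dshape = [
            angles.angular_difference(a, b)
            for a, b in zip(both["alpha_shape_deg"], both["alpha_division_deg"])
        ]
        dvtx = [
            angles.angular_difference(a, b)
            for a, b in zip(both["alpha_vertex_deg"], both["alpha_division_deg"])
        ]
        r = angles.compare_angle_distributions(dshape, dvtx, test="ks")
        stats["shape_vs_vertex_predictor"] = dataclasses.asdict(r)

    (out / "angle_stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    return stats


def _centrosome_stage(config: PipelineConfig, seed: int, out: Path) -> dict:
    rows = []
    rng_root = np.random.SeedSequence(seed)
    for level, child in zip(
        config.tether_levels, rng_root.spawn(len(config.tether_levels))
    ):
        spec = dataclasses.replace(
            config.walk, tether_point=(0.0, 0.0, 0.0), tether_strength=level
        )
        rng = np.random.default_rng(child)
        for i in range(config.n_walks_per_level):
            track = synthetic.gen_centrosome_walk(
                spec, seed=rng, centrosome_id=f"t{level}_w{i}"
            )
            m = centrosomes.track_metrics(track)
            rows.append(
                dict(
                    tether_strength=level,
                    centrosome_id=track.centrosome_id,
                    mean_speed_um_min=m.mean_speed_um_min,
                    total_distance_um=m.total_distance_um,
                    displacement_um=m.displacement_um,
                    dv_displacement_um=m.dv_displacement_um,
                    persistence=m.persistence,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "centrosomes.csv", index=False)
    grouped = df.groupby("tether_strength")[["displacement_um", "persistence"]].mean()
    return {
        "mean_displacement_um": {str(k): float(v) for k, v in
                                 grouped["displacement_um"].items()},
        "mean_persistence": {str(k): float(v) for k, v in
                             grouped["persistence"].items()},
    }


def _recoil_stage(config: PipelineConfig, seed: int, out: Path) -> dict:
    base = config.recoil
    noise_free = dataclasses.replace(base, noise_sd=0.0)
    v_ref = ablation.recoil_velocity(synthetic.gen_kymograph(noise_free))
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(config.n_kymographs)
    rows = []
    for i, child in enumerate(kids):
        s = int(child.generate_state(1)[0] % (2**31))
        spec1 = dataclasses.replace(base, seed=s)
        spec2 = dataclasses.replace(
            base, v0=base.v0 * config.second_cut_v0_factor, seed=s + 1
        )
        pair = ablation.compare_consecutive_cuts(
            synthetic.gen_kymograph(spec1), synthetic.gen_kymograph(spec2)
        )
        rows.append(
            dict(kymo=i, v_first_um_s=pair.v_first_um_s,
                 v_second_um_s=pair.v_second_um_s, ratio=pair.ratio)
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "recoil.csv", index=False)
    summary = {
        "noise_free_velocity_um_s": v_ref,
        "mean_velocity_um_s": float(df["v_first_um_s"].mean()),
        "sd_velocity_um_s": float(df["v_first_um_s"].std(ddof=1)),
        "mean_cut_ratio": float(df["ratio"].mean()),
        "n": int(len(df)),
    }
    (out / "recoil_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def fig4a_demo() -> str:
    """CSV table of both polarity tensors for the worked hexagon example
    at straightening 0 and 1."""
    buf = io.StringIO()
    buf.write("straightening,kind,eta,theta_deg\n")
    for s in (0.0, 1.0):
        cells = polarity.build_fig4a_configuration(s)
        cell = polarity.boundary_example_cell(cells)
        for kind, tensor in (
            ("vertex", polarity.vertex_tensor(cell)),
            ("shape", polarity.shape_tensor(cell)),
        ):
            theta = "" if tensor.theta is None else f"{tensor.theta:.3f}"
            buf.write(f"{s},{kind},{tensor.eta:.6f},{theta}\n")
    return buf.getvalue()
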