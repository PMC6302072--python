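#!/usr/bin/env python
"""Angle statistics on the synthetic division mixture.

Two worlds with identical geometry but different orientation rules:

* shape-following (p_boundary_bias = 0): every division tracks the
  cell's interphase long axis with 15 degrees of noise;
* boundary-biased (p_boundary_bias = 0.7): boundary cells mostly divide
  perpendicular to the boundary regardless of their shape.

The Spearman correlation between the shape axis and the division axis
separates the two regimes; the BC vs NBC angle histograms and the
elongation stratification (cutoff 0.3 = axis ratio 2) are reported for
the boundary-biased world.

Writes results/angle_statistics.json.
"""

import json
from pathlib import Path

import numpy as np

from psbdiv.angles import (
    angle_histogram,
    compare_angle_distributions,
    rank_correlation,
)
from psbdiv.synthetic import (
    DivisionMixtureSpec,
    EpitheliumSpec,
    TrackTimingConfig,
    gen_division_tracks,
    gen_epithelium,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def world(p_boundary: float, seed: int = 8):
    epi = gen_epithelium(EpitheliumSpec(
        n_columns=20, n_rows=16, boundary_column=9,
        boundary_straightening=1.0, seed=seed))
    mix = DivisionMixtureSpec(p_boundary_bias=p_boundary,
                              shape_angle_sd_deg=15.0, seed=seed)
    return gen_division_tracks(epi, mix, TrackTimingConfig(n_events=300)).truth


def main() -> None:
    report = {}
    for label, p in (("shape_following", 0.0), ("boundary_biased", 0.7)):
        truth = world(p)
        bc = [t for t in truth if t["is_boundary_cell"]]
        rho, pval = rank_correlation([t["phi_shape_deg"] for t in bc],
                                     [t["alpha_true_deg"] for t in bc])
        report[label] = {"n_bc": len(bc), "spearman_rho": rho, "p": pval}

    truth = world(0.7)
    bc = [t["alpha_true_deg"] for t in truth if t["is_boundary_cell"]]
    nbc = [t["alpha_true_deg"] for t in truth if not t["is_boundary_cell"]]
    mw = compare_angle_distributions(bc, nbc)
    report["bc_vs_nbc"] = {
        "U": mw.statistic, "p": mw.p_value, "n_bc": mw.n1, "n_nbc": mw.n2,
        "bc_hist_15deg": angle_histogram(bc)[0].tolist(),
        "nbc_hist_15deg": angle_histogram(nbc)[0].tolist(),
        "bc_median_deg": float(np.median(bc)),
        "nbc_median_deg": float(np.median(nbc)),
    }

    moderate = [t["alpha_true_deg"] for t in truth if t["elongation"] <= 0.3]
    elongated = [t["alpha_true_deg"] for t in truth if t["elongation"] > 0.3]
    report["elongation_stratification"] = {
        "n_moderate": len(moderate), "n_elongated": len(elongated),
        "cutoff": 0.3,
    }

    (OUT / "angle_statistics.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))
    print("\nShape-following boundary cells correlate with their long axis; "
          "boundary-biased ones decouple from it and skew toward 0 deg "
          "(boundary-perpendicular), unlike non-boundary cells.")


if __name__ == "__main__":
    main()
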