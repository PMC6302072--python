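#!/usr/bin/env python
"""Recoil-velocity estimator recovery and consecutive-cut comparison.

Simulates post-ablation kymographs d(t) = d0 + v0*tau*(1 - exp(-t/tau))
with measurement noise and checks that the 5-point OLS initial slope
(the standard recoil-velocity proxy) recovers the noise-free value, then
simulates consecutive cut pairs in which the second cut recoils at half
the speed — the signature of a cable whose tension the first cut
already released.

Writes results/recoil_recovery.json.
"""

import json
from pathlib import Path

import numpy as np

from psbdiv.ablation import compare_consecutive_cuts, recoil_velocity
from psbdiv.synthetic import RecoilSpec, gen_kymograph

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    base = dict(v0=0.5, tau=10.0, dt=1.0)
    ref = recoil_velocity(gen_kymograph(RecoilSpec(noise_sd=0.0, **base)))
    vs = [recoil_velocity(gen_kymograph(RecoilSpec(noise_sd=0.05, seed=s, **base)))
          for s in range(200)]

    ratios = []
    for s in range(50):
        k1 = gen_kymograph(RecoilSpec(noise_sd=0.05, seed=2 * s, **base))
        k2 = gen_kymograph(RecoilSpec(v0=0.25, tau=10.0, dt=1.0,
                                      noise_sd=0.05, seed=2 * s + 1))
        ratios.append(compare_consecutive_cuts(k1, k2).ratio)

    report = {
        "true_v0_um_s": 0.5,
        "noise_free_5pt_ols_um_s": ref,
        "mean_estimate_um_s": float(np.mean(vs)),
        "sd_estimate_um_s": float(np.std(vs, ddof=1)),
        "relative_bias_vs_noise_free": float(np.mean(vs) / ref - 1.0),
        "n_kymographs": len(vs),
        "consecutive_cuts": {
            "constructed_ratio": 0.5,
            "mean_measured_ratio": float(np.mean(ratios)),
            "n_pairs": len(ratios),
        },
    }
    (OUT / "recoil_recovery.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))
    print("\nNote the 5-point OLS slope of an exponential relaxation "
          "understates v0 itself (curvature within the fit window); the "
          "estimator is consistent for its noise-free value, which is what "
          "between-condition comparisons use.")


if __name__ == "__main__":
    main()
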