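#!/usr/bin/env python
"""Worked example: what a straight boundary does to a hexagonal cell.

Builds the noise-free hexagonal packing, imposes the straight column
boundary at increasing strengths, and tracks both polarity tensors of
the worked-example boundary cell. At full straightening the tricellular
vertices cluster perpendicular to the boundary (eta_vertex ~ 0.21) while
the outline elongates parallel to it (eta_shape ~ 0.14): a straight
multicellular interface alone can bias a vertex-sensing division
mechanism toward the boundary-perpendicular direction.

Writes results/fig4a_tensors.csv and results/straightening_scan.csv.
"""

import io
from pathlib import Path

import numpy as np
import pandas as pd

from psbdiv.pipeline import fig4a_demo
from psbdiv.polarity import (
    boundary_example_cell,
    build_fig4a_configuration,
    shape_tensor,
    vertex_tensor,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    demo = pd.read_csv(io.StringIO(fig4a_demo()))
    demo.to_csv(OUT / "fig4a_tensors.csv", index=False)
    print("Worked example (straightening 0 vs 1):")
    print(demo.to_string(index=False))

    rows = []
    for s in np.linspace(0.0, 1.0, 11):
        cell = boundary_example_cell(build_fig4a_configuration(float(s)))
        vt, st = vertex_tensor(cell), shape_tensor(cell)
        rows.append(dict(straightening=round(float(s), 2),
                         eta_vertex=vt.eta, eta_shape=st.eta,
                         theta_vertex_deg=vt.theta, theta_shape_deg=st.theta))
    scan = pd.DataFrame(rows)
    scan.to_csv(OUT / "straightening_scan.csv", index=False)
    print("\nBoth magnitudes grow monotonically with straightening;")
    print(f"endpoints: eta_vertex {scan.eta_vertex.iloc[-1]:.4f}, "
          f"eta_shape {scan.eta_shape.iloc[-1]:.4f}")


if __name__ == "__main__":
    main()
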