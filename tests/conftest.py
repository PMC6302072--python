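import numpy as np
import pytest

from psbdiv.polarity import CellSnapshot


def regular_polygon(k: int, r: float = 1.0, phase_deg: float = 0.0) -> np.ndarray:
    ang = np.radians(phase_deg) + 2.0 * np.pi * np.arange(k) / k
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def ellipse_polygon(a: float, b: float, n: int = 360, angle_deg: float = 0.0,
                    center=(0.0, 0.0)) -> np.ndarray:
    psi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(psi), b * np.sin(psi)])
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T + np.asarray(center)


def snapshot(polygon: np.ndarray, tricellular=None, **kw) -> CellSnapshot:
    if tricellular is None:
        tricellular = np.arange(len(polygon))
    defaults = dict(cell_id="cell", frame=0, time_min=0.0)
    defaults.update(kw)
    return CellSnapshot(polygon=polygon, tricellular=tricellular, **defaults)


@pytest.fixture
def hexagon_cell() -> CellSnapshot:
    return snapshot(regular_polygon(6))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
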