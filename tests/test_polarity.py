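"""Shape/vertex polarity tensors and the moment-equivalent ellipse."""

import numpy as np
import pytest

from psbdiv.geometry import second_moment_area
from psbdiv.polarity import (
    CellSnapshot,
    boundary_example_cell,
    build_fig4a_configuration,
    fit_ellipse,
    shape_tensor,
    vertex_tensor,
)

from conftest import ellipse_polygon, regular_polygon, snapshot


class TestIsotropicCell:
    def test_regular_hexagon_both_tensors_vanish(self, hexagon_cell):
        for tensor in (shape_tensor(hexagon_cell), vertex_tensor(hexagon_cell)):
            assert tensor.eta < 1e-9
            assert tensor.is_isotropic and tensor.theta is None

    @pytest.mark.parametrize("k", range(3, 9))
    def test_kfold_symmetric_vertex_sets_are_isotropic(self, k):
        """Any point set with k-fold (k >= 3) rotational symmetry has a
        uniform angular second moment."""
        cell = snapshot(regular_polygon(k, phase_deg=17.0))
        assert vertex_tensor(cell).eta < 1e-9

    def test_diametrically_opposed_clusters_saturate(self):
        """Vertices split into two diametrically opposed groups give eta = 1."""
        poly = ellipse_polygon(2.0, 1.0, n=12)
        # psi = 0 and psi = pi vertices lie exactly on the +/- x rays
        cell = snapshot(poly, tricellular=np.array([0, 6]))
        t = vertex_tensor(cell)
        assert t.eta == pytest.approx(1.0, abs=1e-12)
        assert t.theta == pytest.approx(0.0, abs=1e-9)
        # tight clusters around the two poles approach saturation
        tight = snapshot(ellipse_polygon(2.0, 1.0, n=360),
                         tricellular=np.array([0, 1, 359, 179, 180, 181]))
        assert vertex_tensor(tight).eta > 0.99


class TestStraightBoundaryConfiguration:
    """The worked hexagonal-packing example: straightening the zig-zag
    column boundary clusters vertices perpendicular to it and elongates
    the cell parallel to it."""

    def test_straightened_cell_tensor_magnitudes(self):
        cell = boundary_example_cell(build_fig4a_configuration(1.0))
        vt = vertex_tensor(cell)
        st = shape_tensor(cell)
        assert vt.eta == pytest.approx(0.21, abs=0.02)
        assert st.eta == pytest.approx(0.13, abs=0.02)
        # vertex axis perpendicular to the (vertical) boundary, shape parallel
        assert min(vt.theta, 180.0 - vt.theta) < 1.0
        assert abs(st.theta - 90.0) < 1.0

    def test_unstraightened_cells_are_isotropic(self):
        cell = boundary_example_cell(build_fig4a_configuration(0.0))
        assert vertex_tensor(cell).eta < 1e-9
        assert shape_tensor(cell).eta < 1e-9

    def test_partial_straightening_is_intermediate(self):
        etas_v, etas_s = [], []
        for s in (0.0, 0.5, 1.0):
            cell = boundary_example_cell(build_fig4a_configuration(s))
            etas_v.append(vertex_tensor(cell).eta)
            etas_s.append(shape_tensor(cell).eta)
        assert etas_v[0] < etas_v[1] < etas_v[2]
        assert etas_s[0] < etas_s[1] < etas_s[2]

    def test_straightening_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_fig4a_configuration(1.5)


def _quadrature_second_moment(poly: np.ndarray, n_grid: int = 700) -> np.ndarray:
    """Brute-force area-moment oracle: rasterize the polygon on a dense
    grid and sum outer products of centroid-to-pixel vectors."""
    from matplotlib.path import Path as MplPath

    xmin, ymin = poly.min(axis=0)
    xmax, ymax = poly.max(axis=0)
    xs = np.linspace(xmin, xmax, n_grid)
    ys = np.linspace(ymin, ymax, n_grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(poly).contains_points(pts)
    pix = pts[inside]
    c = pix.mean(axis=0)
    r = pix - c
    da = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return (r.T @ r) * da


class TestShapeTensor:
    def test_matches_quadrature_on_elongated_ellipse(self):
        """Closed-form polygon moments agree with dense pixel quadrature."""
        poly = ellipse_polygon(2.0, 1.0, n=720, angle_deg=30.0)
        exact = second_moment_area(poly)
        approx = _quadrature_second_moment(poly)
        assert np.allclose(approx, exact, rtol=5e-3, atol=1e-3)
        # axis-ratio-2 ellipse: eta = 1 - (b/a)^2 = 0.75
        assert shape_tensor(snapshot(poly)).eta == pytest.approx(0.75, abs=1e-3)

    @pytest.mark.parametrize("phi", [0.0, 23.0, 91.5, 154.0])
    def test_rotation_equivariance(self, phi):
        poly = ellipse_polygon(2.0, 1.0, n=128)
        base = shape_tensor(snapshot(poly))
        rot = shape_tensor(snapshot(ellipse_polygon(2.0, 1.0, n=128, angle_deg=phi)))
        assert rot.eta == pytest.approx(base.eta, abs=1e-9)
        assert rot.theta == pytest.approx((base.theta + phi) % 180.0, abs=1e-6)

    def test_eta_invariant_under_scaling_and_translation(self, rng):
        pts = rng.normal(size=(12, 2))
        from scipy.spatial import ConvexHull

        poly = pts[ConvexHull(pts).vertices]
        e0 = shape_tensor(snapshot(poly)).eta
        e1 = shape_tensor(snapshot(3.7 * poly + np.array([5.0, -2.0]))).eta
        assert e1 == pytest.approx(e0, rel=1e-12)
        assert 0.0 <= e0 <= 1.0

    def test_perimeter_method_converges(self):
        poly = ellipse_polygon(1.8, 1.0, n=96)
        cell = snapshot(poly)
        e1 = shape_tensor(cell, n_samples=720, method="perimeter").eta
        e2 = shape_tensor(cell, n_samples=1440, method="perimeter").eta
        assert abs(e2 - e1) < 1e-4

    def test_perimeter_method_rejects_sparse_sampling(self, hexagon_cell):
        with pytest.raises(ValueError):
            shape_tensor(hexagon_cell, n_samples=12, method="perimeter")


class TestVertexTensor:
    def test_requires_two_vertices(self):
        cell = snapshot(regular_polygon(6), tricellular=np.array([0]))
        with pytest.raises(ValueError):
            vertex_tensor(cell)

    def test_eta_depends_only_on_vertex_angles(self, rng):
        """Changing vertex distances (not angles) leaves the tensor fixed.

        Point-symmetric star polygons keep the centroid at the origin, so
        varying the radii changes only the vector lengths; the unit-vector
        tensor must not move.
        """
        half = np.sort(rng.uniform(0.0, np.pi - 0.1, size=4))
        ang = np.concatenate([half, half + np.pi])

        def star(radii: np.ndarray) -> np.ndarray:
            return np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])

        r_var = rng.uniform(0.5, 2.0, size=4)
        radii_uniform = np.ones(8)
        radii_varied = np.concatenate([r_var, r_var])  # keep point symmetry
        t1 = vertex_tensor(snapshot(star(radii_uniform)))
        t2 = vertex_tensor(snapshot(star(radii_varied)))
        assert t2.eta == pytest.approx(t1.eta, abs=1e-9)


class TestEllipseFit:
    def test_circle_has_zero_elongation(self):
        fit = fit_ellipse(snapshot(ellipse_polygon(1.0, 1.0, n=360)))
        assert fit.elongation == pytest.approx(0.0, abs=1e-6)

    def test_axis_ratio_two_hits_stratification_cutoff(self):
        fit = fit_ellipse(snapshot(ellipse_polygon(2.0, 1.0, n=720)))
        assert fit.elongation == pytest.approx(np.log10(2.0), abs=2e-3)

    def test_axes_match_closed_form_at_high_resolution(self):
        a, b = 2.3, 1.1
        fit = fit_ellipse(snapshot(ellipse_polygon(a, b, n=3600)))
        assert fit.long_axis == pytest.approx(2 * a, rel=1e-3)
        assert fit.short_axis == pytest.approx(2 * b, rel=1e-3)

    @pytest.mark.parametrize("phi", [10.0, 77.0, 135.0])
    def test_rotated_rectangle_orientation(self, phi):
        """A w x h rectangle's principal axis lies along its long side."""
        rect = np.array([[-2.0, -0.5], [2.0, -0.5], [2.0, 0.5], [-2.0, 0.5]])
        th = np.radians(phi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        fit = fit_ellipse(snapshot(rect @ rot.T))
        assert fit.orientation == pytest.approx(phi % 180.0, abs=1e-6)

    def test_degenerate_polygon_rejected(self):
        flat = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            fit_ellipse(snapshot(flat))
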