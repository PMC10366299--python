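import math

import numpy as np
import pytest

from celltransit.analysis_metrics import (ShapeContour, deformation_index,
                                          extract_contour,
                                          membrane_diagnostics,
                                          small_deformation_oracle,
                                          taylor_parameter)
from celltransit.surface_mesh import make_sphere_mesh


def ellipse_contour(a, b, n=2000):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * np.sum(x * yn - xn * y)
    perim = np.sum(np.hypot(xn - x, yn - y))
    return ShapeContour(points=pts, area=area, perimeter=perim)


class TestContour:
    def test_sphere_slice_is_a_circle(self):
        a = 8.5
        c = extract_contour(make_sphere_mesh(a, 5))
        assert c.area == pytest.approx(math.pi * a * a, rel=0.005)
        assert c.perimeter == pytest.approx(2 * math.pi * a, rel=0.005)

    def test_offset_plane_gives_smaller_circle(self):
        c = extract_contour(make_sphere_mesh(5.0, 4), plane_value=3.0)
        assert c.area == pytest.approx(math.pi * 16.0, rel=0.01)

    def test_missing_plane_raises(self):
        with pytest.raises(ValueError):
            extract_contour(make_sphere_mesh(2.0, 2), plane_value=50.0)

    def test_in_plane_translation_invariance(self):
        m1 = make_sphere_mesh(3.0, 3)
        m2 = make_sphere_mesh(3.0, 3, center=(12.0, 0.0, -7.0))
        c1, c2 = extract_contour(m1), extract_contour(m2)
        assert c2.area == pytest.approx(c1.area, rel=1e-9)
        assert c2.perimeter == pytest.approx(c1.perimeter, rel=1e-9)


class TestDeformationIndex:
    def test_circle_is_zero(self):
        assert deformation_index(ellipse_contour(2.0, 2.0)) \
            == pytest.approx(0.0, abs=1e-5)

    def test_two_to_one_ellipse(self):
        # perimeter by quadrature: P ~ 9.68845, A = 2 pi
        assert deformation_index(ellipse_contour(2.0, 1.0)) \
            == pytest.approx(0.0828, abs=2e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_on_star_shaped_contours(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r = 1.0 + 0.3 * np.sin(rng.integers(2, 6) * t + rng.random())
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        c = ShapeContour(pts, 0.5 * np.sum(x * yn - xn * y),
                         np.sum(np.hypot(xn - x, yn - y)))
        assert deformation_index(c) >= 0.0

    def test_scale_invariance(self):
        d1 = deformation_index(ellipse_contour(2.0, 1.0))
        d2 = deformation_index(ellipse_contour(20.0, 10.0))
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            deformation_index(ShapeContour(np.zeros((3, 2)), 1.0, 0.0))


class TestTaylorParameter:
    def test_sphere_is_isotropic(self):
        assert taylor_parameter(make_sphere_mesh(4.0, 4)).D \
            == pytest.approx(0.0, abs=1e-3)

    def test_two_to_one_ellipsoid(self):
        m = make_sphere_mesh(3.0, 4)
        m.vertices[:, 0] *= 2.0
        shape = taylor_parameter(m)
        assert shape.D == pytest.approx(1.0 / 3.0, rel=0.01)
        assert shape.L == pytest.approx(6.0, rel=0.01)
        assert shape.B == pytest.approx(3.0, rel=0.01)

    def test_in_plane_rotation_invariance(self):
        m = make_sphere_mesh(3.0, 4)
        m.vertices[:, 0] *= 1.8
        d0 = taylor_parameter(m).D
        th = 0.83
        R = np.array([[np.cos(th), 0.0, -np.sin(th)], [0.0, 1.0, 0.0],
                      [np.sin(th), 0.0, np.cos(th)]])
        m.vertices = m.vertices @ R.T
        assert taylor_parameter(m).D == pytest.approx(d0, rel=1e-6)


class TestSmallDeformationOracle:
    def test_zero_capillary_number(self):
        assert small_deformation_oracle(0.0, 5.0) == 0.0

    def test_classical_elastic_slope(self):
        # kappa = 3 (neo-Hookean-equivalent small-strain moduli): D = 25/12 Ca
        assert small_deformation_oracle(0.01, 0.0, C=1.0) \
            == pytest.approx(25.0 / 12.0 * 0.01, rel=1e-12)

    def test_linear_in_ca_at_leading_order(self):
        s1 = small_deformation_oracle(1e-3, 3.0) / 1e-3
        s2 = small_deformation_oracle(1e-4, 3.0) / 1e-4
        assert s2 == pytest.approx(s1, rel=1e-4)
        assert s1 > 0

    def test_strictly_decreasing_in_membrane_viscosity(self):
        for Ca in (0.02, 0.05, 0.1):
            ds = [small_deformation_oracle(Ca, eta)
                  for eta in (0.0, 2.0, 5.0, 10.0, 30.0)]
            assert np.all(np.diff(ds) < 0)

    def test_harder_membrane_deforms_less(self):
        assert small_deformation_oracle(0.05, 0.0, C=10.0) \
            < small_deformation_oracle(0.05, 0.0, C=1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            small_deformation_oracle(-0.1, 0.0)


class _Record:
    def __init__(self, x, di, area, gbar, area_ref):
        self.x, self.DI, self.area = x, di, area
        self.gamma_bar, self.area_ref = gbar, area_ref


class TestDiagnostics:
    def test_unstrained_and_inflated_areas(self):
        rec = _Record(x=[0.0, 10.0], di=[0.0, 0.1],
                      area=[100.0, 100.0 * 1.02 ** 2],
                      gbar=[1.0, 2.0], area_ref=100.0)
        out = membrane_diagnostics(rec)
        assert out["area_change_pct"] == pytest.approx(4.04, abs=0.001)
        assert out["peak_DI_x"] == 10.0
        assert out["peak_gamma_bar_x"] == 10.0

    def test_peak_location(self):
        x = np.linspace(-50, 100, 31)
        di = np.exp(-((x + 6) / 10.0) ** 2)
        rec = _Record(x=x, di=di, area=np.full_like(x, 90.0),
                      gbar=np.ones_like(x), area_ref=90.0)
        assert abs(membrane_diagnostics(rec)["peak_DI_x"] + 6.0) < 5.0
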