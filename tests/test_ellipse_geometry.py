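import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbcdetect.ellipse_geometry import (
    ConicCoefficients,
    EllipseParams,
    conic_to_ellipse,
    ellipse_sign,
    fit_conic,
    mea_rasterize,
)
from wbcdetect.errors import DegenerateCandidateError, NonEllipseError, TooSmallError

from conftest import full_midpoint_oracle


def make_ellipse_points(e: EllipseParams, degrees):
    return [e.boundary_point(math.radians(d)) for d in degrees]


class TestFitConic:
    def test_circle_radius_two(self):
        c = fit_conic([(2, 0), (-2, 0), (0, 2), (0, -2), (math.sqrt(2), math.sqrt(2))])
        assert c.a == pytest.approx(-0.25, abs=1e-12)
        assert c.b == pytest.approx(-0.25, abs=1e-12)
        assert c.h == pytest.approx(0.0, abs=1e-12)
        assert c.g == pytest.approx(0.0, abs=1e-12)
        assert c.f == pytest.approx(0.0, abs=1e-12)

    def test_residual_on_sampled_ellipse(self):
        e = EllipseParams(10.0, 20.0, 5.0, 3.0, math.radians(30))
        pts = make_ellipse_points(e, [0, 50, 120, 200, 290])
        c = fit_conic(pts)
        for x, y in pts:
            assert abs(c.evaluate(x, y)) <= 1e-9

    def test_collinear_points_degenerate(self):
        with pytest.raises(DegenerateCandidateError):
            fit_conic([(0, 0), (1, 1), (2, 2), (3, 3), (4, 5)])

    def test_duplicate_points_degenerate(self):
        with pytest.raises(DegenerateCandidateError):
            fit_conic([(0, 0), (0, 0), (2, 2), (3, 1), (4, 5)])


class TestConicToEllipse:
    def test_circle_closed_form(self):
        e = conic_to_ellipse(ConicCoefficients(a=-0.25, h=0.0, b=-0.25, g=0.0, f=0.0))
        assert e.x0 == pytest.approx(0.0, abs=1e-12)
        assert e.y0 == pytest.approx(0.0, abs=1e-12)
        assert e.rmax == pytest.approx(2.0, abs=1e-12)
        assert e.rmin == pytest.approx(2.0, abs=1e-12)
        assert e.theta == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_single(self):
        truth = EllipseParams(10.0, 20.0, 5.0, 3.0, math.radians(30))
        pts = make_ellipse_points(truth, [0, 50, 120, 200, 290])
        rec = conic_to_ellipse(fit_conic(pts))
        assert rec.x0 == pytest.approx(truth.x0, abs=1e-6)
        assert rec.y0 == pytest.approx(truth.y0, abs=1e-6)
        assert rec.rmax == pytest.approx(truth.rmax, abs=1e-6)
        assert rec.rmin == pytest.approx(truth.rmin, abs=1e-6)
        dtheta = (rec.theta - truth.theta + math.pi / 2) % math.pi - math.pi / 2
        assert abs(dtheta) <= 1e-6

    def test_hyperbola_rejected(self):
        with pytest.raises(NonEllipseError):
            conic_to_ellipse(ConicCoefficients(a=1.0, h=0.0, b=-1.0, g=0.0, f=0.0))

    def test_round_trip_many_seeded(self):
        rng = np.random.default_rng(1234)
        checked = 0
        for _ in range(100):
            x0, y0 = rng.uniform(10, 90, 2)
            rmax = rng.uniform(3, 30)
            rmin = rng.uniform(3, rmax)
            theta = rng.uniform(-math.pi / 2, math.pi / 2)
            truth = EllipseParams(x0, y0, rmax, rmin, theta)
            pts = [truth.boundary_point(t) for t in rng.uniform(0, 2 * math.pi, 5)]
            try:
                rec = conic_to_ellipse(fit_conic(pts))
            except (DegenerateCandidateError, NonEllipseError):
                continue
            checked += 1
            assert rec.x0 == pytest.approx(x0, abs=1e-6)
            assert rec.y0 == pytest.approx(y0, abs=1e-6)
            assert rec.rmax == pytest.approx(rmax, abs=1e-6)
            assert rec.rmin == pytest.approx(rmin, abs=1e-6)
            if rmax / rmin > 1 + 1e-9:
                dtheta = (rec.theta - theta + math.pi / 2) % math.pi - math.pi / 2
                assert abs(dtheta) <= 1e-6
        assert checked >= 80  # the degeneracy exclusion must stay rare


class TestMEARasterize:
    def test_matches_midpoint_oracle(self):
        e = EllipseParams(20.0, 20.0, 6.0, 4.0, 0.0)
        shape = mea_rasterize(e, (41, 41))
        assert shape.as_set() == full_midpoint_oracle(e, (41, 41))

    @pytest.mark.parametrize("rmax,rmin", [(1, 1), (3, 2), (5, 5), (8, 3), (12, 7)])
    def test_oracle_equivalence_sample(self, rmax, rmin):
        e = EllipseParams(30.0, 30.0, float(rmax), float(rmin), 0.0)
        shape = mea_rasterize(e, (61, 61))
        assert shape.as_set() == full_midpoint_oracle(e, (61, 61))

    def test_four_fold_symmetry(self):
        e = EllipseParams(30.0, 30.0, 9.0, 5.0, 0.0)
        pts = mea_rasterize(e, (61, 61)).as_set()
        for x, y in pts:
            assert (60 - x, y) in pts
            assert (x, 60 - y) in pts
            assert (60 - x, 60 - y) in pts

    def test_out_of_bounds_discarded(self):
        e = EllipseParams(0.0, 0.0, 5.0, 5.0, 0.0)
        shape = mea_rasterize(e, (10, 10))
        assert shape.count > 0
        assert np.all(shape.pixels >= 0)
        assert np.all(shape.pixels <= 9)

    def test_too_small_axes(self):
        with pytest.raises(TooSmallError):
            mea_rasterize(EllipseParams(10.0, 10.0, 5.0, 0.5, 0.0), (21, 21))

    def test_deterministic(self):
        e = EllipseParams(48.3, 44.7, 14.2, 10.6, 0.5)
        a = mea_rasterize(e, (96, 96)).pixels
        b = mea_rasterize(e, (96, 96)).pixels
        assert np.array_equal(a, b)

    def test_no_duplicates(self):
        e = EllipseParams(48.3, 44.7, 14.2, 10.6, 0.5)
        pix = mea_rasterize(e, (96, 96)).pixels
        assert len({(x, y) for x, y in pix.tolist()}) == pix.shape[0]

    @settings(max_examples=40, deadline=None)
    @given(
        rmax=st.floats(min_value=1.0, max_value=12.0),
        ratio=st.floats(min_value=0.2, max_value=1.0),
    )
    def test_subpixel_bound_property(self, rmax, ratio):
        rmin = max(1.0, rmax * ratio)
        e = EllipseParams(30.0, 30.0, rmax, max(rmin, 1.0), 0.0)
        shape = mea_rasterize(e, (61, 61))
        ts = np.linspace(0, 2 * math.pi, 2001)
        bx = e.x0 + e.rmax * np.cos(ts)
        by = e.y0 + e.rmin * np.sin(ts)
        limit = max(0.5 * math.sqrt(2), 1.0)
        for x, y in shape.pixels:
            assert np.min(np.hypot(bx - x, by - y)) <= limit

    def test_subpixel_distance_bound_axis_aligned(self):
        limit = max(0.5 * math.sqrt(2), 1.0)
        ts = np.linspace(0, 2 * math.pi, 4001)
        for rmax, rmin in [(4, 3), (7, 2), (11, 11), (12, 5)]:
            e = EllipseParams(30.0, 30.0, float(rmax), float(rmin), 0.0)
            bx = e.x0 + rmax * np.cos(ts)
            by = e.y0 + rmin * np.sin(ts)
            for x, y in mea_rasterize(e, (61, 61)).pixels:
                assert np.min(np.hypot(bx - x, by - y)) <= limit


class TestEllipseSign:
    E = EllipseParams(10.0, 20.0, 5.0, 3.0, math.radians(30))

    def test_center_is_inside(self):
        assert ellipse_sign(self.E.x0, self.E.y0, self.E) == -1

    def test_boundary_point_is_zero(self):
        x, y = self.E.boundary_point(math.radians(37))
        assert ellipse_sign(x, y, self.E) == 0

    def test_far_point_is_outside(self):
        assert ellipse_sign(self.E.x0 + 2 * self.E.rmax, self.E.y0, self.E) == 1

    def test_scan_line_monotone(self):
        # along any ray from the center the sign runs -1 ... 0 ... +1
        for ang in np.linspace(0, 2 * math.pi, 13):
            signs = [
                ellipse_sign(
                    self.E.x0 + r * math.cos(ang), self.E.y0 + r * math.sin(ang), self.E
                )
                for r in np.linspace(0, 4 * self.E.rmax, 200)
            ]
            assert signs == sorted(signs)
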