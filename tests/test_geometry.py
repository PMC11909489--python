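"""Geometric/kinematic primitives against closed forms and brute force."""

import numpy as np
import pytest

from gamekin import geometry as geo
from gamekin.data_model import DeviceProfile
from gamekin.errors import DegenerateGeometryError, InsufficientDataError

from conftest import make_trace


class TestResample:
    def test_uniform_trace_is_identity(self):
        t = np.arange(0, 1.0, 1 / 60)
        tr = make_trace(t, np.sin(t), np.cos(t))
        out = geo.resample_uniform(tr, 60)
        np.testing.assert_allclose(out.x, tr.x, atol=1e-12)
        np.testing.assert_allclose(out.t, tr.t, atol=1e-12)

    def test_linear_motion_interpolates_exactly(self):
        # irregular sampling of x(t) = 10 t over one second
        t = np.array([0.0, 0.13, 0.34, 0.57, 0.81, 1.0])
        tr = make_trace(t, 10 * t, np.zeros_like(t))
        out = geo.resample_uniform(tr, 10)
        np.testing.assert_allclose(out.x, np.arange(11, dtype=float),
                                   atol=1e-9)

    def test_sinusoid_interpolation_error_bound(self):
        f, amp, rate = 2.0, 5.0, 100.0
        t = np.sort(np.random.default_rng(0).uniform(0, 1, 400))
        t[0], t[-1] = 0.0, 1.0
        tr = make_trace(t, amp * np.sin(2 * np.pi * f * t), np.zeros_like(t))
        out = geo.resample_uniform(tr, rate)
        err = np.abs(out.x - amp * np.sin(2 * np.pi * f * out.t))
        # linear interpolation error of a sinusoid on the source spacing
        h = np.diff(t).max()
        assert err.max() < amp * (2 * np.pi * f * h) ** 2 / 2

    def test_too_few_samples_raises(self):
        tr = make_trace([0.0], [1.0], [1.0], events=["down"])
        with pytest.raises(InsufficientDataError):
            geo.resample_uniform(tr, 60)


class TestLine:
    def test_horizontal_line(self):
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (10, 0)))
        assert abs(lc.alpha) < 1e-12 and abs(abs(lc.beta) - 1) < 1e-12
        assert abs(lc.delta) < 1e-12

    def test_diagonal_normalized(self):
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (1, 1)))
        assert abs(lc.alpha ** 2 + lc.beta ** 2 - 1) < 1e-12
        assert abs(lc.alpha + lc.beta) < 1e-12     # x - y = 0 up to sign

    def test_random_pairs_endpoints_on_line(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p1, p2 = rng.uniform(-100, 100, (2, 2))
            if np.allclose(p1, p2):
                continue
            lc = geo.line_coefficients(geo.ReachEndpoints(tuple(p1), tuple(p2)))
            for p in (p1, p2):
                assert abs(lc.alpha * p[0] + lc.beta * p[1] + lc.delta) < 1e-9

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            geo.line_coefficients(geo.ReachEndpoints((3, 4), (3, 4)))

    @pytest.mark.parametrize("point,p1,p2,expected", [
        ((5, 3), (0, 0), (10, 0), 3.0),
        ((7, 0), (0, 0), (10, 0), 0.0),
        ((0, 2), (0, 0), (5, 5), np.sqrt(2.0)),
    ])
    def test_point_line_distance(self, point, p1, p2, expected):
        lc = geo.line_coefficients(geo.ReachEndpoints(p1, p2))
        assert geo.point_line_distance(point, lc) == pytest.approx(expected)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p1, p2, q = rng.uniform(-50, 50, (3, 2))
            if np.allclose(p1, p2):
                continue
            d0 = geo.point_line_distance(
                tuple(q), geo.line_coefficients(geo.ReachEndpoints(tuple(p1), tuple(p2))))
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)],
                            [np.sin(ang), np.cos(ang)]])
            shift = rng.uniform(-30, 30, 2)
            p1r, p2r, qr = (rot @ v + shift for v in (p1, p2, q))
            d1 = geo.point_line_distance(
                tuple(qr), geo.line_coefficients(geo.ReachEndpoints(tuple(p1r), tuple(p2r))))
            assert abs(d0 - d1) < 1e-9


class TestPathRmse:
    def test_on_line_zero(self, device):
        t = np.linspace(0, 1, 50)
        tr = make_trace(t, 100 * t, 100 * t)
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (100, 100)))
        assert geo.path_rmse(tr, lc, device).rmse_mm == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_equals_offset(self, device):
        c_mm = 2.5
        c_pt = c_mm / device.mm_per_point
        t = np.linspace(0, 1, 50)
        tr = make_trace(t, 100 * t, np.full(50, c_pt))
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (100, 0)))
        assert geo.path_rmse(tr, lc, device).rmse_mm == pytest.approx(c_mm)

    def test_rms_of_three_four(self, device):
        pts = np.array([3.0, 4.0]) / device.mm_per_point
        tr = make_trace([0, 1], [0, 50], pts)
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (100, 0)))
        assert geo.path_rmse(tr, lc, device).rmse_mm == pytest.approx(3.5355, abs=1e-3)

    def test_gaussian_noise_converges_to_sigma(self, device):
        n, sigma_mm = 10_000, 3.0
        rng = np.random.default_rng(3)
        y = rng.normal(0, sigma_mm / device.mm_per_point, n)
        tr = make_trace(np.linspace(0, 10, n), np.linspace(0, 500, n), y)
        lc = geo.line_coefficients(geo.ReachEndpoints((0, 0), (500, 0)))
        rmse = geo.path_rmse(tr, lc, device).rmse_mm
        assert abs(rmse - sigma_mm) < 3 * sigma_mm / np.sqrt(2 * n)


class TestPolylineDistance:
    poly = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0]])

    def test_on_vertex_zero(self):
        assert geo.polyline_distance((10, 0), self.poly) == pytest.approx(0.0)

    def test_above_horizontal_segment(self):
        assert geo.polyline_distance((5, 2), self.poly) == pytest.approx(2.0)

    def test_beyond_last_vertex_uses_endpoint(self):
        d = geo.polyline_distance((10, 15), self.poly)
        assert d == pytest.approx(5.0)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(4)
        verts = rng.uniform(0, 100, (8, 2))
        # dense brute force: 10^4 points along the polyline
        segs = np.diff(verts, axis=0)
        lens = np.hypot(segs[:, 0], segs[:, 1])
        cum = np.concatenate([[0], np.cumsum(lens)])
        s = np.linspace(0, cum[-1], 10_000)
        ix = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(segs) - 1)
        frac = (s - cum[ix]) / np.where(lens[ix] > 0, lens[ix], 1)
        dense = verts[ix] + frac[:, None] * segs[ix]
        spacing = cum[-1] / (len(s) - 1)
        for _ in range(50):
            q = rng.uniform(-20, 120, 2)
            d = geo.polyline_distance(tuple(q), verts)
            brute = np.min(np.hypot(*(dense - q).T))
            assert d <= brute + 1e-9          # exact min never above sampled min
            assert brute - d < max(0.005 * brute, spacing / 2)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            geo.polyline_distance((0, 0), np.array([[1.0, 1.0]]))


class TestPathLength:
    def test_unit_definition(self, device):
        tr = make_trace([0, 1], [0, 132], [0, 0])
        assert geo.path_length(tr, device) == pytest.approx(0.0254)

    def test_circle_circumference(self, device):
        r = 100.0
        ang = np.linspace(0, 2 * np.pi, 4000)
        tr = make_trace(np.linspace(0, 10, 4000),
                        r * np.cos(ang), r * np.sin(ang))
        expected = 2 * np.pi * r * device.meters_per_point
        assert abs(geo.path_length(tr, device) - expected) / expected < 1e-3

    def test_repeated_point_zero(self, device):
        tr = make_trace([0, 1], [5, 5], [7, 7])
        assert geo.path_length(tr, device) == 0.0

    def test_additive_under_concatenation(self, device):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 2, 101)
        x, y = rng.uniform(0, 500, (2, 101))
        whole = make_trace(t, x, y)
        first = make_trace(t[:51], x[:51], y[:51])
        second = make_trace(t[50:], x[50:], y[50:])
        total = geo.path_length(first, device) + geo.path_length(second, device)
        assert total == pytest.approx(geo.path_length(whole, device))


class TestDerivativeSignal:
    def test_straight_segment_constant_slope(self):
        x = np.linspace(0, 100, 60)
        tr = make_trace(np.linspace(0, 1, 60), x, 2 * x)
        d = geo.derivative_signal(tr)
        np.testing.assert_allclose(d.values, 2.0, atol=1e-9)

    def test_vertical_motion_clamped(self):
        tr = make_trace(np.linspace(0, 1, 30), np.full(30, 5.0),
                        np.linspace(0, 100, 30))
        d = geo.derivative_signal(tr, clamp_bound=1e3)
        np.testing.assert_allclose(d.values, 1e3)

    def test_quarter_circle_matches_closed_form(self):
        # upper-right quarter of x^2 + y^2 = r^2: dy/dx = -x/y
        r = 200.0
        ang = np.linspace(0.05, np.pi / 2 - 0.35, 300)
        x, y = r * np.sin(ang), r * np.cos(ang)
        tr = make_trace(np.linspace(0, 1, 300), x, y)
        d = geo.derivative_signal(tr)
        expected = -x[1:-1] / y[1:-1]
        np.testing.assert_allclose(d.values, expected, rtol=2e-3)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            geo.derivative_signal(make_trace([0, 1], [0, 1], [0, 1]))
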