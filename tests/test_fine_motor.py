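"""Coloring rasterization/accuracy and Morse-tapping scoring."""

import numpy as np
import pytest

from gamekin import fine_motor as fm
from gamekin.data_model import DeviceProfile, TrialRecord
from gamekin.errors import InsufficientDataError, ParameterError
from gamekin.simulator import SimConfig, simulate_coloring, simulate_tapping
from gamekin.tasks import Circle, MessageSpec, ShapeSpec, default_message_task

from conftest import make_trace


class TestRasterize:
    def test_retracing_is_idempotent(self):
        t = np.linspace(0, 1, 50)
        x, y = np.linspace(0, 100, 50), np.full(50, 20.0)
        once = fm.rasterize_strokes([make_trace(t, x, y)], 6.0)
        many = fm.rasterize_strokes(
            [make_trace(t + i, x, y) for i in range(10)], 6.0)
        assert once == many

    def test_single_point_disc_area(self):
        r, cell = 10.0, 2.0
        cells = fm.rasterize_strokes(
            [make_trace([0.0], [100.0], [100.0], events=["down"])], r, cell)
        expected = np.pi * r ** 2 / cell ** 2
        assert abs(len(cells) - expected) / expected < 0.05

    def test_empty_strokes_raise(self):
        with pytest.raises(InsufficientDataError):
            fm.rasterize_strokes([], 6.0)

    def test_zero_brush_raises(self):
        with pytest.raises(ParameterError):
            fm.rasterize_strokes(
                [make_trace([0.0], [0.0], [0.0], events=["down"])], 0.0)

    def test_stroke_order_invariance(self):
        t = np.linspace(0, 1, 30)
        a = make_trace(t, np.linspace(0, 60, 30), np.full(30, 10.0))
        b = make_trace(t, np.full(30, 30.0), np.linspace(0, 60, 30))
        assert fm.rasterize_strokes([a, b], 5.0) == \
            fm.rasterize_strokes([b, a], 5.0)


class TestColoringAccuracy:
    square = ShapeSpec("sq", "polygon",
                       vertices=((0.0, 0.0), (100.0, 0.0),
                                 (100.0, 100.0), (0.0, 100.0)))

    def test_exact_shape_raster_is_perfect(self):
        cells = fm.shape_cells(self.square)
        m = fm.coloring_accuracy(cells, self.square, 10.0)
        assert m.inside_pct == pytest.approx(100.0)
        assert m.outside_pct == pytest.approx(0.0)
        assert m.coverage_pct == pytest.approx(100.0)

    def test_constructed_thirty_in_ten_out(self):
        inside = {(i, j) for i in range(5, 11) for j in range(5, 10)}   # 30
        outside = {(-10 - k, -10) for k in range(10)}                   # 10
        m = fm.coloring_accuracy(inside | outside, self.square, 5.0)
        assert m.inside_pct == pytest.approx(75.0)
        assert m.outside_pct == pytest.approx(25.0)

    def test_all_outside(self):
        cells = {(-5 - k, -5) for k in range(20)}
        m = fm.coloring_accuracy(cells, self.square, 5.0)
        assert m.inside_pct == pytest.approx(0.0)

    def test_empty_cells_flagged(self):
        m = fm.coloring_accuracy(set(), self.square, 5.0)
        assert not m.inside_defined
        assert m.coverage_pct == 0.0

    def test_coverage_monotone_in_strokes(self):
        t = np.linspace(0, 1, 40)
        strokes = [make_trace(t, np.linspace(10, 90, 40), np.full(40, y))
                   for y in (20.0, 50.0, 80.0)]
        prev = -1.0
        for k in range(1, 4):
            cells = fm.rasterize_strokes(strokes[:k], 8.0)
            cov = fm.coloring_accuracy(cells, self.square, 1.0).coverage_pct
            assert cov >= prev
            prev = cov

    def test_simulated_outside_fraction_recovered(self):
        shape = ShapeSpec("circle", "circle", center=(300.0, 300.0),
                          radius=110.0)
        trial = simulate_coloring(shape, SimConfig(seed=3, outside_frac=0.2))
        m = fm.analyze_filling(trial)[0]
        assert m.outside_pct == pytest.approx(20.0, abs=2.0)

    def test_simulated_clean_fill_all_inside(self):
        shape = ShapeSpec("circle", "circle", center=(300.0, 300.0),
                          radius=110.0)
        trial = simulate_coloring(shape, SimConfig(seed=4, outside_frac=0.0,
                                                   coverage_frac=1.0))
        m = fm.analyze_filling(trial)[0]
        assert m.inside_pct == pytest.approx(100.0)
        assert m.coverage_pct > 75.0


class TestClassifyPress:
    spec = MessageSpec(message_text="E")

    @pytest.mark.parametrize("dur,expected", [
        (0.1, "."), (0.5, "-"), (0.3, "."),        # boundary goes to dot
    ])
    def test_duration_classification(self, dur, expected):
        assert fm.classify_press(dur, self.spec) == expected

    def test_nonpositive_duration_raises(self):
        with pytest.raises(ParameterError):
            fm.classify_press(0.0, self.spec)


class TestScoreMessage:
    def test_error_free_simulation_scores_clean(self, message_spec):
        trial = simulate_tapping(message_spec,
                                 SimConfig(seed=1, forced_tap_errors=0,
                                           n_target_exits=0))
        m = fm.score_message(trial)
        assert m.errors_total == 0
        assert m.chars_revealed == len(message_spec.message_text)
        assert m.taps_total == len(message_spec.expected_symbols())

    def test_three_injected_errors_counted(self, message_spec):
        for seed in range(5):
            trial = simulate_tapping(message_spec,
                                     SimConfig(seed=seed, forced_tap_errors=3))
            assert fm.score_message(trial).errors_total == 3

    def test_window_count_covers_trial_duration(self, message_spec):
        trial = simulate_tapping(message_spec, SimConfig(seed=2))
        m = fm.score_message(trial, window_s=10.0)
        assert len(m.per_window) == 18      # 180 s / 10 s

    def test_displacements_match_configured_exits(self, message_spec):
        for n_exits in (0, 2, 4):
            trial = simulate_tapping(message_spec,
                                     SimConfig(seed=3, n_target_exits=n_exits))
            assert fm.score_message(trial).displacements == n_exits

    def test_single_pointer_raises(self, message_spec, device):
        tr = make_trace([0, 0.1], [100, 100], [100, 100],
                        events=["down", "up"])
        trial = TrialRecord(trial_id="x", game="message", hand="both",
                            traces=[tr], task=message_spec, device=device)
        with pytest.raises(InsufficientDataError):
            fm.score_message(trial)

    @pytest.mark.parametrize("p", [0.1, 0.3])
    def test_injected_error_rate_recovered(self, p):
        """Across seeds the scored error count matches the injected count
        exactly, and the pooled rate estimate falls inside a 95% binomial
        interval around p."""
        # ~50 symbols: 17 chars of S/E morse
        spec = MessageSpec(message_text="SSESSESSESSESSESS", switch_time_s=30.0,
                           trial_duration_s=60.0)
        n_sym = len(spec.expected_symbols())
        total_err = total_sym = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, tap_error_p=p, tap_error_decay=1.0)
            trial = simulate_tapping(spec, cfg)
            m = fm.score_message(trial)
            assert m.errors_total == trial.meta["truth"]["n_errors"]
            total_err += m.errors_total
            total_sym += n_sym
        phat = total_err / total_sym
        half = 1.96 * np.sqrt(p * (1 - p) / total_sym)
        assert abs(phat - p) <= half

    def test_tap_rate_rises_and_error_rate_falls(self):
        """With error probability decaying over the trial, windowed error
        rates fall and tap rates rise (dot-presses are quicker)."""
        spec = MessageSpec(message_text="ESE" * 30, switch_time_s=60.0,
                           trial_duration_s=120.0)
        first_err, last_err, first_tap, last_tap = [], [], [], []
        for seed in range(20):
            cfg = SimConfig(seed=seed, tap_error_p=0.6, tap_error_decay=0.6)
            m = fm.score_message(simulate_tapping(spec, cfg))
            rates = [(tap, err) for _, tap, err in m.per_window if tap > 0]
            k = len(rates) // 2
            first_tap.append(np.mean([t for t, _ in rates[:k]]))
            last_tap.append(np.mean([t for t, _ in rates[k:]]))
            first_err.append(np.mean([e for _, e in rates[:k]]))
            last_err.append(np.mean([e for _, e in rates[k:]]))
        assert np.mean(last_err) < np.mean(first_err)
        assert np.mean(last_tap) > np.mean(first_tap)


class TestFixedFinger:
    circle = Circle(500.0, 500.0, 50.0)

    def test_never_leaves_circle(self, device):
        t = np.linspace(0, 10, 200)
        tr = make_trace(t, 500 + 20 * np.sin(t), 500 + 20 * np.cos(t))
        d, _ = fm.fixed_finger_displacements(tr, self.circle, device)
        assert d == 0

    def test_two_out_and_back_crossings(self, device):
        xs = [500, 560, 500, 500, 570, 500]      # out, back, out, back
        tr = make_trace(np.arange(6, dtype=float), xs, [500] * 6)
        d, _ = fm.fixed_finger_displacements(tr, self.circle, device)
        assert d == 2

    def test_stationary_finger_zero_path(self, device):
        tr = make_trace([0, 1, 2], [500] * 3, [500] * 3)
        d, plen = fm.fixed_finger_displacements(tr, self.circle, device)
        assert d == 0 and plen == 0.0
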