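"""Hilbert-phase pipeline and bimanual coordination summaries."""

import numpy as np
import pytest

from gamekin import bimanual as bm
from gamekin.data_model import DeviceProfile, TrialRecord
from gamekin.errors import (AlignmentError, InsufficientDataError,
                            UndefinedPhaseError)
from gamekin.simulator import SimConfig, simulate_bimanual
from gamekin.tasks import BimanualTaskSpec, Circle, default_bimanual_task

from conftest import make_trace


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope(self):
        t = np.arange(0, 10, 0.01)
        phase = bm.instantaneous_phase(np.sin(2 * np.pi * 1.0 * t))
        k = len(phase) // 10
        core = phase[k:-k]
        slope = np.polyfit(t[k:-k], core, 1)[0]
        assert abs(slope - 360.0) / 360.0 < 0.005

    def test_deterministic(self):
        x = np.sin(np.linspace(0, 20, 500))
        np.testing.assert_array_equal(bm.instantaneous_phase(x),
                                      bm.instantaneous_phase(x))

    def test_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            bm.instantaneous_phase(np.sin(np.arange(8)))

    def test_constant_signal_raises(self):
        with pytest.raises(UndefinedPhaseError):
            bm.instantaneous_phase(np.full(100, 2.0))


class TestAngularPosition:
    circle = Circle(0.0, 0.0, 100.0)

    def test_constant_speed_circle(self):
        t = np.linspace(0, 10, 601)
        ang = 2 * np.pi * 0.5 * t
        tr = make_trace(t, 100 * np.cos(ang), 100 * np.sin(ang))
        out = bm.angular_position(tr, self.circle)
        slope = np.polyfit(t, out, 1)[0]
        assert slope == pytest.approx(180.0, rel=1e-6)

    def test_stationary_finger_constant(self):
        x = 100 * np.cos(np.radians(30.0))
        y = 100 * np.sin(np.radians(30.0))
        tr = make_trace([0, 1, 2], [x] * 3, [y] * 3)
        out = bm.angular_position(tr, self.circle)
        np.testing.assert_allclose(out, 30.0, atol=1e-9)

    def test_direction_flips_sign(self):
        t = np.linspace(0, 4, 200)
        ang = 2 * np.pi * 0.5 * t
        cw = make_trace(t, 100 * np.cos(ang), 100 * np.sin(ang))
        ccw = make_trace(t, 100 * np.cos(-ang), 100 * np.sin(-ang))
        s1 = np.polyfit(t, bm.angular_position(cw, self.circle), 1)[0]
        s2 = np.polyfit(t, bm.angular_position(ccw, self.circle), 1)[0]
        assert s1 == pytest.approx(-s2, rel=1e-6)


class TestPhaseDifference:
    def test_identical_is_zero(self):
        p = np.linspace(0, 3600, 100)
        np.testing.assert_allclose(bm.phase_difference(p, p), 0.0)

    def test_constant_180_offset(self):
        p = np.linspace(0, 3600, 100)
        np.testing.assert_allclose(bm.phase_difference(p + 180, p), 180.0)

    def test_wrap_range(self):
        rng = np.random.default_rng(0)
        d = bm.phase_difference(rng.uniform(-1e4, 1e4, 1000),
                                rng.uniform(-1e4, 1e4, 1000))
        assert np.all(d > -180.0) and np.all(d <= 180.0)

    def test_offset_90_with_noise(self):
        rng = np.random.default_rng(1)
        means = []
        for _ in range(100):
            p = np.linspace(0, 3600, 500)
            d = bm.phase_difference(p + 90 + rng.normal(0, 5, 500), p)
            means.append(np.mean(np.abs(d)))
        assert 85 <= np.mean(means) <= 95

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            bm.phase_difference(np.zeros(5), np.zeros(6))

    def test_velocity_difference(self):
        w1, w2 = np.full(10, 1.0), np.full(10, 0.8)
        np.testing.assert_allclose(bm.velocity_difference(w1, w2), 0.2)
        with pytest.raises(AlignmentError):
            bm.velocity_difference(w1, w2[:5])


def planted_offset_trial(offset_deg, mode="in_phase_congruent",
                         omega=0.6, duration=30.0):
    """Two noiseless circling hands with an exact phase offset."""
    task = default_bimanual_task(mode)
    t = np.arange(0, duration, 1 / 60)
    th_l = np.radians(360.0 * omega * t - 90.0)
    th_r = np.radians(360.0 * omega * t - 90.0 + offset_deg)
    if task.mirrored:
        th_r = -th_r
    cl, cr = task.left_circle, task.right_circle
    traces = [
        make_trace(t, cl.cx + cl.r * np.cos(th_l), cl.cy + cl.r * np.sin(th_l),
                   pointer_id=0),
        make_trace(t, cr.cx + cr.r * np.cos(th_r), cr.cy + cr.r * np.sin(th_r),
                   pointer_id=1),
    ]
    return TrialRecord(trial_id="b", game="round", hand="both",
                       traces=traces, task=task, device=DeviceProfile())


class TestCoordinationSummary:
    @pytest.mark.parametrize("mode,expected", [
        ("in_phase_congruent", 0.0),
        ("antiphase_congruent", 180.0),
        ("in_phase_mirrored", 0.0),
        ("antiphase_mirrored", 180.0),
    ])
    def test_noiseless_modes_hit_ideal(self, mode, expected):
        trial = simulate_bimanual(default_bimanual_task(mode),
                                  SimConfig(seed=1, phase_jitter_deg=0.0,
                                            noise_sd_mm=0.0))
        s = bm.coordination_summary(trial)
        assert abs(s.phase_mean_deg - expected) < 2.0

    @pytest.mark.parametrize("offset", [0, 45, 90, 135, 180])
    def test_planted_offset_recovered(self, offset):
        s = bm.coordination_summary(planted_offset_trial(offset))
        assert abs(s.phase_mean_deg - offset) < 2.0

    def test_speed_conversion(self):
        # full revolution in exactly 2 s -> 0.5 rev/s
        s = bm.coordination_summary(planted_offset_trial(0, omega=0.5))
        assert s.omega_right.mean == pytest.approx(0.5, rel=0.01)
        assert s.omega_left.mean == pytest.approx(0.5, rel=0.01)

    def test_jitter_recovered_as_folded_normal_mean(self):
        """Phase jitter with stationary SD 15 deg folds to a mean absolute
        difference of sigma*sqrt(2/pi) ~ 11.97 deg."""
        means = []
        for seed in range(100):
            trial = simulate_bimanual(
                default_bimanual_task("in_phase_congruent"),
                SimConfig(seed=seed, phase_jitter_deg=15.0, noise_sd_mm=0.0))
            means.append(bm.coordination_summary(trial).phase_mean_deg)
        assert 8.0 <= np.mean(means) <= 20.0

    def test_antiphase_less_stable_than_in_phase(self):
        """With antiphase configured harder (larger jitter), the folded
        phase statistics order as in-phase < antiphase deviation from
        ideal."""
        dev_in, dev_anti = [], []
        for seed in range(10):
            t_in = simulate_bimanual(
                default_bimanual_task("in_phase_congruent"),
                SimConfig(seed=seed, phase_jitter_deg=10.0, noise_sd_mm=0.0))
            t_anti = simulate_bimanual(
                default_bimanual_task("antiphase_congruent"),
                SimConfig(seed=seed, phase_jitter_deg=25.0, noise_sd_mm=0.0))
            dev_in.append(bm.coordination_summary(t_in).phase_mean_deg)
            dev_anti.append(
                180.0 - bm.coordination_summary(t_anti).phase_mean_deg)
        assert np.mean(dev_in) < np.mean(dev_anti)

    def test_summary_invariants(self):
        trial = simulate_bimanual(default_bimanual_task("antiphase_mirrored"),
                                  SimConfig(seed=7, phase_jitter_deg=20.0))
        s = bm.coordination_summary(trial)
        assert 0.0 <= s.phase_mean_deg <= 180.0
        assert s.phase_ci95[0] <= s.phase_mean_deg <= s.phase_ci95[1]
        assert s.travel_m["left"] > 0 and s.travel_m["right"] > 0

    def test_single_pointer_raises(self):
        trial = planted_offset_trial(0)
        trial.traces = trial.traces[:1]
        with pytest.raises(InsufficientDataError):
            bm.coordination_summary(trial)
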