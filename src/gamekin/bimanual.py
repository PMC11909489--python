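"""Bimanual circle-tracing analysis: phase and speed synchronization.

Each hand's finger position on its circle is reduced to an angular
series; the oscillatory signal sin(angle) is passed through the Hilbert
transform, whose analytic-signal argument gives the instantaneous phase.
The wrapped phase difference between hands summarizes phase
synchronization (ideal 0 deg for in-phase modes, 180 deg for antiphase),
and the difference of instantaneous angular velocities (revolutions per
second) summarizes speed synchronization.  Mirrored modes negate one
hand's angle before comparison so ideal mirrored coordination also maps
to 0 / 180 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend, hilbert

from . import geometry as geo
from .data_model import TouchTrace, TrialRecord
from .errors import AlignmentError, InsufficientDataError, UndefinedPhaseError
from .tasks import BimanualTaskSpec, Circle


@dataclass
class PhaseSeries:
    """Uniform-grid unwrapped phase (deg) and angular velocity (rev/s)."""

    t: np.ndarray
    phase_deg: np.ndarray
    omega_rev_s: np.ndarray


@dataclass
class Stat:
    mean: float
    sd: float
    ci95: tuple[float, float]
    n: int


@dataclass
class SyncSummary:
    mode: str
    phase_mean_deg: float
    phase_sd_deg: float
    phase_ci95: tuple[float, float]
    omega_right: Stat
    omega_left: Stat
    omega_diff: Stat
    travel_m: dict[str, float]          # per hand
    cv_travel: dict[str, float] | None  # across attempts, when available


def _stat(values: np.ndarray) -> Stat:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n) if n > 0 else 0.0
    return Stat(mean, sd, (mean - half, mean + half), n)


def instantaneous_phase(signal: np.ndarray) -> np.ndarray:
    """Unwrapped instantaneous phase (degrees) via the Hilbert transform.

    The signal is linearly detrended first; for sin(w t + phi) the result
    follows w t + phi - 90 deg up to an additive constant (plus edge
    effects, which callers trim).
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 16:
        raise InsufficientDataError("instantaneous_phase needs >= 16 samples")
    x = detrend(x)
    if float(np.std(x)) < 1e-12:
        raise UndefinedPhaseError("constant signal has no phase")
    analytic = hilbert(x)
    return np.degrees(np.unwrap(np.angle(analytic)))


def angular_position(trace: TouchTrace, circle: Circle) -> np.ndarray:
    """Unwrapped angle (degrees) of each sample around the circle center.

    atan2 on screen coordinates (y down): positive angles advance
    clockwise on screen, counterclockwise in mathematical convention.
    Samples at the exact center carry the previous angle forward.
    """
    dx = trace.x - circle.cx
    dy = trace.y - circle.cy
    r = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx)
    at_center = r < 1e-9
    if np.any(at_center):
        warnings.warn("samples at circle center; carrying last angle forward")
        idx = np.where(~at_center)[0]
        if len(idx) == 0:
            raise UndefinedPhaseError("all samples at circle center")
        filled = np.interp(np.arange(len(ang)), idx, ang[idx])
        ang = np.where(at_center, filled, ang)
    return np.degrees(np.unwrap(ang))


def phase_difference(phase1: np.ndarray, phase2: np.ndarray) -> np.ndarray:
    """Wrapped phase difference phase1 - phase2 in (-180, 180]."""
    p1, p2 = np.asarray(phase1, float), np.asarray(phase2, float)
    if len(p1) != len(p2):
        raise AlignmentError(f"length mismatch: {len(p1)} vs {len(p2)}")
    d = np.mod(p1 - p2 + 180.0, 360.0) - 180.0
    # the -180 boundary (within float noise) belongs to +180
    return np.where(d <= -180.0 + 1e-9, d + 360.0, d)


def velocity_difference(omega1: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """Elementwise angular-velocity difference (rev/s)."""
    w1, w2 = np.asarray(omega1, float), np.asarray(omega2, float)
    if len(w1) != len(w2):
        raise AlignmentError(f"length mismatch: {len(w1)} vs {len(w2)}")
    return w1 - w2


def hand_phase_series(trace: TouchTrace, circle: Circle,
                      rate_hz: float = 60.0,
                      negate: bool = False) -> PhaseSeries:
    """Resample one hand's trace and extract phase + angular velocity."""
    res = geo.resample_uniform(trace, rate_hz)
    angle = angular_position(res, circle)
    if negate:
        angle = -angle
    phase = instantaneous_phase(np.sin(np.radians(angle)))
    omega = np.gradient(angle, res.t) / 360.0
    return PhaseSeries(t=res.t, phase_deg=phase, omega_rev_s=omega)


def _trim(arr: np.ndarray, fraction: float) -> np.ndarray:
    k = int(len(arr) * fraction)
    return arr[k:len(arr) - k] if k > 0 else arr


def coordination_summary(trial: TrialRecord, rate_hz: float = 60.0,
                         trim_fraction: float = 0.1) -> SyncSummary:
    """Phase/speed synchronization summary for one bimanual trial.

    Left/right hands are identified by mean x position (two pointers
    required).  Per hand: angular position -> sin projection -> Hilbert
    phase; both series share the resampling grid, 10% of samples are
    trimmed from each end to suppress transform edge effects, and the
    statistics of |wrapped phase difference| and of the angular-velocity
    series are reported together with per-hand travel distance.
    """
    if trial.game != "round":
        raise ValueError(f"expected a round trial, got {trial.game!r}")
    task: BimanualTaskSpec = trial.task
    pids = trial.pointer_ids()
    if len(pids) < 2:
        raise InsufficientDataError("bimanual analysis needs two pointers")

    def merged(pid: int) -> TouchTrace:
        trs = trial.traces_for_pointer(pid)
        if len(trs) == 1:
            return trs[0]
        trs = sorted(trs, key=lambda tr: tr.t[0])
        return TouchTrace(
            t=np.concatenate([tr.t for tr in trs]),
            x=np.concatenate([tr.x for tr in trs]),
            y=np.concatenate([tr.y for tr in trs]),
            events=sum((tr.events for tr in trs), []),
            pointer_id=pid)

    hands = {pid: merged(pid) for pid in pids[:2]}
    by_x = sorted(hands, key=lambda pid: float(hands[pid].x.mean()))
    left, right = hands[by_x[0]], hands[by_x[1]]

    ps_left = hand_phase_series(left, task.left_circle, rate_hz)
    ps_right = hand_phase_series(right, task.right_circle, rate_hz,
                                 negate=task.mirrored)
    n = min(len(ps_left.t), len(ps_right.t))
    dphi = phase_difference(ps_left.phase_deg[:n], ps_right.phase_deg[:n])
    dphi = _trim(dphi, trim_fraction)
    abs_dphi = np.abs(dphi)

    w_left = _trim(ps_left.omega_rev_s[:n], trim_fraction)
    w_right = _trim(ps_right.omega_rev_s[:n], trim_fraction)
    dw = velocity_difference(w_right, w_left)

    phase_stat = _stat(abs_dphi)
    travel = {
        "left": geo.path_length(left, trial.device),
        "right": geo.path_length(right, trial.device),
    }
    cv_travel = None
    if len(trial.traces_for_pointer(by_x[0])) > 1:
        def cv(pid):
            ds = [geo.path_length(tr, trial.device)
                  for tr in trial.traces_for_pointer(pid) if tr.n >= 2]
            return float(np.std(ds, ddof=1) / np.mean(ds)) if len(ds) > 1 else 0.0
        cv_travel = {"left": cv(by_x[0]), "right": cv(by_x[1])}

    return SyncSummary(
        mode=task.mode,
        phase_mean_deg=phase_stat.mean,
        phase_sd_deg=phase_stat.sd,
        phase_ci95=phase_stat.ci95,
        omega_right=_stat(np.abs(w_right)),
        omega_left=_stat(np.abs(w_left)),
        omega_diff=_stat(dw),
        travel_m=travel,
        cv_travel=cv_travel,
    )
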