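"""Analyzers for the two whole-limb games.

* Drag-and-drop reaches ("market"): per-item RMSE of the perpendicular
  deviation from the straight item-to-crate path, completion time, and
  placement accuracy.
* Track tracing ("race"): the path derivative dy/dx is segmented with
  fixed-K kernel change-point detection (K=12 by default, matching the 12
  manually labeled track breakpoints), each detected segment is paired in
  order with the corresponding ideal sub-polyline, and the per-sample
  perpendicular distance to that sub-polyline yields the error RMSE.  A
  shortcut error is flagged when the trace abandons the track corridor or
  is much shorter than the track itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import Point, Polygon

from . import geometry as geo
from .changepoint import (KernelParams, Segmentation, median_bandwidth,
                          segment_fixed_k)
from .data_model import TouchTrace, TrialRecord
from .errors import ConstantSignalError, InsufficientDataError
from .tasks import MarketTaskSpec, RaceTaskSpec


@dataclass
class ReachMetrics:
    """Outcome of one drag-and-drop reach."""

    item_id: str
    rmse_mm: float
    completion_s: float
    placed_ok: bool


@dataclass
class RaceMetrics:
    """Outcome of one track-tracing attempt."""

    attempt_id: str
    hand: str
    rmse_mm: float
    per_segment_rmse_mm: list[float]
    completion_s: float
    shortcut_error: bool
    segmentation: Segmentation
    notes: list[str] = field(default_factory=list)


def _strokes(trial: TrialRecord) -> list[TouchTrace]:
    """Traces that constitute complete down->up strokes."""
    return [tr for tr in trial.traces if "up" in tr.events]


def analyze_market(trial: TrialRecord) -> list[ReachMetrics]:
    """Per-item reach metrics for a drag-and-drop trial.

    Each item's stroke is the one starting nearest the item's start
    position; items with no stroke are skipped (a warning records them).
    The whole drag path, first touch to release inclusive, contributes to
    the RMSE.
    """
    if trial.game != "market":
        raise ValueError(f"expected a market trial, got {trial.game!r}")
    task: MarketTaskSpec = trial.task
    strokes = _strokes(trial)
    if not strokes:
        raise InsufficientDataError("no complete drag strokes in trial")

    # greedy nearest-start assignment, each stroke used once
    unused = list(strokes)
    out: list[ReachMetrics] = []
    for item in task.items:
        if not unused:
            warnings.warn(f"item {item.item_id}: no stroke available; skipped")
            continue
        d0 = [float(np.hypot(tr.x[0] - item.start[0], tr.y[0] - item.start[1]))
              for tr in unused]
        j = int(np.argmin(d0))
        if d0[j] > 150.0:
            warnings.warn(f"item {item.item_id}: nearest stroke starts "
                          f"{d0[j]:.0f}pt away; skipped")
            continue
        stroke = unused.pop(j)
        line = geo.line_coefficients(
            geo.ReachEndpoints(item.start, item.box_center))
        dev = geo.path_rmse(stroke, line, trial.device)
        box = Polygon(item.box_polygon)
        drop = Point(float(stroke.x[-1]), float(stroke.y[-1]))
        out.append(ReachMetrics(
            item_id=item.item_id,
            rmse_mm=dev.rmse_mm,
            completion_s=stroke.duration_s,
            placed_ok=bool(box.covers(drop)),
        ))
    return out


def detect_shortcut(trace: TouchTrace, task: RaceTaskSpec,
                    off_track_fraction: float = 0.25,
                    shortcut_ratio: float = 0.8) -> bool:
    """True when the trace cuts across instead of following the track.

    Fires when the fraction of samples farther than the corridor
    half-width from the track reaches ``off_track_fraction``, or when the
    traced path is shorter than ``shortcut_ratio`` times the track length.
    """
    d = geo.points_polyline_distance(trace.xy, task.track)
    off_frac = float(np.mean(d > task.corridor_width_pt))
    if off_frac >= off_track_fraction:
        return True
    if trace.n >= 2:
        steps = float(np.hypot(np.diff(trace.x), np.diff(trace.y)).sum())
        if steps < shortcut_ratio * task.track_length_pt():
            return True
    return False


def _smoothed_for_derivative(trace: TouchTrace, rate_hz: float) -> TouchTrace:
    """Low-pass the path before differentiating: touch wobble is noise,
    not curvature.  Distances are still measured on the raw samples."""
    win = int(0.35 * rate_hz) | 1          # ~0.35 s, odd
    if trace.n <= win:
        return trace
    return TouchTrace(t=trace.t, x=savgol_filter(trace.x, win, 2),
                      y=savgol_filter(trace.y, win, 2),
                      events=list(trace.events), pointer_id=trace.pointer_id)


def _pair_segments(seg_samples: list[np.ndarray],
                   subpolys: list[np.ndarray]) -> list[int]:
    """Monotone minimal-cost assignment of detected segments to ideal
    sub-polylines.

    The k-th detected segment maps to the k-th sub-polyline whenever the
    segmentation is clean (the identity is the unique cost minimizer);
    under noisy segmentations the monotone assignment absorbs a spurious
    or missed split instead of shifting every later pairing.
    """
    n_seg, n_sub = len(seg_samples), len(subpolys)
    cost = np.zeros((n_seg, n_sub))
    for i, pts in enumerate(seg_samples):
        w = len(pts)
        for j, sp in enumerate(subpolys):
            cost[i, j] = w * float(np.mean(geo.points_polyline_distance(pts, sp)))
    dp = np.full((n_seg, n_sub), np.inf)
    back = np.zeros((n_seg, n_sub), dtype=int)
    dp[0] = cost[0]
    for i in range(1, n_seg):
        run, arg = np.inf, 0
        for j in range(n_sub):
            if dp[i - 1, j] < run:
                run, arg = dp[i - 1, j], j
            dp[i, j] = cost[i, j] + run
            back[i, j] = arg
    j = int(np.argmin(dp[-1]))
    assign = [0] * n_seg
    assign[-1] = j
    for i in range(n_seg - 1, 0, -1):
        j = int(back[i, j])
        assign[i - 1] = j
    return assign


def analyze_race(trial: TrialRecord, k: int = 12,
                 rate_hz: float = 60.0,
                 params: KernelParams | None = None) -> list[RaceMetrics]:
    """Per-attempt tracing metrics for a race trial.

    Pipeline per attempt: resample -> smooth -> derivative signal ->
    fixed-K kernel segmentation -> monotone pairing of detected segments
    with the ideal sub-polylines between consecutive manual breakpoints ->
    per-sample perpendicular distance to the paired sub-polyline (or its
    immediate neighbor, for samples near a detected boundary) -> RMSE (mm).
    """
    if trial.game != "race":
        raise ValueError(f"expected a race trial, got {trial.game!r}")
    task: RaceTaskSpec = trial.task
    subpolys = task.ideal_subpolylines()
    out: list[RaceMetrics] = []
    for idx, raw in enumerate(_strokes(trial) or trial.traces):
        notes: list[str] = []
        try:
            trace = geo.resample_uniform(raw, rate_hz)
        except InsufficientDataError:
            warnings.warn(f"attempt {idx}: too few samples; marked incomplete")
            continue
        if trace.n < 3:
            warnings.warn(f"attempt {idx}: too few samples; marked incomplete")
            continue
        deriv = geo.derivative_signal(_smoothed_for_derivative(trace, rate_hz))
        min_size = params.min_size if params is not None else 5
        k_eff = k
        if deriv.n < (k + 1) * min_size:
            k_eff = max(deriv.n // min_size - 1, 0)
            notes.append(f"K={k} infeasible for T={deriv.n}; used K={k_eff}")
            warnings.warn(notes[-1])
        p = params
        if p is None:
            try:
                p = KernelParams(gamma=median_bandwidth(deriv), min_size=min_size)
            except ConstantSignalError:
                p = KernelParams(gamma=1.0, min_size=min_size)
        seg = segment_fixed_k(deriv, k_eff, p)
        if seg.n_segments != len(subpolys):
            notes.append(f"{seg.n_segments} detected segments vs "
                         f"{len(subpolys)} ideal sub-polylines")
            warnings.warn(notes[-1])

        # derivative index i corresponds to resampled sample i+1; map the
        # two edge samples onto the first / last segment
        seg_samples: list[np.ndarray] = []
        for s_idx, (a, b) in enumerate(seg.segments()):
            lo = a + 1 if s_idx > 0 else 0
            hi = b + 1 if s_idx < seg.n_segments - 1 else trace.n
            seg_samples.append(trace.xy[lo:hi])
        assign = _pair_segments(seg_samples, subpolys)

        d_mm_parts: list[np.ndarray] = []
        per_segment: list[float] = []
        for pts, j in zip(seg_samples, assign):
            cand = [jj for jj in (j - 1, j, j + 1) if 0 <= jj < len(subpolys)]
            d_pt = np.min(np.column_stack(
                [geo.points_polyline_distance(pts, subpolys[jj])
                 for jj in cand]), axis=1)
            d_mm = d_pt * trial.device.mm_per_point
            d_mm_parts.append(d_mm)
            per_segment.append(float(np.sqrt(np.mean(d_mm ** 2))))
        all_d = np.concatenate(d_mm_parts)
        out.append(RaceMetrics(
            attempt_id=f"{trial.trial_id}:{idx}",
            hand=trial.hand,
            rmse_mm=float(np.sqrt(np.mean(all_d ** 2))),
            per_segment_rmse_mm=per_segment,
            completion_s=raw.duration_s,
            shortcut_error=detect_shortcut(trace, task),
            segmentation=seg,
            notes=notes,
        ))
    if not out:
        raise InsufficientDataError("no analyzable race attempts in trial")
    return out
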