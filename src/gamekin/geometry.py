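"""Geometric and kinematic primitives shared by the game analyzers.

Covers uniform resampling of irregular touch events, perpendicular
deviation from a straight reach path and its RMSE in millimetres, minimum
distance to a polyline (the ideal track), total travel distance, and the
first-order derivative signal dy/dx that feeds change-point detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .data_model import DeviceProfile, TouchTrace
from .errors import DegenerateGeometryError, InsufficientDataError


@dataclass(frozen=True)
class LineCoefficients:
    """Implicit line alpha*x + beta*y + delta = 0, normalized to alpha^2+beta^2=1."""

    alpha: float
    beta: float
    delta: float


@dataclass(frozen=True)
class ReachEndpoints:
    """Start (P1) and target (P2) of a drag-and-drop reach, in screen points."""

    p1: tuple[float, float]
    p2: tuple[float, float]


@dataclass
class DerivativeSignal:
    """Clamped first-order derivative dy/dx along a resampled path."""

    values: np.ndarray
    clamp_bound: float

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class DeviationSeries:
    """Per-sample perpendicular deviations (mm) and their root mean square."""

    d_mm: np.ndarray

    @property
    def rmse_mm(self) -> float:
        return float(np.sqrt(np.mean(self.d_mm ** 2)))


def resample_uniform(trace: TouchTrace, rate: float = 60.0) -> TouchTrace:
    """Linearly interpolate a trace onto a uniform grid of ``rate`` Hz.

    Output sample times are exact multiples of 1/rate inside
    [t_first, t_last].  Duplicate timestamps are collapsed (last wins)
    before interpolation.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t, x, y = trace.t, trace.x, trace.y
    keep = np.concatenate([np.diff(t) > 0, [True]])   # last of each duplicate
    t, x, y = t[keep], x[keep], y[keep]
    if len(t) < 2:
        raise InsufficientDataError(
            f"resampling needs >= 2 distinct timestamps, got {len(t)}")
    dt = 1.0 / rate
    k0 = int(np.ceil(t[0] / dt - 1e-9))
    k1 = int(np.floor(t[-1] / dt + 1e-9))
    grid = np.arange(k0, k1 + 1) * dt
    xi = np.interp(grid, t, x)
    yi = np.interp(grid, t, y)
    events = ["move"] * len(grid)
    if events:
        events[0], events[-1] = "down", "up"
    return TouchTrace(t=grid, x=xi, y=yi, events=events,
                      pointer_id=trace.pointer_id)


def line_coefficients(endpoints: ReachEndpoints) -> LineCoefficients:
    """Implicit coefficients of the shortest path P1->P2."""
    (x1, y1), (x2, y2) = endpoints.p1, endpoints.p2
    alpha, beta = y2 - y1, x1 - x2
    norm = float(np.hypot(alpha, beta))
    if norm < 1e-12:
        raise DegenerateGeometryError("P1 and P2 coincide; no line defined")
    alpha, beta = alpha / norm, beta / norm
    delta = -(alpha * x1 + beta * y1)
    return LineCoefficients(alpha, beta, delta)


def point_line_distance(point, line: LineCoefficients) -> float:
    """Perpendicular distance |alpha*x + beta*y + delta| / sqrt(alpha^2+beta^2)."""
    x, y = point
    norm = np.hypot(line.alpha, line.beta)
    return float(abs(line.alpha * x + line.beta * y + line.delta) / norm)


def points_line_distance(xy: np.ndarray, line: LineCoefficients) -> np.ndarray:
    """Vectorized ``point_line_distance`` over an (N, 2) array."""
    norm = np.hypot(line.alpha, line.beta)
    return np.abs(line.alpha * xy[:, 0] + line.beta * xy[:, 1] + line.delta) / norm


def path_rmse(trace: TouchTrace, line: LineCoefficients,
              device: DeviceProfile) -> DeviationSeries:
    """Per-sample perpendicular deviation from a straight path, in mm.

    Every sample of the trace contributes, including the first and last.
    """
    if trace.n < 1:
        raise InsufficientDataError("path_rmse needs a nonempty trace")
    d_pt = points_line_distance(trace.xy, line)
    return DeviationSeries(d_mm=d_pt * device.mm_per_point)


def polyline_distance(point, polyline: np.ndarray) -> float:
    """Minimum Euclidean distance from a point to a polyline, in points."""
    return float(points_polyline_distance(np.atleast_2d(point),
                                          np.asarray(polyline, dtype=float))[0])


def points_polyline_distance(xy: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Vectorized minimum distance from each row of ``xy`` to the polyline."""
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or len(polyline) < 2:
        raise DegenerateGeometryError("polyline needs >= 2 vertices")
    line = shapely.LineString(polyline)
    pts = shapely.points(np.asarray(xy, dtype=float))
    return shapely.distance(pts, line)


def path_length(trace: TouchTrace, device: DeviceProfile) -> float:
    """Total traveled distance in meters (sum of consecutive segment lengths)."""
    if trace.n < 2:
        raise InsufficientDataError("path_length needs N >= 2")
    steps = np.hypot(np.diff(trace.x), np.diff(trace.y))
    return float(steps.sum() * device.meters_per_point)


def derivative_signal(trace: TouchTrace, clamp_bound: float = 1e3,
                      eps: float = 1e-9) -> DerivativeSignal:
    """Central-difference dy/dx along the path, clamped to +-clamp_bound.

    The slope is formally unbounded (vertical motion); wherever
    |x_{i+1} - x_{i-1}| < eps the slope is set to sign(dy) * clamp_bound,
    and all values are clipped into [-clamp_bound, clamp_bound].
    """
    if trace.n < 3:
        raise InsufficientDataError("derivative_signal needs N >= 3")
    dx = trace.x[2:] - trace.x[:-2]
    dy = trace.y[2:] - trace.y[:-2]
    vals = np.empty_like(dx)
    small = np.abs(dx) < eps
    np.divide(dy, dx, out=vals, where=~small)
    vals[small] = np.sign(dy[small]) * clamp_bound
    np.clip(vals, -clamp_bound, clamp_bound, out=vals)
    return DerivativeSignal(values=vals, clamp_bound=clamp_bound)
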