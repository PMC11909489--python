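"""Analyzers for the coloring and Morse-tapping games.

Coloring ("filling"): strokes are rasterized onto a grid of small cells
with a circular brush; the *set* of colored cells (duplicates count once)
is split into inside/outside of the target shape, giving accuracy
percentages and coverage.

Morse tapping ("message"): press intervals reconstructed from down/up
events are classified as dots or dashes by duration, aligned in order
against the expected dot/dash stream of the hidden message, and mismatches
are errors.  The tapping and holding fingers swap halfway through the
trial; the holding finger's excursions from its circular target are
counted as displacements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import points as _shapely_points
from shapely.prepared import prep

from .data_model import DeviceProfile, TouchTrace, TrialRecord
from .errors import InsufficientDataError, ParameterError
from .tasks import Circle, MessageSpec, ShapeSpec

Cell = tuple[int, int]


# ---------------------------------------------------------------------------
# coloring


@dataclass
class ColoringMetrics:
    shape_id: str
    inside_pct: float          # % of unique colored cells inside the shape
    outside_pct: float         # % outside (the two sum to 100 when defined)
    coverage_pct: float        # % of the shape's own cells that were colored
    completion_s: float
    inside_defined: bool = True


def _disc_offsets(brush_radius_pt: float, cell_pt: float) -> list[Cell]:
    r_cells = brush_radius_pt / cell_pt
    rng = range(-int(math.ceil(r_cells)), int(math.ceil(r_cells)) + 1)
    return [(dx, dy) for dx in rng for dy in rng
            if dx * dx + dy * dy <= r_cells * r_cells]


def rasterize_strokes(strokes: list[TouchTrace], brush_radius_pt: float,
                      cell_pt: float = 2.0) -> set[Cell]:
    """Set of grid cells touched by a circular brush along the strokes.

    Stroke polylines are first subdivided so consecutive points are at
    most half a cell apart; every cell whose index lies within the brush
    radius of an interpolated point is marked.  Retracing contributes
    nothing new — the result is a set.
    """
    if not strokes:
        raise InsufficientDataError("rasterize_strokes needs >= 1 stroke")
    if brush_radius_pt <= 0:
        raise ParameterError("brush radius must be > 0")
    offsets = _disc_offsets(brush_radius_pt, cell_pt)
    cells: set[Cell] = set()
    step = cell_pt / 2.0
    for tr in strokes:
        xs, ys = [tr.x[0]], [tr.y[0]]
        for i in range(1, tr.n):
            seg = math.hypot(tr.x[i] - tr.x[i - 1], tr.y[i] - tr.y[i - 1])
            n_sub = max(int(math.ceil(seg / step)), 1)
            frac = np.linspace(0.0, 1.0, n_sub + 1)[1:]
            xs.extend(tr.x[i - 1] + frac * (tr.x[i] - tr.x[i - 1]))
            ys.extend(tr.y[i - 1] + frac * (tr.y[i] - tr.y[i - 1]))
        ix = np.floor(np.asarray(xs) / cell_pt).astype(int)
        iy = np.floor(np.asarray(ys) / cell_pt).astype(int)
        for cx, cy in zip(ix, iy):
            for dx, dy in offsets:
                cells.add((cx + dx, cy + dy))
    return cells


def shape_cells(shape: ShapeSpec, cell_pt: float | None = None) -> set[Cell]:
    """All grid cells whose centers fall inside the shape (boundary counts)."""
    cell = cell_pt if cell_pt is not None else shape.raster_cell_pt
    geom = shape.to_shapely()
    minx, miny, maxx, maxy = geom.bounds
    ix = np.arange(int(math.floor(minx / cell)) - 1,
                   int(math.ceil(maxx / cell)) + 2)
    iy = np.arange(int(math.floor(miny / cell)) - 1,
                   int(math.ceil(maxy / cell)) + 2)
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    centers = np.column_stack([(gx.ravel() + 0.5) * cell,
                               (gy.ravel() + 0.5) * cell])
    pgeom = prep(geom)
    pts = _shapely_points(centers)
    mask = np.array([pgeom.covers(p) for p in pts])
    return {(int(a), int(b)) for a, b in zip(gx.ravel()[mask], gy.ravel()[mask])}


def coloring_accuracy(cells: set[Cell], shape: ShapeSpec,
                      duration_s: float,
                      cell_pt: float | None = None) -> ColoringMetrics:
    """Inside/outside split of the colored cell set and shape coverage."""
    cell = cell_pt if cell_pt is not None else shape.raster_cell_pt
    target = shape_cells(shape, cell)
    if not cells:
        return ColoringMetrics(shape.shape_id, float("nan"), float("nan"),
                               0.0, duration_s, inside_defined=False)
    n_in = len(cells & target)
    n_total = len(cells)
    inside_pct = 100.0 * n_in / n_total
    coverage_pct = 100.0 * n_in / len(target) if target else 0.0
    return ColoringMetrics(
        shape_id=shape.shape_id,
        inside_pct=inside_pct,
        outside_pct=100.0 - inside_pct,
        coverage_pct=min(coverage_pct, 100.0),
        completion_s=duration_s,
    )


def analyze_filling(trial: TrialRecord) -> list[ColoringMetrics]:
    """Per-shape coloring metrics; strokes go to the nearest shape centroid."""
    if trial.game != "filling":
        raise ValueError(f"expected a filling trial, got {trial.game!r}")
    task = trial.task
    centroids = [np.asarray(s.to_shapely().centroid.coords[0])
                 for s in task.shapes]
    by_shape: dict[int, list[TouchTrace]] = {i: [] for i in range(len(task.shapes))}
    for tr in trial.traces:
        mid = np.array([tr.x.mean(), tr.y.mean()])
        j = int(np.argmin([np.hypot(*(mid - c)) for c in centroids]))
        by_shape[j].append(tr)
    out = []
    for i, shape in enumerate(task.shapes):
        strokes = by_shape[i]
        if not strokes:
            out.append(ColoringMetrics(shape.shape_id, float("nan"),
                                       float("nan"), 0.0, 0.0,
                                       inside_defined=False))
            continue
        cells = rasterize_strokes(strokes, task.brush_radius_pt,
                                  shape.raster_cell_pt)
        dur = sum(tr.duration_s for tr in strokes)
        out.append(coloring_accuracy(cells, shape, dur))
    return out


# ---------------------------------------------------------------------------
# Morse tapping


@dataclass
class Press:
    t_down: float
    t_up: float
    pointer_id: int

    @property
    def duration_s(self) -> float:
        return self.t_up - self.t_down


@dataclass
class TappingMetrics:
    taps_total: int
    errors_total: int
    chars_revealed: int
    per_window: list[tuple[float, float, float]]   # (start_s, tap/s, err/s)
    displacements: int
    fixed_path_len_mm: float


def classify_press(duration_s: float, spec: MessageSpec) -> str:
    """'dot' for presses up to dot_max_s (boundary inclusive), else 'dash'."""
    if duration_s <= 0:
        raise ParameterError("press duration must be positive")
    return "." if duration_s <= spec.dot_max_s else "-"


def extract_presses(trial: TrialRecord) -> list[Press]:
    """Down->up press intervals per trace; orphan events are dropped."""
    presses = []
    for tr in trial.traces:
        t_down = None
        for i, ev in enumerate(tr.events):
            if ev == "down":
                if t_down is not None:
                    warnings.warn("unmatched down event dropped")
                t_down = float(tr.t[i])
            elif ev == "up":
                if t_down is None:
                    warnings.warn("unmatched up event dropped")
                    continue
                presses.append(Press(t_down, float(tr.t[i]), tr.pointer_id))
                t_down = None
    presses.sort(key=lambda p: p.t_down)
    return presses


def fixed_finger_displacements(trace: TouchTrace, target: Circle,
                               device: DeviceProfile) -> tuple[int, float]:
    """Count inside->outside exits from the holding circle + path length (mm).

    The finger is expected to start inside; an entry followed by an exit
    counts once per exit transition.
    """
    d = np.hypot(trace.x - target.cx, trace.y - target.cy)
    inside = d <= target.r
    exits = int(np.sum(inside[:-1] & ~inside[1:]))
    if trace.n >= 2:
        plen = float(np.hypot(np.diff(trace.x), np.diff(trace.y)).sum()
                     * device.mm_per_point)
    else:
        plen = 0.0
    return exits, plen


def _tapper_for_half(presses: list[Press], trial: TrialRecord,
                     lo: float, hi: float) -> int | None:
    counts: dict[int, int] = {}
    for p in presses:
        if lo <= p.t_down < hi:
            counts[p.pointer_id] = counts.get(p.pointer_id, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda pid: counts[pid])


def score_message(trial: TrialRecord, spec: MessageSpec | None = None,
                  window_s: float = 10.0) -> TappingMetrics:
    """Score one Morse-tapping trial.

    Presses of the tapping pointer (per 90-s half) are classified dot/dash
    and matched greedily, in order, against the expected symbol stream of
    the message; each mismatch is one error.  ``chars_revealed`` counts
    message characters whose full symbol sequence was consumed.  Tumbling
    windows of ``window_s`` over the nominal trial duration give tap and
    error rates; the non-tapping pointer supplies displacement count and
    path length.
    """
    if trial.game != "message":
        raise ValueError(f"expected a message trial, got {trial.game!r}")
    spec = spec if spec is not None else trial.task
    if len(trial.pointer_ids()) < 2:
        raise InsufficientDataError("message trial needs two pointers")
    presses = extract_presses(trial)
    if not presses:
        raise InsufficientDataError("no complete presses in trial")

    halves = [(0.0, spec.switch_time_s),
              (spec.switch_time_s, float("inf"))]
    tap_presses: list[Press] = []
    fixed_traces: list[TouchTrace] = []
    for lo, hi in halves:
        tapper = _tapper_for_half(presses, trial, lo, hi)
        if tapper is None:
            continue
        tap_presses.extend(p for p in presses
                           if lo <= p.t_down < hi and p.pointer_id == tapper)
        for tr in trial.traces:
            if tr.pointer_id != tapper and tr.t[0] < hi and tr.t[-1] >= lo:
                mask = (tr.t >= lo) & (tr.t < hi)
                if mask.sum() >= 1:
                    fixed_traces.append(TouchTrace(
                        t=tr.t[mask], x=tr.x[mask], y=tr.y[mask],
                        events=[e for e, m in zip(tr.events, mask) if m],
                        pointer_id=tr.pointer_id))

    expected = spec.expected_symbols()
    produced = [(classify_press(p.duration_s, spec), p) for p in tap_presses]
    n_cmp = min(len(produced), len(expected))
    error_times = [produced[i][1].t_down for i in range(n_cmp)
                   if produced[i][0] != expected[i]]
    errors_total = len(error_times)
    boundaries = spec.char_boundaries()
    chars_revealed = sum(1 for b in boundaries if b <= n_cmp)

    n_windows = int(math.ceil(spec.trial_duration_s / window_s))
    per_window = []
    for w in range(n_windows):
        lo, hi = w * window_s, (w + 1) * window_s
        taps = sum(1 for p in tap_presses if lo <= p.t_down < hi)
        errs = sum(1 for t in error_times if lo <= t < hi)
        per_window.append((lo, taps / window_s, errs / window_s))

    displacements, fixed_len = 0, 0.0
    for tr in fixed_traces:
        d, plen = fixed_finger_displacements(tr, spec.target_circle,
                                             trial.device)
        displacements += d
        fixed_len += plen

    return TappingMetrics(
        taps_total=len(tap_presses),
        errors_total=errors_total,
        chars_revealed=chars_revealed,
        per_window=per_window,
        displacements=displacements,
        fixed_path_len_mm=fixed_len,
    )
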