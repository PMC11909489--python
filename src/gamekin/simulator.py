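"""Synthetic touch-trace generator for all five games.

The generator stands in for study participants: it produces trial records
with the same statistical structure the analyzers are designed to
measure, with every generative parameter known, so each analyzer can be
tested by parameter recovery.  Built-in structure:

* reaches follow a minimum-jerk profile with zero-mean Gaussian
  perpendicular noise;
* a single ``speed_factor`` couples movement speed to injected noise
  (faster => noisier), producing the speed-accuracy tradeoff;
* ``skill`` (monotone in age for cohorts) scales noise down and speed up,
  producing the age trend;
* bimanual phase jitter is a mean-reverting (Ornstein-Uhlenbeck) process,
  with antiphase modes configured harder than in-phase in cohorts.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import DeviceProfile, TouchTrace, TrialRecord
from .tasks import (BIMANUAL_MODES, GAMES, BimanualTaskSpec, FillingTaskSpec,
                    MarketTaskSpec, MessageSpec, RaceTaskSpec, ShapeSpec,
                    default_task)

__all__ = [
    "SimConfig", "CohortSpec", "simulate_reach", "simulate_race",
    "simulate_coloring", "simulate_tapping", "simulate_bimanual",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (all randomness derives from ``seed``)."""

    seed: int = 0
    rate_hz: float = 60.0
    skill: float = 0.7              # in (0, 1]: higher = faster, less noise
    speed_factor: float = 1.0       # > 1 = hurried: faster AND noisier
    noise_sd_mm: float = 2.0        # baseline spatial noise scale
    phase_jitter_deg: float = 10.0  # stationary SD of bimanual phase jitter
    omega_rev_s: tuple[float, float] = (0.6, 0.6)   # left, right
    noise_corr_s: float = 0.25      # correlation time of tracing wobble
    tap_error_p: float = 0.2        # per-symbol Morse error probability
    tap_error_decay: float = 0.85   # multiplicative decay per 10-s window
    forced_tap_errors: int | None = None   # exact error count override
    n_target_exits: int = 2         # fixed-finger excursions per trial
    coverage_frac: float = 0.9      # coloring: fraction of shape to fill
    outside_frac: float = 0.1       # coloring: target fraction of cells outside
    shortcut: bool = False          # race: draw the direct chord instead
    samples_per_reach: int | None = None   # override reach sample count
    age_years: float | None = None

    def noise_sd_pt(self, device: DeviceProfile) -> float:
        return (self.noise_sd_mm * self.speed_factor / self.skill
                / device.mm_per_point)


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a simulated cohort: ages map monotonically to skill."""

    n_participants: int = 31
    age_range_years: tuple[float, float] = (5.0, 14.0)
    games: tuple[str, ...] = GAMES
    skill_range: tuple[float, float] = (0.35, 1.0)

    def skill_for_age(self, age: float) -> float:
        """Linear in log-age between the skill bounds (monotone increasing)."""
        lo, hi = self.age_range_years
        s0, s1 = self.skill_range
        f = (math.log(age) - math.log(lo)) / (math.log(hi) - math.log(lo))
        return float(np.clip(s0 + (s1 - s0) * f, s0, s1))


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _ou_series(rng: np.random.Generator, n: int, sd: float,
               dt: float, tau_s: float) -> np.ndarray:
    """Mean-reverting (OU) noise with stationary SD ``sd``."""
    out = np.zeros(n)
    if sd <= 0 or n == 0:
        return out
    a = math.exp(-dt / tau_s)
    step = sd * math.sqrt(1 - a * a)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = a * out[i - 1] + rng.normal(0.0, step)
    return out


def _trace(t, x, y, pointer_id=0) -> TouchTrace:
    events = ["move"] * len(t)
    events[0], events[-1] = "down", "up"
    return TouchTrace(t=np.asarray(t, float), x=np.asarray(x, float),
                      y=np.asarray(y, float), events=events,
                      pointer_id=pointer_id)


def _clip_screen(x, y, device: DeviceProfile):
    return (np.clip(x, 0.0, device.screen_width_pt),
            np.clip(y, 0.0, device.screen_height_pt))


# ---------------------------------------------------------------------------
# drag-and-drop reaches


def simulate_reach(task: MarketTaskSpec, cfg: SimConfig,
                   hand: str = "right",
                   device: DeviceProfile | None = None) -> TrialRecord:
    """One drag-and-drop attempt: a minimum-jerk drag per item.

    Drag duration shrinks with skill and speed_factor; perpendicular noise
    SD is noise_sd_mm * speed_factor / skill; the drop lands inside the
    crate with probability increasing in skill.
    """
    device = device or DeviceProfile()
    rng = np.random.default_rng(cfg.seed)
    sigma_pt = cfg.noise_sd_pt(device)
    duration = float(np.clip(1.2 / ((0.4 + 0.6 * cfg.skill) * cfg.speed_factor),
                             0.3, 5.0))
    traces, truth_items = [], []
    t0 = 0.0
    for item in task.items:
        p1, p2 = np.asarray(item.start), np.asarray(item.box_center)
        n = cfg.samples_per_reach or max(int(round(duration * cfg.rate_hz)) + 1, 8)
        tau = np.linspace(0.0, 1.0, n)
        pos = p1 + _minimum_jerk(tau)[:, None] * (p2 - p1)
        direction = (p2 - p1) / np.linalg.norm(p2 - p1)
        normal = np.array([-direction[1], direction[0]])
        noise = rng.normal(0.0, sigma_pt, n)
        pos = pos + noise[:, None] * normal

        placed = bool(rng.random() < np.clip(0.55 + 0.5 * cfg.skill, 0.0, 1.0))
        if placed:
            pos[-1] = p2 + rng.normal(0.0, 3.0, 2)
        else:
            xs = [v[0] for v in item.box_polygon]
            pos[-1] = (max(xs) + 12.0, item.box_center[1])
        x, y = _clip_screen(pos[:, 0], pos[:, 1], device)
        traces.append(_trace(t0 + tau * duration, x, y))
        truth_items.append({"item_id": item.item_id, "placed": placed,
                            "duration_s": duration})
        t0 += duration + 0.4

    return TrialRecord(
        trial_id=f"market-s{cfg.seed}", game="market", hand=hand,
        traces=traces, task=task, device=device, age_years=cfg.age_years,
        meta={"truth": {"noise_sd_mm": cfg.noise_sd_mm * cfg.speed_factor / cfg.skill,
                        "speed_factor": cfg.speed_factor,
                        "skill": cfg.skill, "items": truth_items}},
    )


# ---------------------------------------------------------------------------
# track tracing


def simulate_race(task: RaceTaskSpec, cfg: SimConfig,
                  hand: str = "right", n_attempts: int = 1,
                  device: DeviceProfile | None = None) -> TrialRecord:
    """Arc-length traversal of the track with lateral Gaussian noise.

    With ``cfg.shortcut`` the trace is the direct start-to-end chord.
    """
    device = device or DeviceProfile()
    rng = np.random.default_rng(cfg.seed)
    sigma_pt = cfg.noise_sd_pt(device)
    duration = float(np.clip(16.0 / ((0.4 + 0.6 * cfg.skill) * cfg.speed_factor),
                             4.0, task.time_limit_s - 1.0))
    seglen = np.hypot(*np.diff(task.track, axis=0).T)
    cumlen = np.concatenate([[0.0], np.cumsum(seglen)])
    traces = []
    t0 = 0.0
    for _ in range(n_attempts):
        n = int(round(duration * cfg.rate_hz)) + 1
        tt = np.linspace(0.0, duration, n)
        if cfg.shortcut:
            chord_t = np.linspace(0.0, duration * 0.25, max(n // 4, 2))
            frac = chord_t / chord_t[-1]
            x = task.track[0, 0] + frac * (task.track[-1, 0] - task.track[0, 0])
            y = task.track[0, 1] + frac * (task.track[-1, 1] - task.track[0, 1])
            x, y = _clip_screen(x, y, device)
            traces.append(_trace(t0 + chord_t, x, y))
            t0 += duration * 0.25 + 1.0
            continue
        s = cumlen[-1] * tt / duration
        x = np.interp(s, cumlen, task.track[:, 0])
        y = np.interp(s, cumlen, task.track[:, 1])
        tx, ty = np.gradient(x), np.gradient(y)
        norm = np.hypot(tx, ty)
        norm[norm == 0] = 1.0
        nx, ny = -ty / norm, tx / norm
        # smooth lateral wobble: tracing error is band-limited, not white
        noise = _ou_series(rng, n, sigma_pt, 1.0 / cfg.rate_hz, cfg.noise_corr_s)
        x, y = _clip_screen(x + noise * nx, y + noise * ny, device)
        traces.append(_trace(t0 + tt, x, y))
        t0 += duration + 1.0

    return TrialRecord(
        trial_id=f"race-s{cfg.seed}", game="race", hand=hand,
        traces=traces, task=task, device=device, age_years=cfg.age_years,
        meta={"truth": {"noise_sd_mm": cfg.noise_sd_mm * cfg.speed_factor / cfg.skill,
                        "duration_s": duration, "shortcut": cfg.shortcut,
                        "skill": cfg.skill}},
    )


# ---------------------------------------------------------------------------
# coloring


def simulate_coloring(shape: ShapeSpec, cfg: SimConfig,
                      hand: str = "right",
                      brush_radius_pt: float = 6.0,
                      device: DeviceProfile | None = None) -> TrialRecord:
    """Boustrophedon fill of one shape plus boundary overshoot dabs.

    Fills ``coverage_frac`` of the shape's scan rows with strokes kept
    safely inside, then adds short exterior dabs along the boundary until
    the fraction of colored cells outside the shape reaches
    ``outside_frac``.  Ground-truth cell counts are stored in the trial
    meta for recovery testing.
    """
    from .fine_motor import rasterize_strokes, shape_cells

    device = device or DeviceProfile()
    rng = np.random.default_rng(cfg.seed)
    geom = shape.to_shapely()
    inner = geom.buffer(-(brush_radius_pt + shape.raster_cell_pt))
    if inner.is_empty:
        inner = geom.buffer(-brush_radius_pt / 2.0)
    minx, miny, maxx, maxy = inner.bounds

    from shapely.geometry import LineString, Point

    rows = np.arange(miny + brush_radius_pt / 2.0, maxy, 1.5 * brush_radius_pt)
    n_rows = max(int(round(cfg.coverage_frac * len(rows))), 1)
    strokes = []
    for i, ry in enumerate(rows[:n_rows]):
        cut = inner.intersection(LineString([(minx - 10, ry), (maxx + 10, ry)]))
        parts = getattr(cut, "geoms", [cut]) if not cut.is_empty else []
        for part in parts:
            (xa, ya), (xb, yb) = part.coords[0], part.coords[-1]
            if i % 2 == 1:
                xa, xb = xb, xa
            npts = max(int(abs(xb - xa) / 4.0), 2)
            xs = np.linspace(xa, xb, npts)
            ys = np.full(npts, ry)
            strokes.append((xs, ys))

    # exterior dabs until the outside fraction is met
    cells = rasterize_strokes(
        [_trace(np.arange(len(xs)), xs, ys) for xs, ys in strokes],
        brush_radius_pt, shape.raster_cell_pt)
    target = shape_cells(shape, shape.raster_cell_pt)
    n_inside_seed = len(cells & target)
    boundary = geom.exterior if hasattr(geom, "exterior") else geom.boundary
    perim = boundary.length
    offsets = rng.permutation(np.linspace(0.0, perim, 80, endpoint=False))
    dab_strokes = []
    if cfg.outside_frac > 0:
        want_out = cfg.outside_frac / (1.0 - cfg.outside_frac) * n_inside_seed
        for off in offsets:
            n_out = len(cells - target)
            if n_out >= want_out:
                break
            p0 = boundary.interpolate(off)
            p1 = boundary.interpolate((off + 2.0) % perim)
            tangent = np.array([p1.x - p0.x, p1.y - p0.y])
            tangent /= max(np.linalg.norm(tangent), 1e-9)
            normal = np.array([-tangent[1], tangent[0]])
            probe = np.array([p0.x, p0.y]) + normal * (brush_radius_pt + 4)
            if geom.contains(Point(*probe)):
                normal = -normal
            center = (np.array([p0.x, p0.y])
                      + normal * (brush_radius_pt + 2 * shape.raster_cell_pt))
            frac = np.linspace(-1.5, 1.5, 6)
            xs = center[0] + frac * brush_radius_pt * tangent[0]
            ys = center[1] + frac * brush_radius_pt * tangent[1]
            dab_strokes.append((xs, ys))
            cells |= rasterize_strokes([_trace(np.arange(6), xs, ys)],
                                       brush_radius_pt, shape.raster_cell_pt)

    # assemble timed traces (pen speed ~500 pt/s, 0.2 s between strokes)
    traces = []
    t0 = 0.0
    for xs, ys in strokes + dab_strokes:
        plen = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
        dur = max(plen / 500.0, 0.05)
        tt = t0 + np.linspace(0.0, dur, len(xs))
        x, y = _clip_screen(np.asarray(xs), np.asarray(ys), device)
        traces.append(_trace(tt, x, y))
        t0 += dur + 0.2

    n_in = len(cells & target)
    n_out = len(cells - target)
    task = FillingTaskSpec(shapes=[shape], brush_radius_pt=brush_radius_pt)
    return TrialRecord(
        trial_id=f"filling-{shape.shape_id}-s{cfg.seed}", game="filling",
        hand=hand, traces=traces, task=task, device=device,
        age_years=cfg.age_years,
        meta={"truth": {"n_inside": n_in, "n_outside": n_out,
                        "outside_frac": n_out / max(n_in + n_out, 1),
                        "coverage_frac": n_in / max(len(target), 1)}},
    )


# ---------------------------------------------------------------------------
# Morse tapping


def simulate_tapping(spec: MessageSpec, cfg: SimConfig,
                     hand: str = "both",
                     device: DeviceProfile | None = None) -> TrialRecord:
    """Down/up event stream producing the message's dot/dash sequence.

    Wrong-duration presses are injected with probability ``tap_error_p``
    decaying by ``tap_error_decay`` per 10-s window (or exactly
    ``forced_tap_errors`` of them when set).  The tapping and fixed
    pointers swap at the switch time; the fixed finger performs a bounded
    mean-reverting walk inside the target with ``n_target_exits``
    deliberate excursions.
    """
    device = device or DeviceProfile()
    rng = np.random.default_rng(cfg.seed)
    symbols = spec.expected_symbols()
    dot_d, dash_d = spec.dot_max_s * 0.5, spec.dot_max_s * 1.5
    gap, char_gap = 0.3, 0.25

    if cfg.forced_tap_errors is not None:
        k = min(cfg.forced_tap_errors, len(symbols))
        err_idx = set(rng.choice(len(symbols), size=k, replace=False).tolist())
    else:
        err_idx = None

    boundaries = set(spec.char_boundaries())
    presses = []                       # (t_down, duration, pointer_id)
    n_injected = 0
    t = 0.5
    for i, sym in enumerate(symbols):
        if t >= spec.trial_duration_s - 1.0:
            break
        pid = 1 if t < spec.switch_time_s else 2
        dur = dot_d if sym == "." else dash_d
        if err_idx is not None:
            is_err = i in err_idx
        else:
            w = int(t // 10.0)
            is_err = bool(rng.random() < cfg.tap_error_p * cfg.tap_error_decay ** w)
        if is_err:
            dur = dash_d if sym == "." else dot_d
            n_injected += 1
        presses.append((t, dur, pid))
        t += dur + gap
        if (i + 1) in boundaries:
            t += char_gap
        if t < spec.switch_time_s <= t + dash_d + gap:
            t = spec.switch_time_s + 0.5   # pause over the finger switch

    traces = []
    tap_xy = {1: (280.0, 512.0), 2: (420.0, 512.0)}
    for t_down, dur, pid in presses:
        x0, y0 = tap_xy[pid]
        jit = rng.normal(0.0, 2.0, 2)
        traces.append(_trace([t_down, t_down + dur],
                             [x0 + jit[0]] * 2, [y0 + jit[1]] * 2,
                             pointer_id=pid))

    # fixed finger: one long trace per half, pointer opposite the tapper
    circ = spec.target_circle
    half_edges = [(0.0, spec.switch_time_s, 2),
                  (spec.switch_time_s, spec.trial_duration_s, 1)]
    exits_per_half = [cfg.n_target_exits // 2 + cfg.n_target_exits % 2,
                      cfg.n_target_exits // 2]
    for (lo, hi, pid), n_exits in zip(half_edges, exits_per_half):
        tt = np.arange(lo, hi, 0.05)
        n = len(tt)
        walk = np.zeros((n, 2))
        a = math.exp(-0.05 / 1.0)
        sd = circ.r * 0.12
        step = sd * math.sqrt(1 - a * a)
        for i in range(1, n):
            walk[i] = a * walk[i - 1] + rng.normal(0.0, step, 2)
        rad = np.hypot(walk[:, 0], walk[:, 1])
        too_far = rad > 0.55 * circ.r
        walk[too_far] *= (0.55 * circ.r / rad[too_far])[:, None]
        x = circ.cx + walk[:, 0]
        y = circ.cy + walk[:, 1]
        if n_exits > 0 and n > 40:
            slots = np.linspace(0.25, 0.75, n_exits) * n
            for s0 in slots.astype(int):
                seg = slice(s0, min(s0 + 12, n))
                m = len(x[seg])
                # radial excursion: starts/ends at 0.5r (inside), peaks at 1.4r
                rad = circ.r * (0.5 + 0.9 * np.sin(np.linspace(0, math.pi, m)))
                x[seg] = circ.cx + rad
                y[seg] = circ.cy
        x, y = _clip_screen(x, y, device)
        traces.append(_trace(tt, x, y, pointer_id=pid))

    truth = {"n_presses": len(presses), "n_errors": n_injected,
             "n_target_exits": cfg.n_target_exits,
             "tap_error_p": cfg.tap_error_p,
             "tap_error_decay": cfg.tap_error_decay}
    return TrialRecord(
        trial_id=f"message-s{cfg.seed}", game="message", hand=hand,
        traces=traces, task=spec, device=device, age_years=cfg.age_years,
        meta={"truth": truth},
    )


# ---------------------------------------------------------------------------
# bimanual circling


def simulate_bimanual(task: BimanualTaskSpec, cfg: SimConfig,
                      device: DeviceProfile | None = None) -> TrialRecord:
    """Two angular trajectories in the mode's phase/direction relation.

    The right hand carries mean-reverting phase jitter with stationary SD
    ``phase_jitter_deg``; antiphase modes offset it by 180 deg and
    mirrored modes invert its rotation direction.
    """
    device = device or DeviceProfile()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(task.duration_s * cfg.rate_hz)) + 1
    tt = np.linspace(0.0, task.duration_s, n)
    w_l, w_r = cfg.omega_rev_s
    offset = 180.0 if task.antiphase else 0.0

    # each hand jitters independently; the between-hand phase difference
    # then has stationary SD phase_jitter_deg
    dt = tt[1] - tt[0]
    sd_hand = cfg.phase_jitter_deg / math.sqrt(2.0)
    jitter_l = _ou_series(rng, n, sd_hand, dt, 1.0)
    jitter_r = _ou_series(rng, n, sd_hand, dt, 1.0)

    phi0 = -90.0                       # start at the top of the circle
    theta_l = 360.0 * w_l * tt + phi0 + jitter_l
    theta_r = 360.0 * w_r * tt + phi0 + offset + jitter_r
    if task.mirrored:
        theta_r = -theta_r

    def on_circle(theta_deg, circ):
        rad = np.radians(theta_deg)
        r_eff = circ.r + (rng.normal(0.0, cfg.noise_sd_mm / device.mm_per_point, n)
                          if cfg.noise_sd_mm > 0 else 0.0)
        return (circ.cx + r_eff * np.cos(rad), circ.cy + r_eff * np.sin(rad))

    xl, yl = on_circle(theta_l, task.left_circle)
    xr, yr = on_circle(theta_r, task.right_circle)
    xl, yl = _clip_screen(xl, yl, device)
    xr, yr = _clip_screen(xr, yr, device)
    traces = [_trace(tt, xl, yl, pointer_id=0),
              _trace(tt, xr, yr, pointer_id=1)]
    return TrialRecord(
        trial_id=f"round-{task.mode}-s{cfg.seed}", game="round", hand="both",
        traces=traces, task=task, device=device, age_years=cfg.age_years,
        meta={"truth": {"mode": task.mode, "offset_deg": offset,
                        "phase_jitter_deg": cfg.phase_jitter_deg,
                        "omega_rev_s": list(cfg.omega_rev_s)}},
    )


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(spec: CohortSpec, base: SimConfig) -> list[TrialRecord]:
    """Simulate a cohort: ages drawn uniformly, mapped monotonically to skill.

    Each participant plays every configured game once (bimanual
    participants rotate through the four modes); per-participant strategy
    (speed_factor) varies lognormally, tap error probability decreases
    with skill, and antiphase modes get 2.5x the phase jitter.
    """
    rng = np.random.default_rng(base.seed)
    ages = rng.uniform(*spec.age_range_years, spec.n_participants)
    trials: list[TrialRecord] = []
    for pid, age in enumerate(ages):
        skill = spec.skill_for_age(float(age))
        speed = float(np.exp(rng.normal(0.0, 0.25)))
        for gi, game in enumerate(spec.games):
            seed = int((base.seed * 1_000_003 + pid * 101 + gi * 7 + 1)
                       % (2 ** 31 - 1))
            cfg = replace(base, seed=seed, skill=skill, speed_factor=speed,
                          age_years=round(float(age), 1))
            if game == "market":
                trial = simulate_reach(default_task("market"), cfg,
                                       hand="right" if pid % 2 else "left")
            elif game == "race":
                trial = simulate_race(default_task("race"), cfg,
                                      hand="right" if pid % 2 else "left")
            elif game == "filling":
                task = default_task("filling")
                trial = simulate_coloring(task.shapes[pid % len(task.shapes)],
                                          cfg)
            elif game == "message":
                cfg = replace(cfg, tap_error_p=float(
                    np.clip(base.tap_error_p * (1.6 - skill), 0.02, 0.9)))
                trial = simulate_tapping(default_task("message"), cfg)
            elif game == "round":
                mode = BIMANUAL_MODES[pid % len(BIMANUAL_MODES)]
                jit = base.phase_jitter_deg * (2.5 if "antiphase" in mode else 1.0)
                cfg = replace(cfg, phase_jitter_deg=jit / (0.5 + skill))
                trial = simulate_bimanual(default_task("round", mode=mode), cfg)
            else:
                raise ValueError(f"unknown game {game!r}")
            trial.trial_id = f"p{pid:02d}-{trial.trial_id}"
            trials.append(trial)
    return trials
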