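"""Trial record schema, device geometry, readers/writers, validation.

The raw signal of every game is a time-ordered sequence of touch samples
(time, x, y, pointer id, down/move/up event) for one pointer and stroke.
Trials bundle one or more such traces with the task geometry the player
saw and a device profile that converts screen points to physical units.

Two on-disk formats are supported and round-trip losslessly:

* JSON — a top-level list of trial objects (the canonical format, see
  ``schema/trial_schema_v1.json``);
* CSV — long format, one row per sample, with task geometry supplied in a
  separate JSON task file keyed by trial id.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import tasks as _tasks
from .errors import ParseError, SchemaError

EVENTS = ("down", "move", "up")

#: Games whose metrics require actual motion (N >= 2 samples per trace).
MOTION_GAMES = ("market", "race", "filling", "round")


@dataclass(frozen=True)
class TouchSample:
    """One touch event: seconds from trial start, screen points, pointer, type."""

    t: float
    x: float
    y: float
    pointer_id: int = 0
    event: str = "move"


@dataclass
class TouchTrace:
    """Time-ordered samples of a single pointer/stroke, stored as arrays."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: list[str]
    pointer_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.events)):
            raise SchemaError("trace arrays must have equal length")
        if len(self.t) < 1:
            raise SchemaError("trace must contain at least one sample")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def samples(self) -> Iterator[TouchSample]:
        for i in range(self.n):
            yield TouchSample(float(self.t[i]), float(self.x[i]),
                              float(self.y[i]), self.pointer_id, self.events[i])

    @classmethod
    def from_samples(cls, samples: Iterable[TouchSample]) -> "TouchTrace":
        ss = list(samples)
        if not ss:
            raise SchemaError("trace must contain at least one sample")
        pid = ss[0].pointer_id
        return cls(
            t=np.array([s.t for s in ss]),
            x=np.array([s.x for s in ss]),
            y=np.array([s.y for s in ss]),
            events=[s.event for s in ss],
            pointer_id=pid,
        )


@dataclass(frozen=True)
class DeviceProfile:
    """Display geometry: logical point density and screen extent.

    The default matches a 12.9-inch tablet display: 132 logical points per
    inch, 1366 x 1024 points in landscape.  ``meters_per_point`` converts
    on-screen distances to physical distances.
    """

    points_per_inch: float = 132.0
    screen_width_pt: float = 1366.0
    screen_height_pt: float = 1024.0

    def __post_init__(self) -> None:
        if min(self.points_per_inch, self.screen_width_pt, self.screen_height_pt) <= 0:
            raise SchemaError("device profile fields must be strictly positive")

    @property
    def meters_per_point(self) -> float:
        return 0.0254 / self.points_per_inch

    @property
    def mm_per_point(self) -> float:
        return 1000.0 * self.meters_per_point


@dataclass
class TrialRecord:
    """One played trial: traces + task geometry + device + metadata."""

    trial_id: str
    game: str
    hand: str                      # left | right | both
    traces: list[TouchTrace]
    task: object                   # game-specific *TaskSpec from gamekin.tasks
    device: DeviceProfile = field(default_factory=DeviceProfile)
    attempt_index: int = 1
    age_years: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.game not in _tasks.GAMES:
            raise SchemaError(f"trial {self.trial_id}: unknown game {self.game!r}")
        if self.hand not in ("left", "right", "both"):
            raise SchemaError(f"trial {self.trial_id}: unknown hand {self.hand!r}")
        if self.attempt_index < 1:
            raise SchemaError(f"trial {self.trial_id}: attempt_index must be >= 1")
        if not self.traces:
            raise SchemaError(f"trial {self.trial_id}: traces must be nonempty")

    @property
    def duration_s(self) -> float:
        t0 = min(tr.t[0] for tr in self.traces)
        t1 = max(tr.t[-1] for tr in self.traces)
        return float(t1 - t0)

    def pointer_ids(self) -> list[int]:
        return sorted({tr.pointer_id for tr in self.traces})

    def traces_for_pointer(self, pointer_id: int) -> list[TouchTrace]:
        return [tr for tr in self.traces if tr.pointer_id == pointer_id]


@dataclass
class ValidationReport:
    issues: list[tuple[str, str]] = field(default_factory=list)   # (code, message)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append((code, message))

    def codes(self) -> set[str]:
        return {c for c, _ in self.issues}


# ---------------------------------------------------------------------------
# JSON serialization


def trial_to_dict(trial: TrialRecord) -> dict:
    return {
        "trial_id": trial.trial_id,
        "game": trial.game,
        "hand": trial.hand,
        "attempt_index": trial.attempt_index,
        "age_years": trial.age_years,
        "device": {
            "points_per_inch": trial.device.points_per_inch,
            "screen_width_pt": trial.device.screen_width_pt,
            "screen_height_pt": trial.device.screen_height_pt,
        },
        "task": _tasks.task_to_dict(trial.task),
        "traces": [
            {
                "pointer_id": tr.pointer_id,
                "samples": [
                    {"t": float(tr.t[i]), "x": float(tr.x[i]),
                     "y": float(tr.y[i]), "event": tr.events[i]}
                    for i in range(tr.n)
                ],
            }
            for tr in trial.traces
        ],
        "meta": trial.meta,
    }


def trial_from_dict(d: dict) -> TrialRecord:
    try:
        game = str(d["game"])
        dev = d.get("device") or {}
        device = DeviceProfile(
            points_per_inch=float(dev.get("points_per_inch", 132.0)),
            screen_width_pt=float(dev.get("screen_width_pt", 1366.0)),
            screen_height_pt=float(dev.get("screen_height_pt", 1024.0)),
        )
        traces = []
        for j, tr in enumerate(d["traces"]):
            samples = tr["samples"]
            if not samples:
                raise SchemaError(f"traces[{j}].samples: empty trace")
            traces.append(TouchTrace(
                t=np.array([float(s["t"]) for s in samples]),
                x=np.array([float(s["x"]) for s in samples]),
                y=np.array([float(s["y"]) for s in samples]),
                events=[str(s.get("event", "move")) for s in samples],
                pointer_id=int(tr.get("pointer_id", 0)),
            ))
        age = d.get("age_years")
        return TrialRecord(
            trial_id=str(d["trial_id"]),
            game=game,
            hand=str(d.get("hand", "right")),
            attempt_index=int(d.get("attempt_index", 1)),
            age_years=None if age is None else float(age),
            device=device,
            task=_tasks.task_from_dict(game, d["task"]),
            traces=traces,
            meta=dict(d.get("meta") or {}),
        )
    except KeyError as exc:
        raise SchemaError(f"missing required field {exc.args[0]!r} "
                          f"in trial {d.get('trial_id', '?')!r}") from exc


def _normalize_times(trial: TrialRecord) -> TrialRecord:
    """Shift times so the earliest sample of the trial is at t=0."""
    t0 = min(float(tr.t[0]) for tr in trial.traces)
    if t0 != 0.0:
        for tr in trial.traces:
            tr.t = tr.t - t0
    return trial


# ---------------------------------------------------------------------------
# readers / writers


def read_trials(path, format: str | None = None,
                task_file=None) -> list[TrialRecord]:
    """Read trials from a JSON or CSV file.

    ``format`` defaults from the file extension.  CSV files carry no task
    geometry; supply ``task_file`` (JSON mapping trial_id -> task object,
    with optional per-trial ``game``/``device`` keys) or the game's default
    task is attached.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        return _read_trials_json(path)
    if fmt == "csv":
        return _read_trials_csv(path, task_file)
    raise ValueError(f"unknown format {fmt!r}")


def _read_trials_json(path: Path) -> list[TrialRecord]:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: top level must be a list of trials")
    return [_normalize_times(trial_from_dict(d)) for d in payload]


_CSV_HEADER = ["trial_id", "game", "hand", "attempt_index",
               "pointer_id", "t", "x", "y", "event"]


def _read_trials_csv(path: Path, task_file) -> list[TrialRecord]:
    task_map: dict = {}
    if task_file is not None:
        task_map = json.loads(Path(task_file).read_text(encoding="utf-8"))

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = [c for c in _CSV_HEADER if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        rows_by_trial: dict[str, list[dict]] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                rows_by_trial.setdefault(row["trial_id"], []).append({
                    "game": row["game"], "hand": row["hand"],
                    "attempt_index": int(row["attempt_index"]),
                    "pointer_id": int(row["pointer_id"]),
                    "t": float(row["t"]), "x": float(row["x"]),
                    "y": float(row["y"]), "event": row["event"],
                    "age_years": (float(row["age_years"])
                                  if row.get("age_years") else None),
                })
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows_by_trial:
        raise ParseError(f"{path}: no sample rows")

    trials = []
    for trial_id, rows in rows_by_trial.items():
        rows.sort(key=lambda r: (r["pointer_id"], r["t"]))
        game = rows[0]["game"]
        entry = task_map.get(trial_id, task_map.get(game, None))
        if isinstance(entry, dict) and "task" in entry:
            task = _tasks.task_from_dict(entry.get("game", game), entry["task"])
            dev = entry.get("device") or {}
            device = DeviceProfile(
                points_per_inch=float(dev.get("points_per_inch", 132.0)),
                screen_width_pt=float(dev.get("screen_width_pt", 1366.0)),
                screen_height_pt=float(dev.get("screen_height_pt", 1024.0)))
        elif isinstance(entry, dict):
            task = _tasks.task_from_dict(game, entry)
            device = DeviceProfile()
        else:
            task = _tasks.default_task(game)
            device = DeviceProfile()

        traces = []
        for pid in sorted({r["pointer_id"] for r in rows}):
            prows = [r for r in rows if r["pointer_id"] == pid]
            # split into strokes on "down" events
            stroke: list[dict] = []
            for r in prows:
                if r["event"] == "down" and stroke:
                    traces.append(_trace_from_rows(stroke, pid))
                    stroke = []
                stroke.append(r)
            if stroke:
                traces.append(_trace_from_rows(stroke, pid))
        trials.append(_normalize_times(TrialRecord(
            trial_id=trial_id, game=game, hand=rows[0]["hand"],
            attempt_index=rows[0]["attempt_index"],
            age_years=rows[0]["age_years"],
            device=device, task=task, traces=traces)))
    return trials


def _trace_from_rows(rows: list[dict], pid: int) -> TouchTrace:
    return TouchTrace(
        t=np.array([r["t"] for r in rows]),
        x=np.array([r["x"] for r in rows]),
        y=np.array([r["y"] for r in rows]),
        events=[r["event"] for r in rows],
        pointer_id=pid,
    )


def write_trials(trials: list[TrialRecord], path, format: str | None = None,
                 task_file=None) -> None:
    """Write trials to JSON (canonical) or long CSV (+ JSON task sidecar)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = [trial_to_dict(t) for t in trials]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True),
                        encoding="utf-8")
        return
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER + ["age_years"])
        for trial in trials:
            for tr in trial.traces:
                for i in range(tr.n):
                    writer.writerow([
                        trial.trial_id, trial.game, trial.hand,
                        trial.attempt_index, tr.pointer_id,
                        repr(float(tr.t[i])), repr(float(tr.x[i])),
                        repr(float(tr.y[i])), tr.events[i],
                        "" if trial.age_years is None else trial.age_years,
                    ])
    if task_file is not None:
        task_map = {
            t.trial_id: {
                "game": t.game,
                "task": _tasks.task_to_dict(t.task),
                "device": {
                    "points_per_inch": t.device.points_per_inch,
                    "screen_width_pt": t.device.screen_width_pt,
                    "screen_height_pt": t.device.screen_height_pt,
                },
            }
            for t in trials
        }
        Path(task_file).write_text(json.dumps(task_map, indent=1, sort_keys=True),
                                   encoding="utf-8")


# ---------------------------------------------------------------------------
# validation


def validate_trial(trial: TrialRecord) -> ValidationReport:
    """Check a trial for structural and game-specific problems.

    Flags nonmonotonic time, out-of-bounds coordinates, too-short traces for
    motion games, missing task geometry, and incomplete trials (the game's
    goal predicate unmet before its time limit elapsed).
    """
    report = ValidationReport()
    dev = trial.device
    for j, tr in enumerate(trial.traces):
        if np.any(np.diff(tr.t) < 0):
            report.add("nonmonotonic-time",
                       f"trace {j}: sample times decrease")
        if (np.any(tr.x < -1e-6) or np.any(tr.y < -1e-6)
                or np.any(tr.x > dev.screen_width_pt + 1e-6)
                or np.any(tr.y > dev.screen_height_pt + 1e-6)):
            report.add("out-of-bounds-coordinate",
                       f"trace {j}: coordinates outside device bounds")
        if trial.game in MOTION_GAMES and tr.n < 2:
            report.add("short-trace",
                       f"trace {j}: N={tr.n} < 2 for motion game")
    if trial.task is None:
        report.add("missing-task", "trial has no task geometry")
        return report
    _check_complete(trial, report)
    return report


def _check_complete(trial: TrialRecord, report: ValidationReport) -> None:
    game, task = trial.game, trial.task
    dur = trial.duration_s
    if game == "market":
        n_strokes = sum(1 for tr in trial.traces if "up" in tr.events)
        if n_strokes < len(task.items) and dur < task.time_limit_s - 0.5:
            report.add("incomplete-trial",
                       f"{n_strokes}/{len(task.items)} items dragged "
                       f"in {dur:.1f}s")
    elif game == "race":
        end = task.track[-1]
        for j, tr in enumerate(trial.traces):
            d_end = float(np.hypot(tr.x[-1] - end[0], tr.y[-1] - end[1]))
            if (d_end > 2.0 * task.corridor_width_pt
                    and tr.duration_s < task.time_limit_s - 0.5):
                report.add("incomplete-trial",
                           f"trace {j}: ended {d_end:.0f}pt from track end "
                           f"at {tr.duration_s:.1f}s")
    elif game == "filling":
        if dur < task.time_limit_s - 0.5:
            touched = _shapes_touched(trial, task)
            if touched < len(task.shapes):
                report.add("incomplete-trial",
                           f"{touched}/{len(task.shapes)} shapes touched "
                           f"in {dur:.1f}s")
    elif game == "message":
        if dur < task.trial_duration_s - 0.5:
            n_presses = sum(tr.events.count("down") for tr in trial.traces)
            need = len(task.expected_symbols())
            if n_presses < need:
                report.add("incomplete-trial",
                           f"{n_presses}/{need} symbols tapped "
                           f"in {dur:.1f}s")
    elif game == "round":
        if dur < task.duration_s - 0.5:
            report.add("incomplete-trial",
                       f"mode ended at {dur:.1f}s of {task.duration_s:.0f}s")


def _shapes_touched(trial: TrialRecord, task) -> int:
    from shapely import points as shapely_points
    from shapely.prepared import prep

    touched = 0
    for shape in task.shapes:
        geom = prep(shape.to_shapely())
        hit = False
        for tr in trial.traces:
            pts = shapely_points(tr.xy)
            if any(geom.intersects(p) for p in np.atleast_1d(pts)):
                hit = True
                break
        touched += hit
    return touched
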