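"""Per-game task geometry and rules.

Each of the five games carries a task spec describing the geometry the
player interacts with (reach endpoints and crates, the ideal race track,
shapes to color, the Morse message and holding target, the two circles)
plus the game's time limits.  Default layouts matching a 12.9-inch tablet
screen (1366 x 1024 logical points, landscape) are built by the
``default_*`` factories; all geometry is in screen points with the origin
at the top-left corner, x rightward and y downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAMES = ("market", "race", "filling", "message", "round")

BIMANUAL_MODES = (
    "in_phase_congruent",
    "in_phase_mirrored",
    "antiphase_congruent",
    "antiphase_mirrored",
)

#: International (ITU) Morse code for letters and digits.
MORSE_CODE: dict[str, str] = {
    "A": ".-", "B": "-...", "C": "-.-.", "D": "-..", "E": ".",
    "F": "..-.", "G": "--.", "H": "....", "I": "..", "J": ".---",
    "K": "-.-", "L": ".-..", "M": "--", "N": "-.", "O": "---",
    "P": ".--.", "Q": "--.-", "R": ".-.", "S": "...", "T": "-",
    "U": "..-", "V": "...-", "W": ".--", "X": "-..-", "Y": "-.--",
    "Z": "--..",
    "0": "-----", "1": ".----", "2": "..---", "3": "...--", "4": "....-",
    "5": ".....", "6": "-....", "7": "--...", "8": "---..", "9": "----.",
}


@dataclass(frozen=True)
class Circle:
    """A circular target: center (points) and radius (points)."""

    cx: float
    cy: float
    r: float

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "r": self.r}

    @classmethod
    def from_dict(cls, d: dict) -> "Circle":
        return cls(float(d["cx"]), float(d["cy"]), float(d["r"]))


@dataclass(frozen=True)
class MarketItem:
    """One drag-and-drop item: where the fruit starts and the crate it goes in."""

    item_id: str
    start: tuple[float, float]
    box_center: tuple[float, float]
    box_polygon: tuple[tuple[float, float], ...]


@dataclass
class MarketTaskSpec:
    game = "market"
    items: list[MarketItem]
    time_limit_s: float = 60.0


@dataclass
class RaceTaskSpec:
    """Ideal curvilinear track with manually labeled curvature breakpoints."""

    game = "race"
    track: np.ndarray                      # (M, 2) polyline vertices, points
    manual_breakpoints: list[int]          # indices into track, strictly increasing
    corridor_width_pt: float = 40.0
    time_limit_s: float = 30.0

    def __post_init__(self) -> None:
        self.track = np.asarray(self.track, dtype=float)
        bps = list(self.manual_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("manual_breakpoints must be strictly increasing")
        if bps and (bps[0] <= 0 or bps[-1] >= len(self.track) - 1):
            raise ValueError("manual_breakpoints must be interior to the track")

    @property
    def n_ideal_segments(self) -> int:
        return len(self.manual_breakpoints) + 1

    def ideal_subpolylines(self) -> list[np.ndarray]:
        """Split the track at the manual breakpoints (shared junction vertices)."""
        cuts = [0, *self.manual_breakpoints, len(self.track) - 1]
        return [self.track[a:b + 1] for a, b in zip(cuts, cuts[1:])]

    def track_length_pt(self) -> float:
        return float(np.hypot(*np.diff(self.track, axis=0).T).sum())


@dataclass
class ShapeSpec:
    """One shape of the coloring game.

    Circles are stored as center+radius; triangles, stars and generic
    polygons as explicit simple (non-self-intersecting) vertex lists.
    """

    shape_id: str
    kind: str                              # circle | triangle | star | polygon
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: tuple[tuple[float, float], ...] | None = None
    raster_cell_pt: float = 2.0

    def to_shapely(self):
        from shapely.geometry import Point, Polygon

        if self.kind == "circle":
            return Point(*self.center).buffer(self.radius, quad_segs=90)
        return Polygon(self.vertices)


@dataclass
class FillingTaskSpec:
    game = "filling"
    shapes: list[ShapeSpec]
    time_limit_s: float = 120.0
    brush_radius_pt: float = 6.0


@dataclass
class MessageSpec:
    """Morse-tapping task: the hidden message, symbol timing, holding target."""

    game = "message"
    message_text: str
    morse_map: dict[str, str] = field(default_factory=lambda: dict(MORSE_CODE))
    dot_max_s: float = 0.3                 # press duration boundary dot vs dash
    target_circle: Circle = field(default_factory=lambda: Circle(1150.0, 512.0, 70.0))
    switch_time_s: float = 90.0            # tapping/fixed fingers swap here
    trial_duration_s: float = 180.0

    def expected_symbols(self) -> list[str]:
        """Dot/dash stream of the whole message, in tap order."""
        out: list[str] = []
        for ch in self.message_text:
            out.extend(self.morse_map[ch])
        return out

    def char_boundaries(self) -> list[int]:
        """Cumulative symbol count at the end of each message character."""
        n, out = 0, []
        for ch in self.message_text:
            n += len(self.morse_map[ch])
            out.append(n)
        return out


@dataclass
class BimanualTaskSpec:
    game = "round"
    mode: str
    left_circle: Circle = field(default_factory=lambda: Circle(340.0, 512.0, 200.0))
    right_circle: Circle = field(default_factory=lambda: Circle(1026.0, 512.0, 200.0))
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in BIMANUAL_MODES:
            raise ValueError(f"unknown bimanual mode: {self.mode!r}")

    @property
    def antiphase(self) -> bool:
        return self.mode.startswith("antiphase")

    @property
    def mirrored(self) -> bool:
        return self.mode.endswith("mirrored")


# ---------------------------------------------------------------------------
# default layouts


def _regular_polygon(cx, cy, r, n, phase=-90.0):
    ang = np.deg2rad(phase + 360.0 * np.arange(n) / n)
    return tuple((cx + r * math.cos(a), cy + r * math.sin(a)) for a in ang)


def _star_polygon(cx, cy, r_outer, r_inner, n_points=5, phase=-90.0):
    verts = []
    for k in range(2 * n_points):
        r = r_outer if k % 2 == 0 else r_inner
        a = math.radians(phase + 180.0 * k / n_points)
        verts.append((cx + r * math.cos(a), cy + r * math.sin(a)))
    return tuple(verts)


def default_market_task(n_items: int = 4) -> MarketTaskSpec:
    """Fruits along the bottom of the screen, crates along the top."""
    xs = np.linspace(250, 1150, n_items)
    half = 70.0
    items = []
    for i, x in enumerate(xs):
        box = ((x - half, 130.0), (x + half, 130.0),
               (x + half, 270.0), (x - half, 270.0))
        items.append(MarketItem(
            item_id=f"item{i}", start=(float(x), 850.0),
            box_center=(float(x), 200.0), box_polygon=box))
    return MarketTaskSpec(items=items)


#: Slope of each of the 13 track sections (bends = slope changes >= 1.1).
_TRACK_SLOPES = (0.39, -1.04, 0.78, -0.78, 1.30, -0.26, 1.17,
                 -1.17, 0.52, -0.65, 1.43, -0.39, 0.91)


def default_race_task() -> RaceTaskSpec:
    """Winding left-to-right track of 13 sections with distinct headings.

    The road runs across the screen through 12 bends; each bend is a
    labeled curvature breakpoint, and no section ever approaches a
    vertical tangent, so the path derivative dy/dx stays bounded and
    changes distribution exactly at the bends.
    """
    x0, x1 = 100.0, 1266.0
    y_start = 420.0
    dx_leg = (x1 - x0) / len(_TRACK_SLOPES)

    pts: list[tuple[float, float]] = [(x0, y_start)]
    bps: list[int] = []
    x, y = x0, y_start
    for i, slope in enumerate(_TRACK_SLOPES):
        xs = np.linspace(x, x + dx_leg, 12)[1:]
        ys = y + (xs - x) * slope
        pts.extend(zip(map(float, xs), map(float, ys)))
        x, y = float(xs[-1]), float(ys[-1])
        if i < len(_TRACK_SLOPES) - 1:
            bps.append(len(pts) - 1)      # bend vertex
    return RaceTaskSpec(track=np.array(pts), manual_breakpoints=bps)


def default_filling_task() -> FillingTaskSpec:
    """Five shapes mixing curvilinear and rectilinear outlines."""
    shapes = [
        ShapeSpec("circle", "circle", center=(250.0, 300.0), radius=110.0),
        ShapeSpec("triangle", "triangle",
                  vertices=_regular_polygon(600, 300, 125, 3)),
        ShapeSpec("square", "polygon",
                  vertices=((850.0, 200.0), (1050.0, 200.0),
                            (1050.0, 400.0), (850.0, 400.0))),
        ShapeSpec("star", "star",
                  vertices=_star_polygon(400, 720, 130, 52)),
        ShapeSpec("hexagon", "polygon",
                  vertices=_regular_polygon(850, 720, 115, 6)),
    ]
    return FillingTaskSpec(shapes=shapes)


DEFAULT_MESSAGE = "THEQUICKBROWNFOXJUMPSOVERTHELAZYDOG" * 2


def default_message_task(message_text: str = DEFAULT_MESSAGE) -> MessageSpec:
    return MessageSpec(message_text=message_text)


def default_bimanual_task(mode: str = "in_phase_congruent") -> BimanualTaskSpec:
    return BimanualTaskSpec(mode=mode)


def default_task(game: str, mode: str = "in_phase_congruent"):
    if game == "market":
        return default_market_task()
    if game == "race":
        return default_race_task()
    if game == "filling":
        return default_filling_task()
    if game == "message":
        return default_message_task()
    if game == "round":
        return default_bimanual_task(mode)
    raise ValueError(f"unknown game: {game!r}")


# ---------------------------------------------------------------------------
# (de)serialization


def task_to_dict(task) -> dict:
    if isinstance(task, MarketTaskSpec):
        return {
            "items": [
                {"item_id": it.item_id, "start": list(it.start),
                 "box_center": list(it.box_center),
                 "box_polygon": [list(v) for v in it.box_polygon]}
                for it in task.items
            ],
            "time_limit_s": task.time_limit_s,
        }
    if isinstance(task, RaceTaskSpec):
        return {
            "track": task.track.tolist(),
            "manual_breakpoints": list(map(int, task.manual_breakpoints)),
            "corridor_width_pt": task.corridor_width_pt,
            "time_limit_s": task.time_limit_s,
        }
    if isinstance(task, FillingTaskSpec):
        return {
            "shapes": [
                {"shape_id": s.shape_id, "kind": s.kind,
                 "center": list(s.center) if s.center else None,
                 "radius": s.radius,
                 "vertices": [list(v) for v in s.vertices] if s.vertices else None,
                 "raster_cell_pt": s.raster_cell_pt}
                for s in task.shapes
            ],
            "time_limit_s": task.time_limit_s,
            "brush_radius_pt": task.brush_radius_pt,
        }
    if isinstance(task, MessageSpec):
        return {
            "message_text": task.message_text,
            "morse_map": dict(task.morse_map),
            "dot_max_s": task.dot_max_s,
            "target_circle": task.target_circle.to_dict(),
            "switch_time_s": task.switch_time_s,
            "trial_duration_s": task.trial_duration_s,
        }
    if isinstance(task, BimanualTaskSpec):
        return {
            "mode": task.mode,
            "left_circle": task.left_circle.to_dict(),
            "right_circle": task.right_circle.to_dict(),
            "duration_s": task.duration_s,
        }
    raise TypeError(f"unknown task type: {type(task).__name__}")


def task_from_dict(game: str, d: dict):
    if game == "market":
        items = [
            MarketItem(
                item_id=str(it["item_id"]), start=tuple(it["start"]),
                box_center=tuple(it["box_center"]),
                box_polygon=tuple(tuple(v) for v in it["box_polygon"]))
            for it in d["items"]
        ]
        return MarketTaskSpec(items=items,
                              time_limit_s=float(d.get("time_limit_s", 60.0)))
    if game == "race":
        return RaceTaskSpec(
            track=np.asarray(d["track"], dtype=float),
            manual_breakpoints=[int(b) for b in d["manual_breakpoints"]],
            corridor_width_pt=float(d.get("corridor_width_pt", 40.0)),
            time_limit_s=float(d.get("time_limit_s", 30.0)))
    if game == "filling":
        shapes = [
            ShapeSpec(
                shape_id=str(s["shape_id"]), kind=str(s["kind"]),
                center=tuple(s["center"]) if s.get("center") else None,
                radius=float(s["radius"]) if s.get("radius") is not None else None,
                vertices=tuple(tuple(v) for v in s["vertices"]) if s.get("vertices") else None,
                raster_cell_pt=float(s.get("raster_cell_pt", 2.0)))
            for s in d["shapes"]
        ]
        return FillingTaskSpec(
            shapes=shapes, time_limit_s=float(d.get("time_limit_s", 120.0)),
            brush_radius_pt=float(d.get("brush_radius_pt", 6.0)))
    if game == "message":
        return MessageSpec(
            message_text=str(d["message_text"]),
            morse_map=dict(d.get("morse_map", MORSE_CODE)),
            dot_max_s=float(d.get("dot_max_s", 0.3)),
            target_circle=Circle.from_dict(d["target_circle"]),
            switch_time_s=float(d.get("switch_time_s", 90.0)),
            trial_duration_s=float(d.get("trial_duration_s", 180.0)))
    if game == "round":
        return BimanualTaskSpec(
            mode=str(d["mode"]),
            left_circle=Circle.from_dict(d["left_circle"]),
            right_circle=Circle.from_dict(d["right_circle"]),
            duration_s=float(d.get("duration_s", 30.0)))
    raise ValueError(f"unknown game: {game!r}")
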