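"""Traffic scene: car passes, hazard zone and safe-crossing windows.

The scene is a 45 s pedestrian view of a straight road.  Each car is described
only by the azimuth at which it appears in the participant's field of view as a
piecewise-linear function of time; a car "blocks crossing" while its azimuth
lies inside the hazard zone (default ±45° around straight ahead).  Safe
crossing windows are the maximal car-free intervals of the hazard zone, which
for the default schedule are exactly [16, 25] s and [34, 45] s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "CarPass",
    "Scenario",
    "SafeWindow",
    "make_default_scenario",
    "find_safe_windows",
    "COLOUR_PALETTE",
]

#: Non-red colours are drawn from this fixed palette (irrelevant to scoring,
#: fixed for reproducibility).
COLOUR_PALETTE = ("blue", "green", "yellow", "white", "black", "silver", "orange")

SCENE_DURATION = 45.0
HAZARD_ZONE = (-45.0, 45.0)
MIN_GAP = 3.0  # shortest plausible crossing, seconds


@dataclass(frozen=True)
class CarPass:
    """One vehicle passing through the participant's view."""

    car_id: int
    colour: str
    enter_time: float
    exit_time: float
    direction: str  # "left_to_right" | "right_to_left"
    #: piecewise-linear (t, azimuth °) nodes, strictly increasing in t
    track: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.enter_time < self.exit_time):
            raise ValueError("need 0 <= enter_time < exit_time")
        ts = [t for t, _ in self.track]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("track times must be strictly increasing")
        azs = [a for _, a in self.track]
        d = [b - a for a, b in zip(azs, azs[1:])]
        if d and not (all(x >= 0 for x in d) or all(x <= 0 for x in d)):
            raise ValueError("azimuth track must be monotonic for a single pass")

    def azimuth_at(self, t: float) -> float:
        """Linear interpolation of the track; clamped at the ends."""
        pts = self.track
        if t <= pts[0][0]:
            return pts[0][1]
        if t >= pts[-1][0]:
            return pts[-1][1]
        for (t0, a0), (t1, a1) in zip(pts, pts[1:]):
            if t0 <= t <= t1:
                return a0 + (a1 - a0) * (t - t0) / (t1 - t0)
        raise AssertionError("unreachable")

    def hazard_interval(self, zone: tuple[float, float]) -> tuple[float, float] | None:
        """Time interval during which the car's azimuth lies inside ``zone``.

        The track is monotonic, so the occupancy is a single interval (or
        None if the track never enters the zone), clipped to [enter, exit].
        """
        lo, hi = zone
        times: list[float] = []
        for (t0, a0), (t1, a1) in zip(self.track, self.track[1:]):
            amin, amax = min(a0, a1), max(a0, a1)
            if amax < lo or amin > hi:
                continue
            # entry/exit crossing times within this linear segment
            for t, a in ((t0, a0), (t1, a1)):
                if lo <= a <= hi:
                    times.append(t)
            if a1 != a0:
                for bound in (lo, hi):
                    if amin <= bound <= amax:
                        times.append(t0 + (t1 - t0) * (bound - a0) / (a1 - a0))
        if not times:
            return None
        return (min(times), max(times))


@dataclass(frozen=True)
class SafeWindow:
    """A car-free interval of the hazard zone; closed bounds [start, end]."""

    start: float
    end: float
    index: int  # 1-based order

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Scenario:
    scene_duration: float = SCENE_DURATION
    cars: tuple[CarPass, ...] = ()
    hazard_zone: tuple[float, float] = HAZARD_ZONE

    def __post_init__(self) -> None:
        for c in self.cars:
            if c.exit_time > self.scene_duration:
                raise ValueError(f"car {c.car_id} exits after scene end")

    @property
    def n_red(self) -> int:
        return sum(1 for c in self.cars if c.colour == "red")

    # -- JSON round trip (lossless to 6 decimals) ---------------------------

    def to_dict(self) -> dict:
        return {
            "scene_duration": round(self.scene_duration, 6),
            "hazard_zone": [round(self.hazard_zone[0], 6), round(self.hazard_zone[1], 6)],
            "cars": [
                {
                    "car_id": c.car_id,
                    "colour": c.colour,
                    "enter_time": round(c.enter_time, 6),
                    "exit_time": round(c.exit_time, 6),
                    "direction": c.direction,
                    "track": [[round(t, 6), round(a, 6)] for t, a in c.track],
                }
                for c in self.cars
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        cars = tuple(
            CarPass(
                car_id=c["car_id"],
                colour=c["colour"],
                enter_time=c["enter_time"],
                exit_time=c["exit_time"],
                direction=c["direction"],
                track=tuple((t, a) for t, a in c["track"]),
            )
            for c in d["cars"]
        )
        return cls(
            scene_duration=d["scene_duration"],
            cars=cars,
            hazard_zone=tuple(d["hazard_zone"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "Scenario":
        return cls.from_dict(json.loads(s))


def _make_car(car_id: int, colour: str, h_start: float, h_end: float,
              direction: str, zone: tuple[float, float] = HAZARD_ZONE,
              lead_angle: float = 25.0,
              scene_duration: float = SCENE_DURATION) -> CarPass:
    """Car whose hazard-zone dwell is exactly [h_start, h_end].

    The azimuth track is linear at constant angular speed, with exact nodes at
    the hazard boundaries so occupancy endpoints carry no floating-point fuzz,
    extended ``lead_angle`` degrees beyond the zone on each side (clipped to
    the scene).
    """
    lo, hi = zone
    speed = (hi - lo) / (h_end - h_start)  # deg/s
    lead = lead_angle / speed
    enter = max(0.0, h_start - lead)
    exit_ = min(scene_duration, h_end + lead)
    if direction == "left_to_right":
        az_of = lambda t: lo + speed * (t - h_start)  # noqa: E731
    else:
        az_of = lambda t: hi - speed * (t - h_start)  # noqa: E731
    nodes = sorted({enter, h_start, h_end, exit_})
    track = tuple((t, az_of(t)) for t in nodes)
    return CarPass(car_id=car_id, colour=colour, enter_time=enter,
                   exit_time=exit_, direction=direction, track=track)


# Hazard-zone dwell schedule: chained occupancy tiling [0, 16] and [25, 34] so
# the only car-free gaps of the hazard zone are the two crossing windows.
_DEFAULT_DWELLS = (
    (0.0, 2.4), (2.3, 4.7), (4.6, 7.0), (6.9, 9.3),
    (9.2, 11.6), (11.5, 13.9), (13.8, 16.0),
    (25.0, 28.2), (28.0, 31.2), (31.0, 34.0),
)
_RED_CARS = (1, 4, 8)  # 0-based indices: exactly 3 red


def make_default_scenario() -> Scenario:
    """Deterministic default scene: 10 cars, 3 red, windows [16,25] & [34,45]."""
    cars = []
    palette_i = 0
    for i, (h0, h1) in enumerate(_DEFAULT_DWELLS):
        if i in _RED_CARS:
            colour = "red"
        else:
            colour = COLOUR_PALETTE[palette_i % len(COLOUR_PALETTE)]
            palette_i += 1
        direction = "left_to_right" if i % 2 == 0 else "right_to_left"
        cars.append(_make_car(i + 1, colour, h0, h1, direction))
    return Scenario(cars=tuple(cars))


def find_safe_windows(s: Scenario, min_gap: float = MIN_GAP) -> list[SafeWindow]:
    """Maximal car-free intervals of the hazard zone, at least ``min_gap`` long.

    Occupancy endpoints are treated as open when forming windows, so a window
    shares its boundary instant with the adjacent occupancy (closed-interval
    convention: a response exactly at the boundary falls inside the window).
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    occ = sorted(
        iv for c in s.cars
        if (iv := c.hazard_interval(s.hazard_zone)) is not None
    )
    merged: list[list[float]] = []
    for a, b in occ:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    free: list[tuple[float, float]] = []
    cursor = 0.0
    for a, b in merged:
        if a > cursor:
            free.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < s.scene_duration:
        free.append((cursor, s.scene_duration))
    return [
        SafeWindow(start=a, end=b, index=i + 1)
        for i, (a, b) in enumerate((a, b) for a, b in free if b - a >= min_gap)
    ]
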