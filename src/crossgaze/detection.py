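"""Velocity-threshold (I-VT) segmentation of gaze and head traces.

Saccades are maximal runs of samples whose angular gaze velocity exceeds the
threshold (default 50 °/s); runs closer together than ``merge_interval_ms``
are merged, runs shorter than ``min_event_duration`` samples are dropped.
Each event's amplitude is the great-circle angle between the gaze directions
one sample before onset and one sample after offset (the support of the
central-difference velocity), and events split into microsaccades
(amplitude < 1.2°) and macrosaccades (>= 1.2°).  Fixations are the
complementary intervals between consecutive macrosaccades — microsaccades do
not interrupt them.  Head turns are signed yaw-velocity runs with a minimum
net amplitude.

Angular velocity is the central difference of the great-circle angle:
``v[i] = angle(x[i-1], x[i+1]) / (t[i+1] - t[i-1])``.  Note that at 120 Hz
this two-interval support caps the measurable velocity of a displacement A at
A/(2·dt) = 60·A °/s; any additional smoothing lowers the cap to 40·A °/s and
would make every sub-1.2° event invisible to a 50 °/s threshold, which is why
the default ``smoothing_window`` is 1 (the 3-sample centred mean remains
available for lower-noise regimes).

Detection runs on the gaze-in-world signal: the scene-referenced tasks imply
world-referenced gaze, and the synthetic traces are generated in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GazeTrace

__all__ = [
    "DetectorConfig",
    "SaccadeEvent",
    "FixationEvent",
    "HeadTurnEvent",
    "angular_velocity",
    "detect_saccades",
    "classify_saccade",
    "detect_fixations",
    "detect_head_turns",
    "detect_all",
]


@dataclass(frozen=True)
class DetectorConfig:
    velocity_threshold: float = 50.0       # deg/s, the printed saccade cut-off
    amplitude_boundary: float = 1.2        # deg, micro/macro split (>= is macro)
    smoothing_window: int = 1              # samples, centred mean on velocity
    min_event_duration: int = 1            # samples
    merge_interval_ms: float = 20.0        # merge supra-threshold runs closer than this
    head_turn_velocity_threshold: float = 10.0  # deg/s yaw
    head_turn_min_amplitude: float = 5.0   # deg net yaw change

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.amplitude_boundary <= 0:
            raise ValueError("thresholds must be positive")
        if self.merge_interval_ms < 0:
            raise ValueError("merge interval must be non-negative")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be an odd positive sample count")


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float
    offset: float
    amplitude: float       # deg, great-circle onset->offset
    peak_velocity: float   # deg/s
    mean_velocity: float   # deg/s, amplitude / duration
    duration: float        # s
    kind: str              # "micro" | "macro"


@dataclass(frozen=True)
class FixationEvent:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class HeadTurnEvent:
    onset: float
    offset: float
    amplitude: float   # deg, |net yaw change|
    direction: str     # "left" | "right"


def _unit_vectors(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=1
    )


def _great_circle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    dots = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def angular_velocity(trace: "GazeTrace", cfg: DetectorConfig = DetectorConfig()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference angular speed of the gaze direction, deg/s.

    Returns ``(t, v)`` aligned with the gaze samples; the first and last
    samples and any sample whose central-difference support touches an
    invalid sample are NaN.
    """
    t = np.asarray(trace.t_gaze, dtype=float)
    valid = np.asarray(trace.valid, dtype=bool)
    n = t.size
    if n < max(3, cfg.smoothing_window):
        raise ValueError("trace too short")
    u = _unit_vectors(np.asarray(trace.gaze_az, float), np.asarray(trace.gaze_el, float))
    v = np.full(n, np.nan)
    ang = _great_circle_deg(u[:-2], u[2:])
    v[1:-1] = ang / (t[2:] - t[:-2])
    support_ok = valid[:-2] & valid[1:-1] & valid[2:]
    v[1:-1] = np.where(support_ok, v[1:-1], np.nan)
    w = cfg.smoothing_window
    if w > 1:
        kernel = np.ones(w) / w
        sm = np.convolve(v, kernel, mode="same")  # NaN propagates through window
        sm[: w // 2] = np.nan
        sm[-(w // 2):] = np.nan
        v = sm
    return t, v


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (inclusive) of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def classify_saccade(amplitude: float, cfg: DetectorConfig = DetectorConfig()) -> str:
    """"macro" iff amplitude >= boundary (1.2° itself is a macrosaccade)."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    return "macro" if amplitude >= cfg.amplitude_boundary else "micro"


def detect_saccades(trace: "GazeTrace", cfg: DetectorConfig = DetectorConfig()
                    ) -> list[SaccadeEvent]:
    t, v = angular_velocity(trace, cfg)
    valid = np.asarray(trace.valid, dtype=bool)
    u = _unit_vectors(np.asarray(trace.gaze_az, float), np.asarray(trace.gaze_el, float))
    dt_med = float(np.median(np.diff(t)))
    n = t.size

    mask = np.zeros(n, dtype=bool)
    finite = np.isfinite(v)
    mask[finite] = v[finite] > cfg.velocity_threshold

    runs = _runs(mask)
    # merge runs separated by < merge_interval (only across valid samples)
    merged: list[list[int]] = []
    gap_s = cfg.merge_interval_ms / 1000.0
    for a, b in runs:
        if merged:
            pa, pb = merged[-1]
            if (t[a] - t[pb]) < gap_s and valid[pb:a + 1].all():
                merged[-1][1] = b
                continue
        merged.append([a, b])

    events: list[SaccadeEvent] = []
    for a, b in merged:
        if (b - a + 1) < cfg.min_event_duration:
            continue
        ia, ib = max(a - 1, 0), min(b + 1, n - 1)
        if not valid[ia:ib + 1].all():
            continue  # events containing invalid samples are discarded
        amplitude = float(_great_circle_deg(u[ia], u[ib]))
        duration = max(float(t[b] - t[a]), dt_med)
        peak = float(np.nanmax(v[a:b + 1]))
        events.append(
            SaccadeEvent(
                onset=float(t[a]),
                offset=float(t[a]) + duration,
                amplitude=amplitude,
                peak_velocity=peak,
                mean_velocity=amplitude / duration,
                duration=duration,
                kind=classify_saccade(amplitude, cfg),
            )
        )
    return events


def detect_fixations(trace: "GazeTrace",
                     macrosaccades: Sequence[SaccadeEvent]) -> list[FixationEvent]:
    """Complement intervals between consecutive macrosaccades.

    Includes the leading [t0, first onset) and trailing (last offset, T]
    stretches; microsaccades do not interrupt fixations.
    """
    t0 = float(trace.t_gaze[0])
    t1 = float(trace.t_gaze[-1])
    cursor = t0
    out: list[FixationEvent] = []
    prev_end = -np.inf
    for s in macrosaccades:
        if s.kind != "macro":
            raise ValueError("expected macrosaccades only")
        if s.onset < prev_end:
            raise ValueError("macrosaccades must be sorted and non-overlapping")
        prev_end = s.offset
        if s.onset > cursor:
            out.append(FixationEvent(start=cursor, end=s.onset))
        cursor = max(cursor, s.offset)
    if t1 > cursor:
        out.append(FixationEvent(start=cursor, end=t1))
    return out


def detect_head_turns(t: np.ndarray, yaw: np.ndarray,
                      cfg: DetectorConfig = DetectorConfig()) -> list[HeadTurnEvent]:
    """Signed yaw-velocity runs above threshold with net change >= minimum.

    A run keeps a consistent sign; direction "right" for increasing yaw.
    """
    t = np.asarray(t, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("trace too short")
    v = np.full(n, np.nan)
    v[1:-1] = (yaw[2:] - yaw[:-2]) / (t[2:] - t[:-2])
    events: list[HeadTurnEvent] = []
    for sign in (1.0, -1.0):
        mask = np.zeros(n, dtype=bool)
        finite = np.isfinite(v)
        mask[finite] = sign * v[finite] > cfg.head_turn_velocity_threshold
        for a, b in _runs(mask):
            ia, ib = max(a - 1, 0), min(b + 1, n - 1)
            net = yaw[ib] - yaw[ia]
            if abs(net) < cfg.head_turn_min_amplitude:
                continue
            events.append(
                HeadTurnEvent(
                    onset=float(t[a]),
                    offset=float(t[b]),
                    amplitude=float(abs(net)),
                    direction="right" if net > 0 else "left",
                )
            )
    events.sort(key=lambda e: e.onset)
    return events


def detect_all(trace: "GazeTrace", cfg: DetectorConfig = DetectorConfig()
               ) -> tuple[list[SaccadeEvent], list[FixationEvent], list[HeadTurnEvent]]:
    """Run the full detector battery on one trace."""
    saccades = detect_saccades(trace, cfg)
    macros = [s for s in saccades if s.kind == "macro"]
    fixations = detect_fixations(trace, macros)
    head_turns = detect_head_turns(trace.t_head, trace.head_yaw, cfg)
    return saccades, fixations, head_turns
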