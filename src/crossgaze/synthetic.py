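"""Synthetic cohorts, gaze/head traces and verbal responses with ground truth.

Every downstream stage (detection, metrics, scoring, statistics) is exercised
against traces produced here, because the study's participant-level recordings
are not deposited.  The generator emulates:

* a cohort whose per-group age / MoCA / acuity / field medians and ranges
  match the study's demographics table (19 controls, 26 central, 6 peripheral,
  8 combined; two "dual-severe" combined patients with acuity <= 0.1 and field
  radius <= 7° who fail both tasks);
* 120 Hz gaze and 90 Hz head streams over the 45 s scene: slow fixational
  drift (an Ornstein-Uhlenbeck velocity process, RMS ~3 °/s, with weak
  positional mean reversion), Poisson-timed microsaccades (single-interval
  steps just under the 1.2° boundary so they stay resolvable at 120 Hz),
  scene-driven macrosaccades with raised-cosine velocity profiles whose
  duration follows 2.2·A ms + 21 ms (hence a saturating main-sequence peak
  velocity 2A/dur ≈ 909·A/(A+9.55) °/s), and smooth head-yaw ramps;
* AR(1)-correlated tracker noise (sd 0.5°, slowly wandering, as video eye
  trackers produce) added after event synthesis;
* verbal responses placed inside the two car-free windows with group-specific
  delays and truncated-Gaussian jitter, plus a red-car count with a small
  group-dependent miss probability.

All randomness derives from a single integer master seed through documented
``numpy.random.SeedSequence`` keys: stream ``(seed, 0)`` draws the cohort,
``(seed, 1, i, j)`` the trace of participant ``i`` on task ``j`` and
``(seed, 2, i)`` participant ``i``'s responses, so runs are bit-reproducible
and participants are independent.

The injection log records every synthesised event and is the oracle against
which the detector is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from . import clinical
from .scenario import Scenario, find_safe_windows, make_default_scenario

__all__ = [
    "GROUPS",
    "TASKS",
    "Participant",
    "TaskBehaviour",
    "GroupBehaviour",
    "BehaviourParams",
    "GazeTrace",
    "InjectedEvent",
    "InjectionLog",
    "ResponseLog",
    "make_cohort",
    "simulate_trace",
    "simulate_responses",
    "cohort_to_frame",
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_SEED",
]

GROUPS = ("control", "central", "peripheral", "combined")
TASKS = ("safe_crossing", "car_counting")

GAZE_HZ = 120.0
HEAD_HZ = 90.0
#: minimum onset-to-offset separation between injected events of any kind
MIN_EVENT_SEPARATION = 0.08
#: keep this much of the trace clear at both ends so every event has full
#: central-difference support
EDGE_MARGIN = 0.25
#: azimuth range the synthetic gaze/head may occupy (deg)
GAZE_BOUND = 65.0
HEAD_BOUND = 45.0

DEFAULT_COHORT_SIZES = {"control": 19, "central": 26, "peripheral": 6, "combined": 8}
#: master seed pinned for the shipped calibration
DEFAULT_SEED = 20251015


# --------------------------------------------------------------------------
# participants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    age: int
    moca: int
    va_decimal: float
    vf_radius: float
    who_category: str = ""
    dual_severe: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.va_decimal <= 1.25):
            raise ValueError("va_decimal out of (0, 1.25]")
        if not (0 < self.vf_radius <= 90):
            raise ValueError("vf_radius out of (0, 90]")
        if not (0 <= self.moca <= 22):
            raise ValueError("moca out of [0, 22]")


def _median_range(rng: np.random.Generator, lo: float, med: float, hi: float,
                  n: int) -> np.ndarray:
    """Piecewise-uniform draw on [lo, hi] whose population median is ``med``."""
    u = rng.random(n)
    out = np.where(u < 0.5, lo + (med - lo) * 2 * u, med + (hi - med) * (2 * u - 1))
    return out


# demographics: (lo, median, hi) per attribute, mirroring the cohort table
_DEMOGRAPHICS = {
    "control": {"age": (21, 50.0, 86), "moca": (20, 22, 22),
                "va": (0.80, 1.00, 1.20), "vf": (80, 85, 90)},
    "central": {"age": (25, 78.5, 90), "moca": (15, 20, 22),
                "va": (0.05, 0.30, 0.60), "vf": (60, 80, 80)},
    "peripheral": {"age": (27, 55.5, 71), "moca": (20, 21, 21),
                   "va": (0.50, 0.85, 1.00), "vf": (10, 38, 50)},
    "combined": {"age": (32, 56.5, 76), "moca": (17, 20, 22),
                 "va": (0.05, 0.25, 0.30), "vf": (5, 10, 35)},
}
# dual-severe combined patients: acuity and field both at the failure bound
_DUAL_SEVERE = {"va": (0.05, 0.08, 0.10), "vf": (5, 6, 7)}
_GROUP_PREFIX = {"control": "co", "central": "ce", "peripheral": "pe", "combined": "cb"}


def make_cohort(n_per_group: dict[str, int] | None = None,
                seed: int = DEFAULT_SEED) -> list[Participant]:
    """Draw a cohort with group demographics matching the study's table.

    Two of every eight combined-impairment participants (round(n/4)) are made
    "dual severe" (VA <= 0.1 and VF <= 7°), the phenotype that failed both
    tasks in the study.
    """
    sizes = dict(DEFAULT_COHORT_SIZES if n_per_group is None else n_per_group)
    for g, n in sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError("group sizes must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    cohort: list[Participant] = []
    for g in GROUPS:
        n = int(sizes.get(g, 0))
        if n == 0:
            continue
        d = _DEMOGRAPHICS[g]
        age = np.round(_median_range(rng, *d["age"], n)).astype(int)
        moca = np.round(_median_range(rng, *d["moca"], n)).astype(int)
        va = np.round(_median_range(rng, *d["va"], n), 2)
        vf = np.round(_median_range(rng, *d["vf"], n))
        n_severe = (n + 2) // 4 if g == "combined" else 0
        for i in range(n):
            dual = i < n_severe
            if dual:
                va_i = float(np.round(_median_range(rng, *_DUAL_SEVERE["va"], 1)[0], 2))
                vf_i = float(np.round(_median_range(rng, *_DUAL_SEVERE["vf"], 1)[0]))
            else:
                va_i, vf_i = float(va[i]), float(vf[i])
            cohort.append(Participant(
                participant_id=f"{_GROUP_PREFIX[g]}{i + 1:02d}",
                group=g,
                age=int(age[i]),
                moca=int(moca[i]),
                va_decimal=va_i,
                vf_radius=vf_i,
                who_category=clinical.classify_who(va_i, vf_i),
                dual_severe=dual,
            ))
    return cohort


def cohort_to_frame(cohort: list[Participant]) -> pd.DataFrame:
    cols = ["participant_id", "group", "age", "moca", "va_decimal", "vf_radius"]
    df = pd.DataFrame([{c: getattr(p, c) for c in cols} for p in cohort])
    return df


# --------------------------------------------------------------------------
# behaviour parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskBehaviour:
    """Event rates, amplitude scales and response timing for one group x task."""

    macrosaccade_rate: float                 # events/s
    macrosaccade_amplitude_median: float     # deg (log-normal median)
    microsaccade_rate: float                 # events/s
    microsaccade_amplitude_median: float     # deg, < 1.2
    head_turn_rate: float                    # events/s
    head_turn_amplitude_median: float        # deg net yaw
    crossing_delay_median: float             # s after window 1 start
    crossing_delay_median_w2: float          # s after window 2 start
    response_jitter_sd: float = 0.6          # s, truncated Gaussian
    gaze_noise_sd: float = 0.5               # deg, AR(1) tracker noise
    drift_velocity_rms: float = 3.0          # deg/s fixational drift (< 10)
    microsaccade_peak_velocity_scale: float = 120.0   # deg/s per deg amplitude
    macrosaccade_amplitude_sigma: float = 0.45        # log-space sd
    microsaccade_amplitude_sigma: float = 0.05        # log-space sd
    head_turn_amplitude_sigma: float = 0.35           # log-space sd
    #: force event counts to round(rate * duration) instead of Poisson draws
    deterministic_counts: bool = False

    def __post_init__(self) -> None:
        for name in ("macrosaccade_rate", "microsaccade_rate", "head_turn_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.microsaccade_amplitude_median < 1.2):
            raise ValueError("microsaccade amplitude median must be in (0, 1.2)")
        if self.macrosaccade_amplitude_median < 1.2:
            raise ValueError("macrosaccade amplitude median must be >= 1.2")
        if self.gaze_noise_sd < 0 or self.response_jitter_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.microsaccade_peak_velocity_scale <= 0:
            raise ValueError("peak velocity scale must be positive")


@dataclass(frozen=True)
class GroupBehaviour:
    tasks: dict[str, TaskBehaviour]
    red_car_miss_p: float = 0.0


@dataclass(frozen=True)
class BehaviourParams:
    groups: dict[str, GroupBehaviour]
    #: flagged dual-severe participants give no responses and report 0 cars
    dual_severe_failure: bool = True
    version: int = 1

    def task(self, group: str, task: str) -> TaskBehaviour:
        return self.groups[group].tasks[task]

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviourParams":
        groups = {
            g: GroupBehaviour(
                red_car_miss_p=float(gd.get("red_car_miss_p", 0.0)),
                tasks={t: TaskBehaviour(**td) for t, td in gd["tasks"].items()},
            )
            for g, gd in d["groups"].items()
        }
        return cls(groups=groups,
                   dual_severe_failure=bool(d.get("dual_severe_failure", True)),
                   version=int(d.get("version", 1)))

    @classmethod
    def from_yaml(cls, path) -> "BehaviourParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "BehaviourParams":
        """Shipped calibration (versioned YAML packaged with the library)."""
        text = resources.files("crossgaze").joinpath(
            "data/default_behaviour.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

@dataclass
class GazeTrace:
    participant_id: str
    task: str
    t_gaze: np.ndarray
    gaze_az: np.ndarray
    gaze_el: np.ndarray
    valid: np.ndarray
    t_head: np.ndarray
    head_yaw: np.ndarray
    head_pitch: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.t_gaze[-1] - self.t_gaze[0])

    def write_csv(self, gaze_path, head_path, header_comment: str | None = None) -> None:
        gaze = pd.DataFrame({
            "t": np.round(self.t_gaze, 6),
            "gaze_az": np.round(self.gaze_az, 6),
            "gaze_el": np.round(self.gaze_el, 6),
            "valid": self.valid.astype(int),
        })
        head = pd.DataFrame({
            "t": np.round(self.t_head, 6),
            "head_yaw": np.round(self.head_yaw, 6),
            "head_pitch": np.round(self.head_pitch, 6),
        })
        for path, frame in ((gaze_path, gaze), (head_path, head)):
            with open(path, "w") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                frame.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, gaze_path, head_path, participant_id: str = "",
                 task: str = "") -> "GazeTrace":
        gaze = pd.read_csv(gaze_path, comment="#")
        head = pd.read_csv(head_path, comment="#")
        for frame, cols, path in ((gaze, ("t", "gaze_az", "gaze_el", "valid"), gaze_path),
                                  (head, ("t", "head_yaw", "head_pitch"), head_path)):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            participant_id=participant_id, task=task,
            t_gaze=gaze["t"].to_numpy(float),
            gaze_az=gaze["gaze_az"].to_numpy(float),
            gaze_el=gaze["gaze_el"].to_numpy(float),
            valid=gaze["valid"].to_numpy(bool),
            t_head=head["t"].to_numpy(float),
            head_yaw=head["head_yaw"].to_numpy(float),
            head_pitch=head["head_pitch"].to_numpy(float),
        )


@dataclass(frozen=True)
class InjectedEvent:
    kind: str            # "macrosaccade" | "microsaccade" | "head_turn"
    onset: float
    offset: float
    amplitude: float
    peak_velocity: float


@dataclass
class InjectionLog:
    participant_id: str
    task: str
    events: list[InjectedEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[InjectedEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_json(self) -> str:
        return json.dumps({
            "participant_id": self.participant_id,
            "task": self.task,
            "events": [asdict(e) for e in self.events],
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "InjectionLog":
        d = json.loads(s)
        return cls(participant_id=d["participant_id"], task=d["task"],
                   events=[InjectedEvent(**e) for e in d["events"]])


@dataclass
class ResponseLog:
    participant_id: str
    crossing_response_times: list[float]
    red_car_count_reported: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ResponseLog":
        return cls(**json.loads(s))


# --------------------------------------------------------------------------
# trace synthesis
# --------------------------------------------------------------------------

def _rng_from(seed, *key: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _trunc_lognormal(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float, n: int) -> np.ndarray:
    """Log-normal with given median, resampled into [lo, hi]."""
    out = rng.lognormal(np.log(median), sigma, size=n)
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.lognormal(np.log(median), sigma, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _smooth_random_process(rng: np.random.Generator, n: int, dt: float,
                           vel_rms: float, tau_v: float = 0.25,
                           tau_p: float = 1.5) -> np.ndarray:
    """Integrated OU velocity with weak positional leak: slow bounded drift."""
    if vel_rms <= 0:
        return np.zeros(n)
    a = np.exp(-dt / tau_v)
    w = rng.standard_normal(n)
    vel = lfilter([vel_rms * np.sqrt(1 - a * a)], [1.0, -a], w)
    leak = 1.0 - dt / tau_p
    pos = lfilter([dt], [1.0, -leak], vel)
    return pos


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               phi: float = 0.99) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    return lfilter([sd * np.sqrt(1 - phi * phi)], [1.0, -phi], w)


def _schedule_events(rng: np.random.Generator, durations: np.ndarray,
                     duration_total: float, min_sep: float,
                     edge: float) -> tuple[np.ndarray, int]:
    """Random non-overlapping onsets with at least ``min_sep`` between events.

    Returns (onsets, n_used).  If the draw cannot fit, the count is truncated
    to the maximal feasible number (upper Poisson tail only).
    """
    usable = duration_total - 2 * edge
    n = len(durations)
    while n > 0 and durations[:n].sum() + (n + 1) * min_sep > usable:
        n -= 1
    if n == 0:
        return np.empty(0), 0
    free = usable - durations[:n].sum() - (n + 1) * min_sep
    w = rng.random(n + 1)
    gaps = free * w / w.sum()
    onsets = np.empty(n)
    pos = edge
    for i in range(n):
        pos += gaps[i] + min_sep
        onsets[i] = pos
        pos += durations[i]
    return onsets, n


def _raised_cosine_displacement(tau: np.ndarray, dur: float) -> np.ndarray:
    """Fraction of amplitude travelled at time tau into a raised-cosine saccade."""
    x = np.clip(tau / dur, 0.0, 1.0)
    return x - np.sin(2 * np.pi * x) / (2 * np.pi)


def _macro_duration(amplitude: np.ndarray) -> np.ndarray:
    """Duration law 2.2 ms/deg + 21 ms; with a raised-cosine profile the peak
    velocity 2A/dur is a saturating main sequence (~909*A/(A+9.55) deg/s)."""
    return 2.2e-3 * amplitude + 0.021


def simulate_trace(p: Participant, task: str, s: Scenario,
                   params: BehaviourParams, seed,
                   participant_index: int = 0) -> tuple[GazeTrace, InjectionLog]:
    """Synthesise one 45 s viewing: gaze+head streams plus ground-truth log.

    ``seed`` may be the master integer seed (participant/task substreams are
    derived from it) or a ready ``numpy.random.Generator``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    tb = params.task(p.group, task)
    T = s.scene_duration
    rng = _rng_from(seed, 1, participant_index, TASKS.index(task))

    # feasibility of the requested *rates* (expected occupancy)
    exp_n = (tb.macrosaccade_rate + tb.microsaccade_rate) * T
    exp_dur = (tb.macrosaccade_rate * T * _macro_duration(
        np.array([tb.macrosaccade_amplitude_median])).item()
        + tb.microsaccade_rate * T / GAZE_HZ)
    if exp_dur + (exp_n + 1) * MIN_EVENT_SEPARATION > T - 2 * EDGE_MARGIN:
        raise ValueError("requested event rates cannot satisfy the "
                         "non-overlap constraint")

    dt_g = 1.0 / GAZE_HZ
    dt_h = 1.0 / HEAD_HZ
    n_g = int(round(T * GAZE_HZ))
    n_h = int(round(T * HEAD_HZ))
    t_gaze = np.arange(n_g) * dt_g
    t_head = np.arange(n_h) * dt_h

    # ---- saccade schedule (macro + micro interleaved, global 80 ms gaps) --
    if tb.deterministic_counts:
        n_macro = int(round(tb.macrosaccade_rate * T))
        n_micro = int(round(tb.microsaccade_rate * T))
    else:
        n_macro = rng.poisson(tb.macrosaccade_rate * T)
        n_micro = rng.poisson(tb.microsaccade_rate * T)
    amp_macro = _trunc_lognormal(rng, tb.macrosaccade_amplitude_median,
                                 tb.macrosaccade_amplitude_sigma, 2.5, 60.0,
                                 n_macro) if n_macro else np.empty(0)
    # lower bound keeps the sampled central-difference peak A/(2*dt) ~ 60*A
    # comfortably above the 50 deg/s threshold; upper bound leaves headroom
    # below the 1.2 deg boundary for measurement noise
    amp_micro = _trunc_lognormal(rng, tb.microsaccade_amplitude_median,
                                 tb.microsaccade_amplitude_sigma, 0.92, 1.13,
                                 n_micro) if n_micro else np.empty(0)
    kinds = np.array(["macro"] * n_macro + ["micro"] * n_micro)
    amps = np.concatenate([amp_macro, amp_micro])
    order = rng.permutation(len(kinds))
    kinds, amps = kinds[order], amps[order]
    # micros get a two-sample slot so grid-snapping the step (ceil) stays
    # inside it and scheduled separations survive
    durs = np.where(kinds == "macro", _macro_duration(amps), 2 * dt_g)
    onsets, n_used = _schedule_events(rng, durs, T, MIN_EVENT_SEPARATION,
                                      EDGE_MARGIN)
    kinds, amps, durs = kinds[:n_used], amps[:n_used], durs[:n_used]

    az = np.zeros(n_g)
    cur = float(rng.normal(0.0, 2.0))
    az += cur
    events: list[InjectedEvent] = []
    for kind, A, dur, on in zip(kinds, amps, durs, onsets):
        if kind == "micro":
            k = int(np.ceil(on * GAZE_HZ - 1e-9))
            k = min(max(k, 1), n_g - 3)
            direction = rng.choice((-1.0, 1.0))
            if abs(cur + direction * A) > GAZE_BOUND:
                direction = -np.sign(cur)
            az[k + 1:] += direction * A
            cur += direction * A
            events.append(InjectedEvent(
                kind="microsaccade", onset=t_gaze[k], offset=t_gaze[k + 1],
                amplitude=float(A),
                peak_velocity=float(tb.microsaccade_peak_velocity_scale * A)))
        else:
            active = [c for c in s.cars if c.enter_time <= on <= c.exit_time]
            if active:
                car = active[rng.integers(len(active))]
                target = car.azimuth_at(on) + rng.normal(0.0, 3.0)
            else:
                target = rng.uniform(-40.0, 40.0)
            direction = 1.0 if target >= cur else -1.0
            if abs(cur + direction * A) > GAZE_BOUND:
                direction = -np.sign(cur)
            sel = (t_gaze > on) & (t_gaze < on + dur)
            az[sel] += direction * A * _raised_cosine_displacement(
                t_gaze[sel] - on, dur)
            az[t_gaze >= on + dur] += direction * A
            cur += direction * A
            events.append(InjectedEvent(
                kind="macrosaccade", onset=float(on), offset=float(on + dur),
                amplitude=float(A), peak_velocity=float(2 * A / dur)))

    # ---- drift, noise, validity ------------------------------------------
    az += _smooth_random_process(rng, n_g, dt_g, vel_rms=tb.drift_velocity_rms)
    el = _smooth_random_process(rng, n_g, dt_g,
                                vel_rms=2.0 * tb.drift_velocity_rms / 3.0)
    az += _ar1_noise(rng, n_g, tb.gaze_noise_sd)
    el += _ar1_noise(rng, n_g, tb.gaze_noise_sd)
    valid = rng.random(n_g) >= 0.001  # ~99.9% valid samples

    # ---- head stream ------------------------------------------------------
    # head-turn counts are under-dispersed relative to Poisson: scanning is
    # paced by the car schedule, so per-viewing counts cluster tightly around
    # the scene-determined number
    lam_h = tb.head_turn_rate * T
    if lam_h <= 0:
        n_turn = 0
    elif tb.deterministic_counts:
        n_turn = int(round(lam_h))
    else:
        n_turn = max(0, int(round(lam_h + rng.normal(0.0, 0.35 * np.sqrt(lam_h)))))
    amp_turn = _trunc_lognormal(rng, tb.head_turn_amplitude_median,
                                tb.head_turn_amplitude_sigma, 8.0, 60.0,
                                n_turn) if n_turn else np.empty(0)
    vp_turn = rng.uniform(60.0, 110.0, size=len(amp_turn))
    dur_turn = 2.0 * amp_turn / vp_turn
    on_turn, n_t = _schedule_events(rng, dur_turn, T, 2.5 * MIN_EVENT_SEPARATION,
                                    EDGE_MARGIN)
    amp_turn, dur_turn = amp_turn[:n_t], dur_turn[:n_t]

    yaw = np.zeros(n_h)
    yaw_cur = 0.0
    for A, dur, on in zip(amp_turn, dur_turn, on_turn):
        k = int(round(on * GAZE_HZ))
        gaze_here = az[min(k, n_g - 1)]
        if abs(gaze_here) > 20.0:
            direction = 1.0 if gaze_here >= yaw_cur else -1.0
        else:
            direction = rng.choice((-1.0, 1.0))
        if abs(yaw_cur + direction * A) > HEAD_BOUND:
            direction = -np.sign(yaw_cur) if yaw_cur != 0 else direction
        sel = (t_head > on) & (t_head < on + dur)
        yaw[sel] += direction * A * _raised_cosine_displacement(t_head[sel] - on, dur)
        yaw[t_head >= on + dur] += direction * A
        yaw_cur += direction * A
        events.append(InjectedEvent(
            kind="head_turn", onset=float(on), offset=float(on + dur),
            amplitude=float(A), peak_velocity=float(2 * A / dur)))

    yaw += _smooth_random_process(rng, n_h, dt_h, vel_rms=1.2)
    yaw += _ar1_noise(rng, n_h, 0.1, phi=0.95)
    pitch = _smooth_random_process(rng, n_h, dt_h, vel_rms=0.8)
    pitch += _ar1_noise(rng, n_h, 0.1, phi=0.95)

    events.sort(key=lambda e: (e.onset, e.kind))
    trace = GazeTrace(
        participant_id=p.participant_id, task=task,
        t_gaze=t_gaze, gaze_az=az, gaze_el=el, valid=valid,
        t_head=t_head, head_yaw=yaw, head_pitch=pitch,
    )
    log = InjectionLog(participant_id=p.participant_id, task=task, events=events)
    return trace, log


# --------------------------------------------------------------------------
# responses
# --------------------------------------------------------------------------

def simulate_responses(p: Participant, s: Scenario, params: BehaviourParams,
                       seed, participant_index: int = 0) -> ResponseLog:
    """Verbal task output: one crossing response per perceived window and a
    red-car count.  Dual-severe participants (when the failure flag is on)
    produce no responses and report zero cars."""
    rng = _rng_from(seed, 2, participant_index)
    windows = find_safe_windows(s)
    truth = s.n_red
    if p.dual_severe and params.dual_severe_failure:
        return ResponseLog(participant_id=p.participant_id,
                           crossing_response_times=[],
                           red_car_count_reported=0)
    tb = params.task(p.group, "safe_crossing")
    times: list[float] = []
    for w in windows:
        delay = tb.crossing_delay_median if w.index == 1 else tb.crossing_delay_median_w2
        t = w.start + delay + rng.normal(0.0, tb.response_jitter_sd)
        times.append(float(np.clip(t, w.start, w.end)))
    miss_p = params.groups[p.group].red_car_miss_p
    misses = rng.binomial(truth, miss_p) if truth > 0 else 0
    return ResponseLog(participant_id=p.participant_id,
                       crossing_response_times=times,
                       red_car_count_reported=int(truth - misses))
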