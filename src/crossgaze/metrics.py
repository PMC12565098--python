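"""Per-viewing aggregation of detected events into the summary statistics
compared across groups (counts, total/average amplitudes, velocities,
durations).  Averages over zero events are reported as missing (NaN), not
zero, so they drop out of median-based group statistics pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd

from .detection import FixationEvent, HeadTurnEvent, SaccadeEvent

__all__ = ["TrialSummary", "summarize_trial", "summaries_to_frame", "SUMMARY_METRICS"]

SUMMARY_METRICS = (
    "n_macrosaccades", "n_microsaccades", "n_fixations", "n_head_turns",
    "total_macrosaccade_amplitude", "total_microsaccade_duration",
    "avg_fixation_duration", "avg_macrosaccade_velocity",
    "avg_microsaccade_velocity", "avg_macrosaccade_amplitude",
)


@dataclass(frozen=True)
class TrialSummary:
    participant_id: str
    task: str
    n_macrosaccades: int
    n_microsaccades: int
    n_fixations: int
    n_head_turns: int
    total_macrosaccade_amplitude: float
    total_microsaccade_duration: float
    avg_fixation_duration: float
    avg_macrosaccade_velocity: float
    avg_microsaccade_velocity: float
    avg_macrosaccade_amplitude: float


def _check_sorted(events: Sequence, label: str) -> None:
    prev_end = -math.inf
    for e in events:
        onset = getattr(e, "onset", getattr(e, "start", None))
        offset = getattr(e, "offset", getattr(e, "end", None))
        if onset < prev_end - 1e-9:
            raise ValueError(f"{label} events overlap or are unsorted")
        prev_end = offset


def _mean(xs: list[float]) -> float:
    return sum(xs) / len(xs) if xs else math.nan


def summarize_trial(saccades: Sequence[SaccadeEvent],
                    fixations: Sequence[FixationEvent],
                    head_turns: Sequence[HeadTurnEvent],
                    participant_id: str, task: str,
                    include_boundary_fixations: bool = True) -> TrialSummary:
    """Aggregate one viewing's detected events.

    ``include_boundary_fixations=False`` drops the leading/trailing intervals
    from the fixation-duration average (the count keeps them).
    """
    _check_sorted(saccades, "saccade")
    _check_sorted(fixations, "fixation")
    _check_sorted(head_turns, "head turn")
    macros = [s for s in saccades if s.kind == "macro"]
    micros = [s for s in saccades if s.kind == "micro"]
    fix_for_avg = list(fixations)
    if not include_boundary_fixations and len(fix_for_avg) >= 2:
        fix_for_avg = fix_for_avg[1:-1]
    return TrialSummary(
        participant_id=participant_id,
        task=task,
        n_macrosaccades=len(macros),
        n_microsaccades=len(micros),
        n_fixations=len(fixations),
        n_head_turns=len(head_turns),
        total_macrosaccade_amplitude=sum(s.amplitude for s in macros),
        total_microsaccade_duration=sum(s.duration for s in micros),
        avg_fixation_duration=_mean([f.duration for f in fix_for_avg]),
        avg_macrosaccade_velocity=_mean([s.mean_velocity for s in macros]),
        avg_microsaccade_velocity=_mean([s.mean_velocity for s in micros]),
        avg_macrosaccade_amplitude=_mean([s.amplitude for s in macros]),
    )


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """One row per participant x task; the statistics module's input contract."""
    return pd.DataFrame([asdict(s) for s in summaries])
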