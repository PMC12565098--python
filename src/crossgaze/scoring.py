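"""Scoring of the two behavioural tasks.

Safe crossing: each verbal response is assigned to the safe window containing
it (closed bounds, so a response exactly on a boundary counts as inside); the
earliest response per window is that window's crossing time (CT1, CT2).
Responses outside every window are ignored but reported back for inspection.

Car counting: the report is correct iff it equals the number of red cars the
scenario actually contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .scenario import SafeWindow, Scenario
from .synthetic import ResponseLog

__all__ = ["CrossingScore", "CarCountScore", "score_crossing", "score_cars"]


@dataclass(frozen=True)
class CrossingScore:
    n_identified: int
    ct1: float  # NaN when window 1 was not identified
    ct2: float
    ignored_responses: tuple[float, ...] = ()


@dataclass(frozen=True)
class CarCountScore:
    reported: int
    truth: int
    correct: bool


def score_crossing(responses: ResponseLog | Sequence[float],
                   windows: Sequence[SafeWindow]) -> CrossingScore:
    times = (responses.crossing_response_times
             if isinstance(responses, ResponseLog) else list(responses))
    ct: dict[int, float] = {}
    ignored: list[float] = []
    for t in times:
        for w in windows:
            if w.contains(t):
                ct[w.index] = min(ct.get(w.index, math.inf), t)
                break
        else:
            ignored.append(t)
    return CrossingScore(
        n_identified=len(ct),
        ct1=ct.get(1, math.nan),
        ct2=ct.get(2, math.nan),
        ignored_responses=tuple(ignored),
    )


def score_cars(reported: int, s: Scenario) -> CarCountScore:
    if reported < 0:
        raise ValueError("reported count must be >= 0")
    truth = s.n_red
    return CarCountScore(reported=reported, truth=truth,
                         correct=(reported == truth))
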