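"""Visual-search outcome measures.

The task presents a target picture among 4, 9 or 19 distracters (10 trials
each), bracketed by two simple reaction-time blocks (5 trials each) in which
the target pops out, so their reaction time is taken as the motor response
time. Under a serial-search model the search-task reaction time is motor time
plus scan time, so the primary outcome per condition is

    search_time = median(search RTs) - median(pooled reaction-task RTs)

False-alarm trials (the child touched a wrong picture) are excluded from all
medians; their count over the three search conditions is the error outcome.
The two reaction-time blocks are pooled into one median (robust to the small
per-block trial counts). Negative search times can arise with noisy data and
are deliberately not clamped — clamping would bias group medians.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

from .errors import ValidationError

__all__ = [
    "CONDITIONS",
    "SEARCH_CONDITIONS",
    "RT_CONDITIONS",
    "MEASURE_BY_CONDITION",
    "SearchTrial",
    "SearchOutcome",
    "search_outcome",
    "classify_search",
]

RT_CONDITIONS = ("RT_pre", "RT_post")
SEARCH_CONDITIONS = ("D4", "D9", "D19")
CONDITIONS = RT_CONDITIONS[:1] + SEARCH_CONDITIONS + RT_CONDITIONS[1:]

#: Norm-table measure name per search condition (named by total item count).
MEASURE_BY_CONDITION = {"D4": "search_time_5", "D9": "search_time_10", "D19": "search_time_20"}


@dataclass(frozen=True)
class SearchTrial:
    """One trial: condition, reaction time (s), and the false-alarm flag."""

    condition: str
    rt: float
    false_alarm: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}; expected {CONDITIONS}")
        if not self.rt > 0:
            raise ValidationError(f"reaction time must be positive, got {self.rt}")


@dataclass(frozen=True)
class SearchOutcome:
    """Per-patient search outcomes; a measure is ``None`` when not computable."""

    search_time_5: Optional[float]
    search_time_10: Optional[float]
    search_time_20: Optional[float]
    response_time: Optional[float]
    total_errors: int

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "search_time_5": self.search_time_5,
            "search_time_10": self.search_time_10,
            "search_time_20": self.search_time_20,
            "response_time": self.response_time,
            "total_errors": float(self.total_errors),
        }


def _median(values) -> Optional[float]:
    return float(statistics.median(values)) if values else None


def search_outcome(trials: Iterable[SearchTrial]) -> SearchOutcome:
    """Compute medians, motor-time subtraction and the error count."""
    trials = list(trials)
    if not trials:
        raise ValidationError("search_outcome requires at least one trial")
    valid: Dict[str, list] = {c: [] for c in CONDITIONS}
    total_errors = 0
    for t in trials:
        if t.false_alarm:
            if t.condition in SEARCH_CONDITIONS:
                total_errors += 1
            continue
        valid[t.condition].append(t.rt)

    response_time = _median(valid["RT_pre"] + valid["RT_post"])
    times = {}
    for cond, measure in MEASURE_BY_CONDITION.items():
        med = _median(valid[cond])
        times[measure] = (med - response_time) if (med is not None and response_time is not None) else None
    return SearchOutcome(
        search_time_5=times["search_time_5"],
        search_time_10=times["search_time_10"],
        search_time_20=times["search_time_20"],
        response_time=response_time,
        total_errors=total_errors,
    )


def classify_search(outcome: SearchOutcome, norms, entry_age: float) -> Mapping[str, Optional[bool]]:
    """Flag each outcome measure against its 10th-percentile norm.

    A flag is ``True`` when the measure is strictly on the worse side of the
    cutoff (longer time, more errors), ``None`` when the measure is missing.
    """
    flags: Dict[str, Optional[bool]] = {}
    for measure, value in outcome.as_dict().items():
        flags[measure] = None if value is None else norms.classify(value, measure, entry_age)
    return flags
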