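"""Adaptive staircases and scoring for the three motion-perception tasks.

Global motion (GM) and motion speed (MS) thresholds are measured with a
transformed up/down staircase: two consecutive correct responses make the
next trial harder, each error makes it easier. Such a 2-consecutive-correct /
1-incorrect rule converges on the stimulus level where P(correct) =
sqrt(1/2) ~ 0.707. The run stops at the 8th reversal (a trial where the step
direction changes) and the threshold is the arithmetic mean of the last 4
reversal levels.

Steps are multiplicative by default: one step harder multiplies the level by
``(1 - s)``, one step easier divides by it, with the scaling factor ``s``
optionally switching to a finer late value once a configured reversal count
is reached (the motion-speed task uses 0.33 then 0.25 from the fifth
reversal). Multiplicative steps suit both coherence (bounded in (0, 1]) and
speed differences, which span large dynamic ranges; an additive mode is
available for level scales where that is more natural.

Motion-defined form (MDF) is not adaptive: each object is shown in up to
three conditions of decreasing difficulty and scores 1, 0.5 or 0 for
recognition in condition 1, 2 or 3. Failure in the final condition makes the
item inconclusive and it is excluded from the proportion-correct score, the
same logic as the L94 control conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import NotEvaluableError, ValidationError

__all__ = [
    "StaircaseConfig",
    "Staircase",
    "ThresholdResult",
    "staircase_threshold",
    "replay_staircase",
    "run_staircase",
    "mdf_score",
    "GM_CONFIG",
    "MS_CONFIG",
]

HARDER = "harder"
EASIER = "easier"


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive track.

    ``n_correct_to_harder`` / ``n_incorrect_to_easier`` encode the up/down
    rule; (2, 1) is the transformed rule converging at 70.7% correct, (1, 2)
    is the opposite reading of the same name. Consecutive-response counters
    reset after every step. ``late_scaling_factor`` (if set) replaces
    ``scaling_factor`` for every step taken once ``late_from_reversal``
    reversals have been logged.
    """

    start_level: float
    scaling_factor: float = 0.33
    late_scaling_factor: Optional[float] = None
    late_from_reversal: int = 5
    n_reversals_stop: int = 8
    n_reversals_average: int = 4
    n_correct_to_harder: int = 2
    n_incorrect_to_easier: int = 1
    level_bounds: Tuple[float, float] = (1e-9, math.inf)
    step_mode: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        for name, s in (("scaling_factor", self.scaling_factor),
                        ("late_scaling_factor", self.late_scaling_factor)):
            if s is not None and not (0.0 < s < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {s}")
        if self.n_reversals_average > self.n_reversals_stop:
            raise ValidationError("n_reversals_average must not exceed n_reversals_stop")
        lo, hi = self.level_bounds
        if not (lo < hi):
            raise ValidationError(f"invalid level bounds {self.level_bounds}")
        if self.step_mode == "multiplicative" and lo <= 0:
            raise ValidationError("multiplicative steps require a positive lower bound")
        if self.step_mode not in ("multiplicative", "additive"):
            raise ValidationError(f"unknown step_mode {self.step_mode!r}")
        if not (lo <= self.start_level <= hi):
            raise ValidationError(f"start_level {self.start_level} outside bounds {self.level_bounds}")
        if self.n_correct_to_harder < 1 or self.n_incorrect_to_easier < 1:
            raise ValidationError("up/down counts must be >= 1")


#: Global motion: coherence starts fully coherent; harder = lower coherence.
GM_CONFIG = StaircaseConfig(start_level=1.0, scaling_factor=0.33, level_bounds=(1e-9, 1.0))

#: Motion speed: speed difference in deg/s; finer steps from the 5th reversal.
MS_CONFIG = StaircaseConfig(
    start_level=17.0, scaling_factor=0.33, late_scaling_factor=0.25, late_from_reversal=5
)


class Staircase:
    """Mutable state of one adaptive track (the trace).

    Levels, trial outcomes and reversal bookkeeping are fully determined by
    the config and the response sequence, so a recorded run can be replayed
    bit-exactly with :func:`replay_staircase`.
    """

    def __init__(self, cfg: StaircaseConfig):
        self.cfg = cfg
        self.level: float = cfg.start_level
        self.trials: List[Tuple[float, bool]] = []
        self.reversals: List[Tuple[int, float]] = []  # (trial index, level)
        self.terminated: bool = False
        self._n_correct = 0
        self._n_incorrect = 0
        self._last_dir: Optional[str] = None

    @property
    def reversal_levels(self) -> List[float]:
        return [lvl for _, lvl in self.reversals]

    def step(self, correct: bool) -> "Staircase":
        """Record one response at the current level and update the track."""
        if self.terminated:
            raise ValidationError("staircase already terminated at "
                                  f"{len(self.reversals)} reversals")
        self.trials.append((self.level, bool(correct)))
        if correct:
            self._n_correct += 1
            self._n_incorrect = 0
            if self._n_correct >= self.cfg.n_correct_to_harder:
                self._move(HARDER)
        else:
            self._n_incorrect += 1
            self._n_correct = 0
            if self._n_incorrect >= self.cfg.n_incorrect_to_easier:
                self._move(EASIER)
        return self

    def _move(self, direction: str) -> None:
        self._n_correct = 0
        self._n_incorrect = 0
        if self._last_dir is not None and direction != self._last_dir:
            self.reversals.append((len(self.trials) - 1, self.level))
        self._last_dir = direction
        if len(self.reversals) >= self.cfg.n_reversals_stop:
            self.terminated = True
            return
        s = self.cfg.scaling_factor
        if (self.cfg.late_scaling_factor is not None
                and len(self.reversals) >= self.cfg.late_from_reversal):
            s = self.cfg.late_scaling_factor
        if self.cfg.step_mode == "multiplicative":
            new = self.level * (1.0 - s) if direction == HARDER else self.level / (1.0 - s)
        else:
            new = self.level - s if direction == HARDER else self.level + s
        lo, hi = self.cfg.level_bounds
        self.level = min(max(new, lo), hi)


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold extracted from a terminated staircase trace."""

    task: str
    value: float
    n_trials: int
    reversal_levels: Tuple[float, ...] = field(default=(), repr=False)


def staircase_threshold(stair: Staircase, task: str = "") -> ThresholdResult:
    """Mean of the last ``n_reversals_average`` reversal levels."""
    cfg = stair.cfg
    if not stair.terminated or len(stair.reversals) < cfg.n_reversals_stop:
        raise NotEvaluableError(
            f"staircase not terminated: {len(stair.reversals)} of "
            f"{cfg.n_reversals_stop} reversals reached"
        )
    tail = stair.reversal_levels[-cfg.n_reversals_average:]
    return ThresholdResult(
        task=task,
        value=sum(tail) / len(tail),
        n_trials=len(stair.trials),
        reversal_levels=tuple(stair.reversal_levels),
    )


def replay_staircase(cfg: StaircaseConfig, responses: Iterable[bool]) -> Staircase:
    """Rebuild a trace from a recorded response sequence.

    Stops early if the track terminates; raises if responses continue past
    termination would be needed (extra responses are ignored).
    """
    stair = Staircase(cfg)
    for correct in responses:
        if stair.terminated:
            break
        stair.step(correct)
    return stair


def run_staircase(
    cfg: StaircaseConfig,
    responder: Callable[[float], bool],
    max_trials: int = 10_000,
) -> Staircase:
    """Drive a staircase with a responder ``level -> correct`` until it terminates."""
    stair = Staircase(cfg)
    for _ in range(max_trials):
        if stair.terminated:
            return stair
        stair.step(responder(stair.level))
    if not stair.terminated:
        raise NotEvaluableError(
            f"staircase did not terminate within {max_trials} trials "
            f"({len(stair.reversals)} reversals)"
        )
    return stair


_MDF_SCORES = {1: 1.0, 2: 0.5, 3: 0.0}


def mdf_score(conditions: Sequence[Union[int, None, str]]) -> Tuple[Optional[float], int, int]:
    """Motion-defined-form proportion correct.

    ``conditions`` holds, per object, the condition (1, 2 or 3) at which it
    was recognised, or ``None``/``"never"`` if it was not recognised in the
    final condition (inconclusive, excluded). Returns
    ``(score, n_conclusive, n_inconclusive)``; score is ``None`` when no
    conclusive item remains.
    """
    if len(conditions) == 0:
        raise ValidationError("mdf_score requires at least one item")
    scores = []
    n_inconclusive = 0
    for c in conditions:
        if c is None or (isinstance(c, str) and c.lower() == "never"):
            n_inconclusive += 1
            continue
        if c not in _MDF_SCORES:
            raise ValidationError(f"MDF condition must be 1, 2, 3 or 'never', got {c!r}")
        scores.append(_MDF_SCORES[c])
    if not scores:
        return None, 0, n_inconclusive
    return sum(scores) / len(scores), len(scores), n_inconclusive


def with_start_level(cfg: StaircaseConfig, start_level: float) -> StaircaseConfig:
    """Convenience: a copy of ``cfg`` with a different starting level."""
    return replace(cfg, start_level=start_level)
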