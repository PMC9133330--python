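"""Item and subtask scoring for the L94 object-recognition battery.

The L94 probes recognition of line drawings under suboptimal viewing
conditions with five subtasks:

* ``VISM`` — visual matching of prototypical drawings (binary items),
* ``NOISE`` — drawings occluded by noise, 7 noise levels per item,
* ``OVERL`` — overlapping drawings, 4 overlap levels per item,
* ``VIEW`` — unconventional views, 3 or 4 view levels per item,
* ``DEVOS`` — De Vos drawings with a target and a control condition (binary).

Graded items are scored ``(k - j) / (k - 1)`` where ``k`` is the number of
conditions and ``j`` the 1-based index of the first condition at which the
object was recognised; recognition only at the final (control) condition
scores 0 and failure at the control condition makes the item *inconclusive* —
the failure may reflect naming or language rather than perception, so the
item is dropped from the subtask mean entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .errors import ValidationError

__all__ = [
    "SUBTASKS",
    "BINARY_SUBTASKS",
    "ItemResponse",
    "SubtaskScore",
    "item_score",
    "subtask_score",
    "l94_evaluable",
]

SUBTASKS = ("VISM", "NOISE", "OVERL", "VIEW", "DEVOS")
BINARY_SUBTASKS = frozenset({"VISM", "DEVOS"})

#: Allowed condition counts per subtask (binary subtasks have a single
#: target condition; VIEW mixes 3- and 4-condition items).
_K_ALLOWED = {
    "VISM": frozenset({1}),
    "DEVOS": frozenset({1}),
    "NOISE": frozenset({7}),
    "OVERL": frozenset({4}),
    "VIEW": frozenset({3, 4}),
}

#: VIEW items named by category rather than object by typically developing
#: controls; excluded from scoring by default (overridable).
DEFAULT_VIEW_EXCLUSIONS = ("rifle", "bench", "alarm clock")

INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ItemResponse:
    """One L94 item outcome.

    ``j`` is the 1-based index of the condition at which the object was
    recognised, or ``None`` if it was never recognised before the control
    condition ("never"). ``control_recognized`` records the outcome of the
    control condition (always True for VISM, which has no control).
    """

    subtask: str
    j: Optional[int]
    k: int
    control_recognized: bool = True
    item_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subtask not in SUBTASKS:
            raise ValidationError(f"unknown subtask {self.subtask!r}; expected one of {SUBTASKS}")
        if self.k not in _K_ALLOWED[self.subtask]:
            raise ValidationError(
                f"{self.subtask} items have k in {sorted(_K_ALLOWED[self.subtask])}, got k={self.k}"
            )
        if self.j is not None and not (1 <= self.j <= self.k):
            raise ValidationError(f"j must satisfy 1 <= j <= k={self.k}, got j={self.j}")


def item_score(r: ItemResponse) -> Union[float, str]:
    """Score one item in [0, 1], or return :data:`INCONCLUSIVE`.

    Binary subtasks score 1 if the target was recognised, 0 otherwise.
    Graded subtasks score ``(k - j) / (k - 1)``: 1 at the hardest condition,
    0 when recognition only occurred at the control (j = k). An item whose
    control condition was failed is inconclusive regardless of ``j``.
    """
    if not r.control_recognized:
        return INCONCLUSIVE
    if r.subtask in BINARY_SUBTASKS:
        return 1.0 if r.j == 1 else 0.0
    if r.j is None:
        # The control is the last graded condition: recognising it would have
        # set j = k, so "never recognised" contradicts a passed control.
        raise ValidationError(
            f"{r.subtask} item marked never-recognised but control condition passed"
        )
    return (r.k - r.j) / (r.k - 1)


@dataclass(frozen=True)
class SubtaskScore:
    """Average conclusive item score for one subtask.

    ``score`` is ``None`` when every administered item was inconclusive, in
    which case the subtask is not evaluable.
    """

    subtask: str
    score: Optional[float]
    n_conclusive: int
    n_inconclusive: int

    @property
    def evaluable(self) -> bool:
        return self.score is not None


def subtask_score(items: Iterable[ItemResponse]) -> SubtaskScore:
    """Average the conclusive item scores of one subtask."""
    items = list(items)
    if not items:
        raise ValidationError("subtask_score requires at least one item")
    subtasks = {r.subtask for r in items}
    if len(subtasks) != 1:
        raise ValidationError(f"items from multiple subtasks: {sorted(subtasks)}")
    (name,) = subtasks
    scores = [item_score(r) for r in items]
    conclusive = [s for s in scores if s is not INCONCLUSIVE]
    n_inc = len(scores) - len(conclusive)
    mean = sum(conclusive) / len(conclusive) if conclusive else None
    return SubtaskScore(subtask=name, score=mean, n_conclusive=len(conclusive), n_inconclusive=n_inc)


def l94_evaluable(evaluability: Mapping[str, bool], min_subtasks: int = 3) -> bool:
    """Whether a patient enters the analysis: at least 3 of 5 subtasks evaluable."""
    unknown = set(evaluability) - set(SUBTASKS)
    if unknown:
        raise ValidationError(f"unknown subtasks {sorted(unknown)}")
    return sum(bool(v) for v in evaluability.values()) >= min_subtasks
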