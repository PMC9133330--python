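"""Age-referenced percentile classification and patient-level roll-up.

Each task score is compared with the cutoff of the norm band containing the
patient's entry age (developmental age, or chronological age when capped —
see :mod:`dorsalkit.ages`). An entry age outside every band falls back to the
nearest band, ties going to the younger band. A score is flagged only when
it lies strictly on the worse side of the cutoff: "below the percentile"
means a tie at the cutoff is not flagged.

Two flag severities are in play: object-recognition scores are *abnormal*
below the 5th percentile (z < -1.645), while the other dorsal functions use
a *weak* threshold at the 10th percentile (z < -1.282). A dorsal function
(motion, attention, visuomotor) is weak when at least one of its tasks is
flagged, and a patient has a *general* dorsal-stream dysfunction when at
least two of the three non-object-recognition functions are weak.

The norm tables for the motion and search tasks ship as packaged data
(:func:`default_norms`); object-recognition norms are proprietary test
material and must be supplied by the user or derived from a synthetic
reference cohort's empirical percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence, Tuple

import yaml

from .errors import ValidationError

__all__ = [
    "NormBand",
    "NormEntry",
    "NormTable",
    "default_norms",
    "classify_score",
    "ClassificationPolicy",
    "default_policy",
    "PatientClassification",
    "rollup",
]

#: Standard-normal cutoffs equivalent to the two percentile criteria.
Z_5TH = -1.645
Z_10TH = -1.282


@dataclass(frozen=True)
class NormBand:
    lo: float  # months, inclusive
    hi: float  # months, inclusive
    cutoff: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError(f"band lower bound {self.lo} exceeds upper {self.hi}")

    def distance(self, age: float) -> float:
        if age < self.lo:
            return self.lo - age
        if age > self.hi:
            return age - self.hi
        return 0.0


@dataclass(frozen=True)
class NormEntry:
    measure: str
    percentile: int
    worse: str  # "higher" | "lower"
    bands: Tuple[NormBand, ...]

    def __post_init__(self) -> None:
        if self.worse not in ("higher", "lower"):
            raise ValidationError(f"worse must be 'higher' or 'lower', got {self.worse!r}")
        if self.percentile not in (5, 10):
            raise ValidationError(f"percentile must be 5 or 10, got {self.percentile}")
        if not self.bands:
            raise ValidationError(f"measure {self.measure!r} has no norm bands")
        ordered = sorted(self.bands, key=lambda b: b.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo <= a.hi:
                raise ValidationError(f"overlapping norm bands for {self.measure!r}")

    def band_for(self, age: float) -> NormBand:
        """Band containing ``age``, else the nearest band (ties to younger)."""
        return min(self.bands, key=lambda b: (b.distance(age), b.lo))


class NormTable:
    """Collection of per-measure norm entries with YAML round-trip."""

    def __init__(self, entries: Mapping[str, NormEntry]):
        self.entries: Dict[str, NormEntry] = dict(entries)

    def __contains__(self, measure: str) -> bool:
        return measure in self.entries

    def cutoff(self, measure: str, age: float) -> float:
        return self._entry(measure).band_for(age).cutoff

    def classify(self, value: float, measure: str, entry_age: float) -> bool:
        """True iff ``value`` is strictly on the worse side of the age cutoff."""
        entry = self._entry(measure)
        cutoff = entry.band_for(entry_age).cutoff
        return value > cutoff if entry.worse == "higher" else value < cutoff

    def _entry(self, measure: str) -> NormEntry:
        try:
            return self.entries[measure]
        except KeyError:
            raise ValidationError(
                f"measure {measure!r} not in norm table; known: {sorted(self.entries)}"
            ) from None

    def merged(self, other: "NormTable") -> "NormTable":
        merged = dict(self.entries)
        merged.update(other.entries)
        return NormTable(merged)

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "NormTable":
        entries = {}
        for name, spec in data["measures"].items():
            bands = tuple(NormBand(float(b["lo"]), float(b["hi"]), float(b["cutoff"]))
                          for b in spec["bands"])
            entries[name] = NormEntry(
                measure=name,
                percentile=int(spec["percentile"]),
                worse=str(spec["worse"]),
                bands=bands,
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "NormTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> Dict:
        return {
            "measures": {
                name: {
                    "percentile": e.percentile,
                    "worse": e.worse,
                    "bands": [{"lo": b.lo, "hi": b.hi, "cutoff": b.cutoff} for b in e.bands],
                }
                for name, e in sorted(self.entries.items())
            }
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_norms() -> NormTable:
    """Packaged cutoffs for the motion-perception and visual-search measures."""
    ref = resources.files("dorsalkit.data").joinpath("norm_tables.yaml")
    with ref.open() as fh:
        return NormTable.from_dict(yaml.safe_load(fh))


def classify_score(value: float, measure: str, entry_age: float, norms: NormTable) -> bool:
    """Functional form of :meth:`NormTable.classify`."""
    return norms.classify(value, measure, entry_age)


L94_MEASURES = ("l94_vism", "l94_noise", "l94_overl", "l94_view", "l94_devos")
MOTION_MEASURES = ("gm_coherence", "mdf_proportion", "ms_speed")
ATTENTION_MEASURES = ("search_time_5", "search_time_10", "search_time_20",
                      "response_time", "total_errors")
VISUOMOTOR_MEASURES = ("beery_vmi", "mosaics")


@dataclass(frozen=True)
class ClassificationPolicy:
    """Grouping of task measures into functions plus roll-up thresholds."""

    functions: Mapping[str, Tuple[str, ...]] = field(default_factory=lambda: {
        "object_recognition": L94_MEASURES,
        "motion": MOTION_MEASURES,
        "attention": ATTENTION_MEASURES,
        "visuomotor": VISUOMOTOR_MEASURES,
    })
    or_function: str = "object_recognition"
    abnormal_percentile: int = 5
    weak_percentile: int = 10
    general_min_weak: int = 2
    min_or_tasks: int = 3

    def __post_init__(self) -> None:
        if self.or_function not in self.functions:
            raise ValidationError(f"or_function {self.or_function!r} not in grouping")
        seen: set = set()
        for tasks in self.functions.values():
            dup = seen & set(tasks)
            if dup:
                raise ValidationError(f"tasks assigned to multiple functions: {sorted(dup)}")
            seen |= set(tasks)

    @property
    def dorsal_functions(self) -> Tuple[str, ...]:
        return tuple(f for f in self.functions if f != self.or_function)


def default_policy() -> ClassificationPolicy:
    return ClassificationPolicy()


@dataclass(frozen=True)
class PatientClassification:
    """Per-patient flags rolled up to function level.

    ``task_flags`` maps measure -> True/False/None (None = not administered
    or not evaluable). ``general_dysfunction`` is meaningful only when
    ``functions_complete`` is True — the pipeline excludes incomplete
    patients from function-level analyses.
    """

    task_flags: Mapping[str, Optional[bool]]
    function_weak: Mapping[str, Optional[bool]]
    n_abnormal_l94: int
    l94_evaluable: bool
    or_impaired: bool
    n_weak_functions: int
    general_dysfunction: bool
    functions_complete: bool


def rollup(task_flags: Mapping[str, Optional[bool]],
           policy: Optional[ClassificationPolicy] = None) -> PatientClassification:
    """Roll task flags up to function weakness and overall categories."""
    policy = policy or default_policy()
    known = {t for tasks in policy.functions.values() for t in tasks}
    unknown = set(task_flags) - known
    if unknown:
        raise ValidationError(f"flags for tasks outside the policy grouping: {sorted(unknown)}")

    or_tasks = policy.functions[policy.or_function]
    or_flags = [task_flags.get(t) for t in or_tasks]
    n_abnormal = sum(1 for f in or_flags if f is True)
    n_or_eval = sum(1 for f in or_flags if f is not None)

    function_weak: Dict[str, Optional[bool]] = {}
    for fn in policy.dorsal_functions:
        flags = [task_flags.get(t) for t in policy.functions[fn]]
        if all(f is None for f in flags):
            function_weak[fn] = None  # function not assessed
        else:
            function_weak[fn] = any(f is True for f in flags)

    n_weak = sum(1 for v in function_weak.values() if v is True)
    complete = all(v is not None for v in function_weak.values())
    return PatientClassification(
        task_flags=dict(task_flags),
        function_weak=function_weak,
        n_abnormal_l94=n_abnormal,
        l94_evaluable=n_or_eval >= policy.min_or_tasks,
        or_impaired=n_abnormal >= 1,
        n_weak_functions=n_weak,
        general_dysfunction=n_weak >= policy.general_min_weak,
        functions_complete=complete,
    )
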