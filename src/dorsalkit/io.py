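"""Delimited-text input/output for cohort tables.

A cohort is a directory of plain CSV tables:

``patients.csv``
    patient_id, ca_dorsal (months), ca_iq (months), piq (blank if unknown),
    age_equivalents (semicolon-separated months).
``l94_items.csv``
    patient_id, subtask (VISM/NOISE/OVERL/VIEW/DEVOS), item_id,
    j (1-based condition index or "never"), k, control_recognized (0/1).
``motion_trials.csv``
    patient_id, task (gm_coherence/ms_speed), trial_index, level, correct (0/1).
``mdf_items.csv``
    patient_id, item_id, condition (1/2/3 or "never").
``search_trials.csv``
    patient_id, condition (RT_pre/D4/D9/D19/RT_post), trial_index, rt,
    false_alarm (0/1).
``visuomotor.csv``
    patient_id, task (beery_vmi/mosaics), score (standard/scaled score).

Any table may be absent or empty; the pipeline treats missing tasks as not
administered for the patients concerned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ValidationError

__all__ = ["CohortData", "read_cohort", "write_cohort"]

_TABLES = ("patients", "l94_items", "motion_trials", "mdf_items", "search_trials", "visuomotor")

_EMPTY_COLUMNS = {
    "patients": ["patient_id", "ca_dorsal", "ca_iq", "piq", "age_equivalents"],
    "l94_items": ["patient_id", "subtask", "item_id", "j", "k", "control_recognized"],
    "motion_trials": ["patient_id", "task", "trial_index", "level", "correct"],
    "mdf_items": ["patient_id", "item_id", "condition"],
    "search_trials": ["patient_id", "condition", "trial_index", "rt", "false_alarm"],
    "visuomotor": ["patient_id", "task", "score"],
}


def _empty(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_EMPTY_COLUMNS[name])


@dataclass
class CohortData:
    """In-memory cohort: one DataFrame per input table."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty("patients"))
    l94_items: pd.DataFrame = field(default_factory=lambda: _empty("l94_items"))
    motion_trials: pd.DataFrame = field(default_factory=lambda: _empty("motion_trials"))
    mdf_items: pd.DataFrame = field(default_factory=lambda: _empty("mdf_items"))
    search_trials: pd.DataFrame = field(default_factory=lambda: _empty("search_trials"))
    visuomotor: pd.DataFrame = field(default_factory=lambda: _empty("visuomotor"))

    def validate(self) -> None:
        for name in _TABLES:
            df = getattr(self, name)
            missing = set(_EMPTY_COLUMNS[name]) - set(df.columns)
            if missing:
                raise ValidationError(f"table {name!r} lacks columns {sorted(missing)}")
        ids = set(self.patients["patient_id"])
        for name in _TABLES[1:]:
            df = getattr(self, name)
            if len(df):
                orphans = set(df["patient_id"]) - ids
                if orphans:
                    raise ValidationError(
                        f"table {name!r} references unknown patients {sorted(orphans)[:5]}"
                    )


def write_cohort(cohort: CohortData, directory) -> Path:
    """Write all cohort tables to ``directory`` as CSV; returns the path."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(cohort, name).to_csv(out / f"{name}.csv", index=False)
    return out


def read_cohort(directory) -> CohortData:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)
    if not d.is_dir():
        raise ValidationError(f"cohort directory {d} does not exist")
    kwargs = {}
    for name in _TABLES:
        path = d / f"{name}.csv"
        if path.exists():
            df = pd.read_csv(path, dtype={"patient_id": str})
            if "j" in df.columns:
                df["j"] = df["j"].astype(object)
            kwargs[name] = df if len(df.columns) > 1 else _empty(name)
        else:
            kwargs[name] = _empty(name)
    cohort = CohortData(**kwargs)
    cohort.validate()
    return cohort
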