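"""Deterministic fixture cohorts that reproduce specified marginal counts.

The published group-level results are marginal counts (how many patients had
>= 1, >= 2, >= 3 abnormal object-recognition scores; per-subtask abnormal
counts; weak-function counts split by object-recognition impairment). The
per-patient raw data behind them is not deposited. This module *constructs*
a synthetic raw-data cohort — item responses, staircase trial sequences,
search trials, visuomotor scores and ages — that, when run through the full
scoring + classification pipeline, yields exactly a requested set of
marginal counts. It is the round-trip fixture for pipeline tests and for
reproducing the published percentages end to end.

Everything here is synthetic: the object-recognition and visuomotor norm
cutoffs attached to the fixture are invented placeholders (the real norms
are proprietary test material), and planted scores sit far from every
cutoff so that classification is unambiguous. Construction is deterministic
— no randomness is needed because only counts are specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import pandas as pd

from .errors import ValidationError
from .io import CohortData
from .motion import GM_CONFIG, MS_CONFIG, run_staircase
from .norms import NormBand, NormEntry, NormTable, default_norms

__all__ = ["FixtureSpec", "make_fixture_cohort", "fixture_norms"]

_SUBTASK_ORDER = ("VISM", "NOISE", "OVERL", "VIEW", "DEVOS")
_ITEMS_PER_SUBTASK = {"VISM": 10, "NOISE": 6, "OVERL": 6, "VIEW": 17, "DEVOS": 43}
_K = {"VISM": 1, "NOISE": 7, "OVERL": 4, "VIEW": 4, "DEVOS": 1}

_DORSAL_CYCLE = ("motion", "attention", "visuomotor")

#: Deterministic observer targets: correct iff level >= target. Weak targets
#: put the resulting reversal mean far above the cutoff, normal targets far
#: below (GM/MS norms flag high thresholds).
_GM_TARGET = {"weak": 0.9, "ok": 0.2}
_MS_TARGET = {"weak": 40.0, "ok": 3.0}

_ENTRY_AGE = 62  # months: middle norm band for every packaged measure


@dataclass(frozen=True)
class FixtureSpec:
    """Marginal counts the fixture cohort must reproduce.

    Defaults reproduce the published cohort: 46 evaluable patients, the
    per-subtask administration/abnormality counts, 29/11/6 patients with
    >=1 / >=2 / >=3 abnormal object-recognition scores, and a 29-patient
    subgroup (18 impaired / 11 unimpaired) with 13 vs 3 showing >=1 weak
    dorsal function and 6 vs 1 showing >=2.
    """

    n_patients: int = 46
    l94_administered: Mapping[str, int] = field(default_factory=lambda: {
        "VISM": 41, "NOISE": 45, "OVERL": 45, "VIEW": 44, "DEVOS": 40})
    l94_abnormal: Mapping[str, int] = field(default_factory=lambda: {
        "VISM": 4, "NOISE": 8, "OVERL": 6, "VIEW": 13, "DEVOS": 15})
    n_ge1: int = 29
    n_ge2: int = 11
    n_ge3: int = 6
    impaired_group: int = 18
    normal_group: int = 11
    impaired_weak_ge1: int = 13
    impaired_weak_ge2: int = 6
    normal_weak_ge1: int = 3
    normal_weak_ge2: int = 1

    def validate(self) -> None:
        n = self.n_patients
        if not (0 <= self.n_ge3 <= self.n_ge2 <= self.n_ge1 <= n):
            raise ValidationError(
                f"count criteria must nest: >=3 ({self.n_ge3}) <= >=2 ({self.n_ge2}) "
                f"<= >=1 ({self.n_ge1}) <= n ({n})")
        for table, what in ((self.l94_administered, "administered"),
                            (self.l94_abnormal, "abnormal")):
            unknown = set(table) - set(_SUBTASK_ORDER)
            if unknown:
                raise ValidationError(f"unknown subtasks in {what} counts: {sorted(unknown)}")
        for t in _SUBTASK_ORDER:
            adm = self.l94_administered.get(t, n)
            if not 0 <= adm <= n:
                raise ValidationError(f"administered count for {t} out of range: {adm}")
            if not 0 <= self.l94_abnormal.get(t, 0) <= adm:
                raise ValidationError(f"abnormal count for {t} exceeds administered")
        total_flags = self.n_ge1 + self.n_ge2 + self.n_ge3
        if sum(self.l94_abnormal.values()) != total_flags:
            raise ValidationError(
                f"subtask abnormal counts sum to {sum(self.l94_abnormal.values())} but the "
                f">=1/>=2/>=3 criteria imply {total_flags} flags (patients hold at most 3)")
        n_unflagged = n - self.n_ge1
        missing = {t: n - self.l94_administered.get(t, n) for t in _SUBTASK_ORDER}
        if sum(missing.values()) > 2 * n_unflagged:
            raise ValidationError(
                "cannot place missing subtasks on unflagged patients while keeping "
                ">=3 subtasks per patient")
        if any(m > n_unflagged for m in missing.values()):
            raise ValidationError("a subtask is missing for more patients than are unflagged")
        if self.impaired_group > self.n_ge1 or self.normal_group > n_unflagged:
            raise ValidationError("subgroup sizes exceed available patients")
        if not (0 <= self.impaired_weak_ge2 <= self.impaired_weak_ge1 <= self.impaired_group):
            raise ValidationError("impaired-group weak counts must nest within the group")
        if not (0 <= self.normal_weak_ge2 <= self.normal_weak_ge1 <= self.normal_group):
            raise ValidationError("normal-group weak counts must nest within the group")


def fixture_norms() -> NormTable:
    """Packaged motion/search norms plus synthetic object-recognition and
    visuomotor cutoffs (placeholders for proprietary norm tables)."""
    synthetic = {}
    band = (NormBand(0.0, 240.0, 0.5),)
    for t in _SUBTASK_ORDER:
        name = f"l94_{t.lower()}"
        synthetic[name] = NormEntry(measure=name, percentile=5, worse="lower", bands=band)
    synthetic["beery_vmi"] = NormEntry(
        measure="beery_vmi", percentile=10, worse="lower",
        bands=(NormBand(0.0, 240.0, 81.0),))
    synthetic["mosaics"] = NormEntry(
        measure="mosaics", percentile=10, worse="lower",
        bands=(NormBand(0.0, 240.0, 6.2),))
    return default_norms().merged(NormTable(synthetic))


def _assign_flags(spec: FixtureSpec) -> Tuple[List[List[str]], List[List[str]]]:
    """Per-patient (abnormal subtasks, missing subtasks); greedy construction."""
    n = spec.n_patients
    e3 = spec.n_ge3
    e2 = spec.n_ge2 - spec.n_ge3
    e1 = spec.n_ge1 - spec.n_ge2
    flag_need = [3] * e3 + [2] * e2 + [1] * e1 + [0] * (n - spec.n_ge1)

    # Missing subtasks go to unflagged patients (at most 2 each) so every
    # flagged patient has all five subtasks available for flag placement.
    missing_left = {t: n - spec.l94_administered.get(t, n) for t in _SUBTASK_ORDER}
    missing: List[List[str]] = [[] for _ in range(n)]
    for i in range(spec.n_ge1, n):
        while len(missing[i]) < 2 and sum(missing_left.values()) > 0:
            t = max((t for t in _SUBTASK_ORDER if t not in missing[i]),
                    key=lambda t: (missing_left[t], ))
            if missing_left[t] == 0:
                break
            missing[i].append(t)
            missing_left[t] -= 1
    if sum(missing_left.values()) > 0:
        raise ValidationError("could not place all missing subtasks; spec inconsistent")

    demand = {t: spec.l94_abnormal.get(t, 0) for t in _SUBTASK_ORDER}
    flags: List[List[str]] = [[] for _ in range(n)]
    order = {t: i for i, t in enumerate(_SUBTASK_ORDER)}
    for i in range(n):
        for _ in range(flag_need[i]):
            candidates = [t for t in _SUBTASK_ORDER
                          if t not in flags[i] and t not in missing[i] and demand[t] > 0]
            if not candidates:
                raise ValidationError("abnormal counts cannot be realised; spec inconsistent")
            t = max(candidates, key=lambda t: (demand[t], -order[t]))
            flags[i].append(t)
            demand[t] -= 1
    if any(demand.values()):
        raise ValidationError("abnormal counts cannot be realised; spec inconsistent")
    return flags, missing


def _weak_functions(spec: FixtureSpec) -> Dict[int, Tuple[str, ...]]:
    """Planted weak dorsal functions per subgroup patient index."""
    weak: Dict[int, Tuple[str, ...]] = {}
    # impaired subgroup: first `impaired_group` flagged patients (0-based ids)
    for rank in range(spec.impaired_group):
        pid = rank
        if rank < spec.impaired_weak_ge2:
            weak[pid] = ("motion", "attention")
        elif rank < spec.impaired_weak_ge1:
            weak[pid] = (_DORSAL_CYCLE[(rank - spec.impaired_weak_ge2) % 3],)
        else:
            weak[pid] = ()
    # unimpaired subgroup: first `normal_group` unflagged patients
    for rank in range(spec.normal_group):
        pid = spec.n_ge1 + rank
        if rank < spec.normal_weak_ge2:
            weak[pid] = ("motion", "attention")
        elif rank < spec.normal_weak_ge1:
            weak[pid] = (_DORSAL_CYCLE[(rank - spec.normal_weak_ge2) % 3],)
        else:
            weak[pid] = ()
    return weak


def _staircase_rows(pid: str, task: str, target: float, cfg) -> List[dict]:
    stair = run_staircase(cfg, lambda level: level >= target)
    return [
        {"patient_id": pid, "task": task, "trial_index": i, "level": level,
         "correct": int(correct)}
        for i, (level, correct) in enumerate(stair.trials)
    ]


def make_fixture_cohort(spec: FixtureSpec | None = None) -> Tuple[CohortData, NormTable]:
    """Construct the raw-data cohort realising ``spec`` plus its norm table.

    The returned cohort, run through the pipeline with the returned norms,
    reproduces every count in the spec exactly (a pipeline invariant that is
    tested as a round-trip).
    """
    spec = spec or FixtureSpec()
    spec.validate()
    flags, missing = _assign_flags(spec)
    weak = _weak_functions(spec)

    pid = [f"P{i:03d}" for i in range(spec.n_patients)]
    patients = pd.DataFrame({
        "patient_id": pid,
        "ca_dorsal": _ENTRY_AGE,
        "ca_iq": 60,
        "piq": 100,
        "age_equivalents": "60;60;60",
    })

    l94_rows, motion_rows, mdf_rows, search_rows, vm_rows = [], [], [], [], []
    for i in range(spec.n_patients):
        p = pid[i]
        # --- object recognition items -----------------------------------
        for t in _SUBTASK_ORDER:
            if t in missing[i]:
                continue
            abnormal = t in flags[i]
            k = _K[t]
            for item in range(_ITEMS_PER_SUBTASK[t]):
                if t == "VIEW":
                    k = 3 if item < 8 else 4
                if item == 0 and t == "NOISE":
                    # one inconclusive item exercises the exclusion rule
                    l94_rows.append({"patient_id": p, "subtask": t, "item_id": f"{t}{item}",
                                     "j": "never", "k": k, "control_recognized": 0})
                    continue
                if abnormal:
                    j = "never" if k == 1 else k
                else:
                    j = 1
                l94_rows.append({"patient_id": p, "subtask": t, "item_id": f"{t}{item}",
                                 "j": j, "k": k, "control_recognized": 1})

        in_subgroup = i in weak
        weak_fns = weak.get(i, ())

        # --- motion (all patients) ---------------------------------------
        gm_target = _GM_TARGET["weak" if "motion" in weak_fns else "ok"]
        motion_rows += _staircase_rows(p, "gm_coherence", gm_target, GM_CONFIG)
        motion_rows += _staircase_rows(p, "ms_speed", _MS_TARGET["ok"], MS_CONFIG)
        for item in range(18):
            mdf_rows.append({"patient_id": p, "item_id": f"MDF{item}", "condition": 1})

        # --- attention (subgroup only: its absence elsewhere is what keeps
        #     non-subgroup patients out of the function-level analysis) ----
        if in_subgroup:
            d4 = 4.0 if "attention" in weak_fns else 1.5
            for cond, rt, ntr in (("RT_pre", 1.0, 5), ("D4", d4, 10), ("D9", 2.0, 10),
                                  ("D19", 4.0, 10), ("RT_post", 1.0, 5)):
                for trial in range(ntr):
                    search_rows.append({"patient_id": p, "condition": cond,
                                        "trial_index": trial, "rt": rt, "false_alarm": 0})

        # --- visuomotor (all patients) -----------------------------------
        beery = 70.0 if "visuomotor" in weak_fns else 100.0
        vm_rows.append({"patient_id": p, "task": "beery_vmi", "score": beery})
        vm_rows.append({"patient_id": p, "task": "mosaics", "score": 10.0})

    cohort = CohortData(
        patients=patients,
        l94_items=pd.DataFrame(l94_rows),
        motion_trials=pd.DataFrame(motion_rows),
        mdf_items=pd.DataFrame(mdf_rows),
        search_trials=pd.DataFrame(search_rows),
        visuomotor=pd.DataFrame(vm_rows),
    )
    cohort.validate()
    return cohort, fixture_norms()
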