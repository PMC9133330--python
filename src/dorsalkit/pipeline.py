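"""End-to-end run: scoring -> developmental age -> classification -> inference.

:func:`analyze` takes an in-memory cohort (:class:`dorsalkit.io.CohortData`),
a norm table and a classification policy, and produces a :class:`RunReport`
with the per-patient classification table and the group-level statistics the
study design calls for: marginal abnormality counts on the
object-recognition battery with exact confidence intervals and one-sample
binomial tests against Monte Carlo base rates, the weak-function split
between patients with and without object-recognition impairment with
Fisher's exact tests, and Mann-Whitney comparisons of the raw performance
levels.

Missing data follows the study's policy: a patient missing a task is
excluded only from the analyses that need it, never globally. Patients enter
at all only with >= 3 evaluable object-recognition subtasks, and enter the
function-level analysis only with >= 1 completed task per dorsal function.

Runs are deterministic given the config: all Monte Carlo draws are seeded
from the config seed, and the machine-readable report is written with sorted
keys so that identical configs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .ages import AgeRecord, developmental_age
from .baserate import BaseRateQuery, base_rate_curve, base_rate_function_curve
from .errors import NotEvaluableError, ValidationError
from .io import CohortData, read_cohort
from .l94 import SUBTASKS, ItemResponse, subtask_score
from .motion import GM_CONFIG, MS_CONFIG, StaircaseConfig, mdf_score, replay_staircase, staircase_threshold
from .norms import (ClassificationPolicy, NormTable, Z_5TH, Z_10TH, default_policy, rollup)
from .search import SearchTrial, search_outcome
from .stats import ContingencyTable2x2, binomial_vs_baserate, exact_binomial_ci, fisher_exact, mann_whitney_u
from .synthetic import ReferenceModel, default_reference_model

__all__ = ["RunConfig", "RunReport", "analyze", "run_pipeline", "score_patient"]

_MOTION_CONFIGS: Dict[str, StaircaseConfig] = {"gm_coherence": GM_CONFIG, "ms_speed": MS_CONFIG}

#: Measures whose *lower* values are worse (used to orient one-sided
#: Mann-Whitney comparisons); all others are worse when higher.
_LOWER_WORSE = {"mdf_proportion", "beery_vmi", "mosaics"} | {f"l94_{t.lower()}" for t in SUBTASKS}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    cohort_dir: str
    norms_path: Optional[str] = None      # merged over the packaged defaults
    model_path: Optional[str] = None      # reference model for base rates
    base_rates: Optional[Mapping[str, float]] = None  # fixed, skips Monte Carlo
    n_sims: int = 200_000
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_norms(cfg: RunConfig) -> NormTable:
    from .norms import default_norms

    norms = default_norms()
    if cfg.norms_path:
        norms = norms.merged(NormTable.from_yaml(cfg.norms_path))
    return norms


def score_patient(pid: str, cohort: CohortData,
                  motion_configs: Optional[Mapping[str, StaircaseConfig]] = None
                  ) -> Dict[str, Optional[float]]:
    """All measure values for one patient (``None`` = not administered/evaluable)."""
    motion_configs = motion_configs or _MOTION_CONFIGS
    values: Dict[str, Optional[float]] = {}

    items = cohort.l94_items
    items = items[items["patient_id"] == pid]
    for t in SUBTASKS:
        sub = items[items["subtask"] == t]
        if len(sub) == 0:
            values[f"l94_{t.lower()}"] = None
            continue
        responses = [
            ItemResponse(
                subtask=t,
                j=None if str(r.j).lower() == "never" else int(r.j),
                k=int(r.k),
                control_recognized=bool(int(r.control_recognized)),
                item_id=str(r.item_id),
            )
            for r in sub.itertuples()
        ]
        values[f"l94_{t.lower()}"] = subtask_score(responses).score

    trials = cohort.motion_trials
    trials = trials[trials["patient_id"] == pid]
    for task, cfg in motion_configs.items():
        sub = trials[trials["task"] == task].sort_values("trial_index")
        if len(sub) == 0:
            values[task] = None
            continue
        stair = replay_staircase(cfg, [bool(int(c)) for c in sub["correct"]])
        replayed = [lvl for lvl, _ in stair.trials]
        recorded = [float(x) for x in sub["level"]][: len(replayed)]
        if not np.allclose(replayed, recorded, rtol=0.0, atol=1e-9):
            raise ValidationError(
                f"recorded staircase levels for patient {pid} task {task} do not "
                "replay from the responses under the configured staircase")
        try:
            values[task] = staircase_threshold(stair, task=task).value
        except NotEvaluableError:
            values[task] = None  # unterminated run: task not evaluable

    mdf = cohort.mdf_items
    mdf = mdf[mdf["patient_id"] == pid]
    if len(mdf) == 0:
        values["mdf_proportion"] = None
    else:
        conds = [None if str(c).lower() == "never" else int(c) for c in mdf["condition"]]
        values["mdf_proportion"], _, _ = mdf_score(conds)

    st = cohort.search_trials
    st = st[st["patient_id"] == pid]
    if len(st) == 0:
        values.update({m: None for m in ("search_time_5", "search_time_10",
                                         "search_time_20", "response_time", "total_errors")})
    else:
        outcome = search_outcome(
            SearchTrial(condition=str(r.condition), rt=float(r.rt),
                        false_alarm=bool(int(r.false_alarm)))
            for r in st.itertuples())
        values.update(outcome.as_dict())

    vm = cohort.visuomotor
    vm = vm[vm["patient_id"] == pid]
    for task in ("beery_vmi", "mosaics"):
        sub = vm[vm["task"] == task]
        values[task] = float(sub["score"].iloc[0]) if len(sub) else None
    return values


def _entry_age(row) -> float:
    piq = row.piq
    piq = None if pd.isna(piq) else float(piq)
    equivalents = [float(x) for x in str(row.age_equivalents).split(";") if x != ""]
    rec = AgeRecord(age_equivalents=equivalents, ca_iq=float(row.ca_iq),
                    ca_dorsal=float(row.ca_dorsal), piq=piq)
    return developmental_age(rec).entry_age


def _rate_block(count: int, n: int, p0: Optional[float]) -> Dict:
    block: Dict = {"count": int(count), "n": int(n)}
    if n > 0:
        pct = 100.0 * count / n
        lo, hi = exact_binomial_ci(count, n)
        block.update({"percent": pct, "ci_low_percent": 100.0 * lo,
                      "ci_high_percent": 100.0 * hi})
        if p0 is not None:
            t = binomial_vs_baserate(count, n, p0)
            block.update({"base_rate_percent": 100.0 * p0,
                          "p_vs_base_rate": t.p_one_sided, "z_approx": t.statistic})
    return block


def _fisher_block(k1: int, n1: int, k2: int, n2: int) -> Dict:
    t = fisher_exact(ContingencyTable2x2.from_rates(k1, n1, k2, n2))
    return {"table": [[k1, n1 - k1], [k2, n2 - k2]],
            "odds_ratio": t.statistic, "p_one_sided": t.p_one_sided,
            "p_two_sided": t.p_two_sided}


def _compute_base_rates(cfg: RunConfig, model: ReferenceModel,
                        policy: ClassificationPolicy) -> Dict[str, float]:
    """Monte Carlo base rates for the criteria the summary tests against."""
    if cfg.base_rates is not None:
        return dict(cfg.base_rates)
    or_tasks = policy.functions[policy.or_function]
    names = list(model.task_names)
    idx = [names.index(t) for t in or_tasks]
    sub_corr = model.correlation[np.ix_(idx, idx)]
    or_model = ReferenceModel(functions={policy.or_function: tuple(or_tasks)},
                              correlation=sub_corr)
    q = BaseRateQuery(z_threshold=Z_5TH, n_sims=cfg.n_sims, seed=cfg.seed)
    curve = base_rate_curve(or_model, q, k_values=(1, 2, 3))
    rates = {f"l94_ge{k}": est.proportion for k, est in curve.items()}

    grouping = {fn: policy.functions[fn] for fn in policy.dorsal_functions}
    qf = BaseRateQuery(z_threshold=Z_10TH, grouping=grouping, m_min=1,
                       n_sims=cfg.n_sims, seed=cfg.seed + 1)
    fn_curve = base_rate_function_curve(model, qf, m_values=(1, 2, 3))
    rates.update({f"functions_ge{m}": est.proportion for m, est in fn_curve.items()})
    for fn in policy.dorsal_functions:
        sub_idx = [names.index(t) for t in policy.functions[fn]]
        sub_model = ReferenceModel(functions={fn: tuple(policy.functions[fn])},
                                   correlation=model.correlation[np.ix_(sub_idx, sub_idx)])
        qs = BaseRateQuery(z_threshold=Z_10TH, n_sims=cfg.n_sims, seed=cfg.seed + 2)
        rates[f"{fn}_ge1"] = base_rate_curve(sub_model, qs, k_values=(1,))[1].proportion
    return rates


@dataclass
class RunReport:
    """Pipeline output: per-patient table, group summary, provenance."""

    patients: pd.DataFrame
    summary: Dict
    provenance: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"summary": self.summary, "provenance": self.provenance}
        return json.dumps(payload, sort_keys=True, indent=2, allow_nan=True)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patient_classifications.csv", index=False)
        (out / "summary.json").write_text(self.to_json() + "\n")
        (out / "report.txt").write_text(self.human_report() + "\n")
        return out

    def human_report(self) -> str:
        s = self.summary
        lines = ["Dorsal-stream battery analysis", "=" * 32]
        l94 = s.get("l94", {})
        lines.append(f"Patients with >=3 evaluable object-recognition subtasks: "
                     f"{l94.get('n_evaluable', 0)}")
        for key, label in (("ge1", ">=1 abnormal"), ("ge2", ">=2 abnormal"),
                           ("ge3", ">=3 abnormal")):
            b = l94.get(key)
            if b and "percent" in b:
                lines.append(
                    f"  {label}: {b['count']}/{b['n']} ({b['percent']:.1f}%, "
                    f"95% CI {b['ci_low_percent']:.1f}-{b['ci_high_percent']:.1f}%)")
        fa = s.get("function_analysis")
        if fa:
            lines.append(f"Function-level subgroup: {fa['n_complete']} patients "
                         f"({fa['impaired']['n']} impaired / {fa['normal']['n']} unimpaired "
                         "object recognition)")
            for grp in ("impaired", "normal"):
                g = fa[grp]
                lines.append(f"  {grp}: >=1 weak {g['ge1_weak']['count']}/{g['n']}, "
                             f">=2 weak {g['ge2_weak']['count']}/{g['n']}")
        return "\n".join(lines)


def analyze(cohort: CohortData, norms: NormTable,
            policy: Optional[ClassificationPolicy] = None,
            cfg: Optional[RunConfig] = None,
            model: Optional[ReferenceModel] = None) -> RunReport:
    """Run scoring, classification and inference on an in-memory cohort."""
    policy = policy or default_policy()
    cfg = cfg or RunConfig(cohort_dir="")
    cohort.validate()
    model = model or (ReferenceModel.from_yaml(cfg.model_path) if cfg.model_path
                      else default_reference_model())

    rows: List[Dict] = []
    classifications = {}
    for row in cohort.patients.itertuples():
        pid = str(row.patient_id)
        entry_age = _entry_age(row)
        values = score_patient(pid, cohort)
        flags = {m: (norms.classify(v, m, entry_age) if v is not None and m in norms else None)
                 for m, v in values.items()}
        cls = rollup(flags, policy)
        classifications[pid] = cls
        rec: Dict = {"patient_id": pid, "entry_age_months": entry_age}
        rec.update({m: values[m] for m in sorted(values)})
        rec.update({f"flag_{m}": flags[m] for m in sorted(flags)})
        rec.update({
            "n_abnormal_l94": cls.n_abnormal_l94,
            "l94_evaluable": cls.l94_evaluable,
            "or_impaired": cls.or_impaired,
            "n_weak_functions": cls.n_weak_functions,
            "functions_complete": cls.functions_complete,
            "general_dysfunction": cls.general_dysfunction,
        })
        for fn in policy.dorsal_functions:
            rec[f"weak_{fn}"] = cls.function_weak[fn]
        rows.append(rec)

    patients = pd.DataFrame(rows)
    summary: Dict = {}

    included = [pid for pid, c in classifications.items() if c.l94_evaluable]
    base_rates = _compute_base_rates(cfg, model, policy) if included else {}
    summary["base_rates_percent"] = {k: 100.0 * v for k, v in sorted(base_rates.items())}

    # --- object-recognition marginals ------------------------------------
    n_inc = len(included)
    counts = [classifications[p].n_abnormal_l94 for p in included]
    l94_summary: Dict = {"n_evaluable": n_inc}
    for k in (1, 2, 3):
        l94_summary[f"ge{k}"] = _rate_block(
            sum(c >= k for c in counts), n_inc, base_rates.get(f"l94_ge{k}"))
    per_subtask = {}
    for t in SUBTASKS:
        m = f"l94_{t.lower()}"
        administered = [p for p in included if classifications[p].task_flags.get(m) is not None]
        abnormal = sum(1 for p in administered if classifications[p].task_flags[m] is True)
        per_subtask[t] = _rate_block(abnormal, len(administered), 0.05 if administered else None)
    l94_summary["per_subtask"] = per_subtask
    summary["l94"] = l94_summary

    # --- function-level subgroup -----------------------------------------
    complete = [p for p in included if classifications[p].functions_complete]
    impaired = [p for p in complete if classifications[p].or_impaired]
    normal = [p for p in complete if not classifications[p].or_impaired]
    fa: Dict = {"n_complete": len(complete)}
    for name, grp in (("impaired", impaired), ("normal", normal)):
        weak_counts = [classifications[p].n_weak_functions for p in grp]
        block = {"n": len(grp)}
        for m in (1, 2, 3):
            p0 = base_rates.get(f"functions_ge{m}") if grp else None
            block[f"ge{m}_weak"] = _rate_block(sum(c >= m for c in weak_counts), len(grp), p0)
        block["general_dysfunction"] = block["ge2_weak"]
        fa[name] = block
    if impaired and normal:
        fa["fisher_ge1_weak"] = _fisher_block(
            fa["impaired"]["ge1_weak"]["count"], len(impaired),
            fa["normal"]["ge1_weak"]["count"], len(normal))
        fa["fisher_ge2_weak"] = _fisher_block(
            fa["impaired"]["ge2_weak"]["count"], len(impaired),
            fa["normal"]["ge2_weak"]["count"], len(normal))
        per_fn = {}
        for fn in policy.dorsal_functions:
            k1 = sum(1 for p in impaired if classifications[p].function_weak[fn] is True)
            k2 = sum(1 for p in normal if classifications[p].function_weak[fn] is True)
            per_fn[fn] = _fisher_block(k1, len(impaired), k2, len(normal))
        fa["fisher_per_function"] = per_fn
        fa["mann_whitney"] = _group_comparisons(patients, impaired, normal)
    summary["function_analysis"] = fa

    provenance = {"package_version": _version, "seed": cfg.seed, "n_sims": cfg.n_sims,
                  "n_patients": int(len(cohort.patients))}
    return RunReport(patients=patients, summary=summary, provenance=provenance)


def _group_comparisons(patients: pd.DataFrame, impaired, normal) -> Dict:
    """One-sided Mann-Whitney tests expecting the impaired group to be worse."""
    out = {}
    indexed = patients.set_index("patient_id")
    measures = [c for c in indexed.columns
                if not c.startswith(("flag_", "weak_"))
                and c not in ("entry_age_months", "n_abnormal_l94", "l94_evaluable",
                              "or_impaired", "n_weak_functions", "functions_complete",
                              "general_dysfunction")]
    for m in measures:
        x = indexed.loc[impaired, m].dropna().astype(float).tolist()
        y = indexed.loc[normal, m].dropna().astype(float).tolist()
        if not x or not y:
            continue
        alternative = "less" if m in _LOWER_WORSE else "greater"
        t = mann_whitney_u(x, y, alternative=alternative)
        out[m] = {"U": t.statistic, "p_one_sided": t.p_one_sided,
                  "p_two_sided": t.p_two_sided, "method": t.method,
                  "n_impaired": len(x), "n_normal": len(y)}
    return out


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Load a cohort directory per the config, analyse it, write reports."""
    cohort = read_cohort(cfg.cohort_dir)
    norms = _load_norms(cfg)
    report = analyze(cohort, norms, cfg=cfg)
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report
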