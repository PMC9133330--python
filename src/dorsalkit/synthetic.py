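"""Synthetic reference populations, patient cohorts, observers and RT data.

No raw data is deposited with the study this pipeline reproduces, and the
reference-group correlation matrices behind its base rates are unpublished.
This module therefore generates every input the pipeline needs with known
ground truth:

* a *reference model* — correlated standard-normal task scores for a healthy
  population, from which base rates and empirical percentiles follow;
* *patient cohorts* with a planted standardized decrement on chosen
  functions, for parameter-recovery tests;
* *psychometric observers* answering staircase trials with a
  cumulative-Gaussian (on log stimulus level) probability of success;
* *search reaction times* as lognormal draws whose median follows a
  motor-plus-serial-scan model.

The default correlation fixture is exchangeable: 0.3 between tasks of the
same function and 0.1 between functions. That is a stand-in, not an
authoritative estimate — it spans the regime the published base rates imply
(a 5-task >=1-abnormal rate between the independence value 22.6% and the
perfect-correlation value 5%).

All randomness flows from explicit integer seeds; one root seed is split
per generator via :func:`numpy.random.SeedSequence` children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ValidationError

__all__ = [
    "DEFAULT_FUNCTIONS",
    "ReferenceModel",
    "exchangeable_correlation",
    "default_reference_model",
    "generate_reference_scores",
    "ImpairmentSpec",
    "generate_patient_cohort",
    "ObserverModel",
    "psychometric_p",
    "simulate_observer_response",
    "make_observer_responder",
    "convergence_level",
    "generate_search_rts",
]

#: Task measures grouped by dorsal function, matching the default
#: classification policy in :mod:`dorsalkit.norms`.
DEFAULT_FUNCTIONS: Dict[str, Tuple[str, ...]] = {
    "object_recognition": ("l94_vism", "l94_noise", "l94_overl", "l94_view", "l94_devos"),
    "motion": ("gm_coherence", "mdf_proportion", "ms_speed"),
    "attention": ("search_time_5", "search_time_10", "search_time_20",
                  "response_time", "total_errors"),
    "visuomotor": ("beery_vmi", "mosaics"),
}

_SYM_TOL = 1e-12
_EIG_TOL = -1e-10


@dataclass(frozen=True)
class ReferenceModel:
    """Latent-trait model of the healthy reference population.

    Task scores are jointly standard normal with the given correlation
    matrix (rows/columns ordered as the flattened function grouping). Lower
    latent scores mean worse performance, whatever the sign convention of
    the raw task units.
    """

    functions: Mapping[str, Tuple[str, ...]]
    correlation: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", corr)
        n = len(self.task_names)
        if corr.shape != (n, n):
            raise ValidationError(f"correlation must be {n}x{n}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=_SYM_TOL, rtol=0.0):
            raise ValidationError("correlation matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(corr), 1.0, atol=_SYM_TOL, rtol=0.0):
            raise ValidationError("correlation matrix must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < _EIG_TOL:
            raise ValidationError(
                "correlation matrix is not positive semi-definite: "
                f"smallest eigenvalue {eigvals.min():.3e}"
            )

    @property
    def task_names(self) -> Tuple[str, ...]:
        return tuple(t for tasks in self.functions.values() for t in tasks)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def task_indices(self, function: str) -> Tuple[int, ...]:
        if function not in self.functions:
            raise ValidationError(f"unknown function {function!r}; known: {sorted(self.functions)}")
        names = self.task_names
        return tuple(names.index(t) for t in self.functions[function])

    def factor(self) -> np.ndarray:
        """Matrix F with F F^T = correlation (eigendecomposition; handles
        singular matrices such as perfect correlation)."""
        w, v = np.linalg.eigh(self.correlation)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "correlation" in data:
            functions = {f: tuple(ts) for f, ts in data["functions"].items()}
            corr = np.asarray(data["correlation"], dtype=float)
            return cls(functions=functions, correlation=corr, seed=int(data.get("seed", 0)))
        return default_reference_model(
            rho_within=float(data.get("rho_within", 0.3)),
            rho_between=float(data.get("rho_between", 0.1)),
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        data = {
            "functions": {f: list(ts) for f, ts in self.functions.items()},
            "correlation": [[float(x) for x in row] for row in self.correlation],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def exchangeable_correlation(functions: Mapping[str, Sequence[str]],
                             rho_within: float, rho_between: float) -> np.ndarray:
    """Correlation matrix with one rho within functions, another between."""
    labels = [f for f, tasks in functions.items() for _ in tasks]
    n = len(labels)
    corr = np.full((n, n), float(rho_between))
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                corr[i, j] = float(rho_within)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_reference_model(rho_within: float = 0.3, rho_between: float = 0.1,
                            seed: int = 0) -> ReferenceModel:
    """The default (non-authoritative) exchangeable reference fixture."""
    corr = exchangeable_correlation(DEFAULT_FUNCTIONS, rho_within, rho_between)
    return ReferenceModel(functions=DEFAULT_FUNCTIONS, correlation=corr, seed=seed)


def _rng(seed: Optional[int], default_seed: int, stream: int) -> np.random.Generator:
    root = default_seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(root).spawn(stream + 1)[stream])


def generate_reference_scores(model: ReferenceModel, n: int,
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Draw ``n`` reference individuals; columns are standardized task scores."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = _rng(seed, model.seed, 0)
    z = rng.standard_normal((n, model.n_tasks))
    scores = z @ model.factor().T
    return pd.DataFrame(scores, columns=list(model.task_names))


@dataclass(frozen=True)
class ImpairmentSpec:
    """Planted impairment: a mean decrement (z-units) on whole functions."""

    affected_functions: Tuple[str, ...]
    shift: float
    n_patients: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValidationError(f"shift must be >= 0, got {self.shift}")
        if self.n_patients < 1:
            raise ValidationError(f"n_patients must be >= 1, got {self.n_patients}")

    @classmethod
    def from_yaml(cls, path) -> "ImpairmentSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            affected_functions=tuple(data.get("affected_functions", ())),
            shift=float(data.get("shift", 0.0)),
            n_patients=int(data["n_patients"]),
            seed=int(data.get("seed", 0)),
        )


def generate_patient_cohort(model: ReferenceModel,
                            spec: ImpairmentSpec) -> Tuple[pd.DataFrame, pd.Series]:
    """Patient scores with the planted decrement, plus ground-truth task labels.

    Returns ``(scores, affected)``: ``scores`` is patients x tasks in
    standardized units with affected-task means shifted by ``-spec.shift``;
    ``affected`` is a boolean Series over task names.
    """
    for fn in spec.affected_functions:
        if fn not in model.functions:
            raise ValidationError(f"unknown function {fn!r}; known: {sorted(model.functions)}")
    rng = _rng(spec.seed, model.seed, 1)
    z = rng.standard_normal((spec.n_patients, model.n_tasks))
    scores = z @ model.factor().T
    affected = pd.Series(False, index=list(model.task_names))
    for fn in spec.affected_functions:
        for idx in model.task_indices(fn):
            scores[:, idx] -= spec.shift
            affected.iloc[idx] = True
    return pd.DataFrame(scores, columns=list(model.task_names)), affected


@dataclass(frozen=True)
class ObserverModel:
    """Psychophysical observer with a cumulative-Gaussian psychometric function.

    P(correct at level L) = guess + (1 - guess - lapse) * F(L) with
    F(L) = Phi(slope * (log L - log threshold)) by default ("gaussian" on log
    level; "logistic" substitutes the logistic CDF). ``true_threshold`` is
    the level of F's midpoint (F = 0.5), ``slope`` is steepness per log-unit.
    Higher levels are easier.
    """

    true_threshold: float
    slope: float
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.true_threshold > 0:
            raise ValidationError("true_threshold must be positive")
        if not self.slope > 0:
            raise ValidationError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValidationError("lapse_rate must lie in [0, 0.1]")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValidationError("guess_rate must lie in [0, 1)")
        if self.family not in ("gaussian", "logistic"):
            raise ValidationError(f"unknown psychometric family {self.family!r}")


def _psychometric_f(obs: ObserverModel, level: float) -> float:
    x = obs.slope * (math.log(level) - math.log(obs.true_threshold))
    if obs.family == "gaussian":
        return float(norm.cdf(x))
    return 1.0 / (1.0 + math.exp(-x))


def psychometric_p(obs: ObserverModel, level: float) -> float:
    """Probability of a correct response at ``level``."""
    if not level > 0:
        raise ValidationError(f"stimulus level must be positive, got {level}")
    return obs.guess_rate + (1.0 - obs.guess_rate - obs.lapse_rate) * _psychometric_f(obs, level)


def simulate_observer_response(obs: ObserverModel, level: float,
                               rng: np.random.Generator) -> bool:
    return bool(rng.random() < psychometric_p(obs, level))


def make_observer_responder(obs: ObserverModel, rng: np.random.Generator):
    """A ``level -> correct`` callable for :func:`dorsalkit.motion.run_staircase`."""
    return lambda level: simulate_observer_response(obs, level, rng)


def convergence_level(obs: ObserverModel, p_target: float = math.sqrt(0.5)) -> float:
    """Stimulus level where P(correct) equals ``p_target``.

    The 2-consecutive-correct / 1-incorrect staircase converges where
    P(correct)^2 = 1/2, i.e. p_target = sqrt(1/2) ~ 0.707.
    """
    f = (p_target - obs.guess_rate) / (1.0 - obs.guess_rate - obs.lapse_rate)
    if not 0.0 < f < 1.0:
        raise ValidationError(
            f"target probability {p_target} unreachable for this observer (F={f:.3f})"
        )
    if obs.family == "gaussian":
        x = float(norm.ppf(f))
    else:
        x = math.log(f / (1.0 - f))
    return obs.true_threshold * math.exp(x / obs.slope)


def generate_search_rts(motor_median: float, scan_per_item: float, n_distracters: int,
                        n_trials: int, error_rate: float = 0.0,
                        seed: int = 0, sigma: float = 0.25) -> pd.DataFrame:
    """Simulated search-trial reaction times with false-alarm flags.

    Trials are lognormal around a serial-search median: the generated
    median is motor_median + scan_per_item * (n_distracters + 1) / 2 (a
    multiplicative lognormal disturbance with log-sd ``sigma`` leaves the
    median exact). Right-skew matches real RT data; only the median enters
    the pipeline, so the family is chosen for its correct median. False
    alarms are flagged Bernoulli(error_rate).
    """
    if motor_median <= 0 or scan_per_item < 0:
        raise ValidationError("durations must be positive (scan time non-negative)")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValidationError("error_rate must lie in [0, 1)")
    rng = _rng(seed, seed, 2)
    target_median = motor_median + scan_per_item * (n_distracters + 1) / 2.0
    rts = target_median * np.exp(sigma * rng.standard_normal(n_trials))
    false_alarm = rng.random(n_trials) < error_rate
    return pd.DataFrame({"rt": rts, "false_alarm": false_alarm})
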