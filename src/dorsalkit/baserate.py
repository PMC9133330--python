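"""Monte Carlo base rates for multi-test abnormality criteria.

Administering a battery of k tests inflates the chance that a healthy child
shows "at least one abnormally low score" well beyond the single-test
percentile: with five independent tests at the 5th percentile the expected
rate is 1 - 0.95^5 = 22.6%, while perfectly correlated tests give 5%. The
*base rate* of a count criterion is the expected proportion of the healthy
population meeting it, and it depends on the inter-test correlations.

The engine draws standardized score vectors from a correlated reference
model (:class:`dorsalkit.synthetic.ReferenceModel`), applies the percentile
cutoff as a z-threshold (-1.645 for the 5th percentile, -1.282 for the
10th), and counts simulants with >= k abnormally low scores — or, with a
task->function grouping, simulants with >= m functions having at least one
abnormally low score. All criteria evaluated through
:func:`base_rate_curve` / :func:`base_rate_function_curve` share a single
set of draws, which makes monotonicity in the criterion count exact per
seed.

:func:`closed_form_oracle` gives the exact Poisson-binomial tail under
independence, used as a verification oracle for the Monte Carlo path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .norms import Z_5TH, Z_10TH
from .synthetic import ReferenceModel, exchangeable_correlation

__all__ = [
    "BaseRateQuery",
    "BaseRateEstimate",
    "base_rate_counts",
    "base_rate_functions",
    "base_rate_curve",
    "base_rate_function_curve",
    "closed_form_oracle",
    "exchangeable_sweep",
]

_CHUNK = 200_000  # simulants per draw block; bounds peak memory


@dataclass(frozen=True)
class BaseRateQuery:
    """A base-rate question: cutoff, criterion count, and simulation size.

    ``z_threshold`` may be a scalar applied to every task or a per-task
    sequence. ``grouping`` (function -> task names) switches from counting
    abnormal tasks (``k_min``) to counting weak functions (``m_min``).
    """

    z_threshold: Union[float, Sequence[float]] = Z_5TH
    k_min: int = 1
    grouping: Optional[Mapping[str, Sequence[str]]] = None
    m_min: Optional[int] = None
    n_sims: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 10_000:
            raise ValidationError(f"n_sims must be >= 10^4, got {self.n_sims}")
        if self.k_min < 1:
            raise ValidationError(f"k_min must be >= 1, got {self.k_min}")
        if self.m_min is not None and self.m_min < 0:
            raise ValidationError(f"m_min must be >= 0, got {self.m_min}")


@dataclass(frozen=True)
class BaseRateEstimate:
    """Monte Carlo estimate with its binomial standard error."""

    proportion: float
    se: float
    n_sims: int
    query: Dict = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def _thresholds(model: ReferenceModel, z: Union[float, Sequence[float]]) -> np.ndarray:
    zarr = np.asarray(z, dtype=float)
    if zarr.ndim == 0:
        return np.full(model.n_tasks, float(zarr))
    if zarr.shape != (model.n_tasks,):
        raise ValidationError(
            f"z_threshold must be scalar or length {model.n_tasks}, got shape {zarr.shape}"
        )
    return zarr


def _estimate(hits: int, n: int, query: Dict) -> BaseRateEstimate:
    p = hits / n
    return BaseRateEstimate(proportion=p, se=math.sqrt(p * (1.0 - p) / n), n_sims=n, query=query)


def _simulate_counts(model: ReferenceModel, z: np.ndarray, n_sims: int, seed: int,
                     group_idx: Optional[Sequence[Sequence[int]]] = None) -> np.ndarray:
    """Histogram-free per-simulant criterion counts, drawn in blocks.

    Returns the vector of abnormal-task counts (or weak-function counts when
    ``group_idx`` is given) over all simulants.
    """
    factor_t = model.factor().T
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims, dtype=np.int32)
    done = 0
    while done < n_sims:
        m = min(_CHUNK, n_sims - done)
        scores = rng.standard_normal((m, model.n_tasks)) @ factor_t
        low = scores < z  # strict: "below the percentile"
        if group_idx is None:
            out[done:done + m] = low.sum(axis=1)
        else:
            weak = np.column_stack([low[:, idx].any(axis=1) for idx in group_idx])
            out[done:done + m] = weak.sum(axis=1)
        done += m
    return out


def base_rate_counts(model: ReferenceModel, q: BaseRateQuery) -> BaseRateEstimate:
    """Proportion of simulated healthy individuals with >= k_min scores below z."""
    z = _thresholds(model, q.z_threshold)
    counts = _simulate_counts(model, z, q.n_sims, q.seed)
    hits = int((counts >= q.k_min).sum())
    return _estimate(hits, q.n_sims, {"k_min": q.k_min, "seed": q.seed,
                                      "z_threshold": np.asarray(q.z_threshold).tolist()})


def base_rate_curve(model: ReferenceModel, q: BaseRateQuery,
                    k_values: Sequence[int]) -> Dict[int, BaseRateEstimate]:
    """Base rates for several k_min criteria from one shared set of draws."""
    z = _thresholds(model, q.z_threshold)
    counts = _simulate_counts(model, z, q.n_sims, q.seed)
    return {int(k): _estimate(int((counts >= k).sum()), q.n_sims,
                              {"k_min": int(k), "seed": q.seed})
            for k in k_values}


def _group_indices(model: ReferenceModel,
                   grouping: Mapping[str, Sequence[str]]) -> Tuple[Tuple[int, ...], ...]:
    names = list(model.task_names)
    idx = []
    for fn, tasks in grouping.items():
        if len(tasks) == 0:
            raise ValidationError(f"function {fn!r} has no tasks")
        missing = [t for t in tasks if t not in names]
        if missing:
            raise ValidationError(f"function {fn!r} references unknown tasks {missing}")
        idx.append(tuple(names.index(t) for t in tasks))
    return tuple(idx)


def base_rate_functions(model: ReferenceModel, q: BaseRateQuery) -> BaseRateEstimate:
    """Proportion with >= m_min weak functions (>=1 task below z per function)."""
    if q.grouping is None or q.m_min is None:
        raise ValidationError("base_rate_functions requires grouping and m_min")
    z = _thresholds(model, q.z_threshold)
    counts = _simulate_counts(model, z, q.n_sims, q.seed,
                              group_idx=_group_indices(model, q.grouping))
    hits = int((counts >= q.m_min).sum())
    return _estimate(hits, q.n_sims, {"m_min": q.m_min, "seed": q.seed})


def base_rate_function_curve(model: ReferenceModel, q: BaseRateQuery,
                             m_values: Sequence[int]) -> Dict[int, BaseRateEstimate]:
    """Function-level base rates for several m_min from one shared set of draws."""
    if q.grouping is None:
        raise ValidationError("base_rate_function_curve requires grouping")
    z = _thresholds(model, q.z_threshold)
    counts = _simulate_counts(model, z, q.n_sims, q.seed,
                              group_idx=_group_indices(model, q.grouping))
    return {int(m): _estimate(int((counts >= m).sum()), q.n_sims,
                              {"m_min": int(m), "seed": q.seed})
            for m in m_values}


def closed_form_oracle(marginals: Sequence[float], k_min: int) -> float:
    """Exact P(at least k_min of the events occur) under independence.

    Poisson-binomial tail by dynamic-programming convolution of the event
    indicators with probabilities ``marginals``.
    """
    p = np.asarray(marginals, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValidationError("marginal probabilities must lie in [0, 1]")
    if k_min < 0:
        raise ValidationError("k_min must be >= 0")
    if k_min == 0:
        return 1.0
    if k_min > p.size:
        return 0.0
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for pi in p:
        pmf[1:] = pmf[1:] * (1.0 - pi) + pmf[:-1] * pi
        pmf[0] *= 1.0 - pi
    return float(pmf[k_min:].sum())


def exchangeable_sweep(marginals: Sequence[float], m_min: int,
                       rhos: Sequence[float], n_sims: int = 200_000,
                       seed: int = 0) -> Dict[float, BaseRateEstimate]:
    """P(>= m_min weak functions) across exchangeable correlations.

    Each function is modelled as a single latent trait; ``marginals`` fix the
    per-function weak probabilities via per-task z-thresholds, and the
    exchangeable correlation rho is swept. Used to bracket published
    function-level base rates whose true correlation structure is unknown.
    """
    from scipy.stats import norm

    names = tuple(f"fn{i}" for i in range(len(marginals)))
    functions = {n: (n,) for n in names}
    z = norm.ppf(np.asarray(marginals, dtype=float))
    out: Dict[float, BaseRateEstimate] = {}
    for rho in rhos:
        corr = exchangeable_correlation(functions, rho_within=1.0, rho_between=float(rho))
        model = ReferenceModel(functions=functions, correlation=corr)
        q = BaseRateQuery(z_threshold=z, grouping=functions, m_min=m_min,
                          n_sims=n_sims, seed=seed)
        out[float(rho)] = base_rate_functions(model, q)
    return out
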