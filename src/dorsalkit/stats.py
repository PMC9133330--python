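"""Inferential layer: binomial, Fisher-exact and Mann-Whitney tests, exact CIs.

These wrap scipy / statsmodels primitives behind a uniform
:class:`TestResult`, with the conventions the pipeline reports:

* observed group rates are tested against a *fixed* base rate with the exact
  one-sided binomial tail (a normal-approximation z is reported as a
  secondary descriptive statistic only — its continuity-correction variant
  is a flag);
* proportions carry Clopper-Pearson ("exact") 95% intervals;
* 2x2 group comparisons use Fisher's exact test (small samples, low expected
  counts), one-sided in the direction of the observed association, two-sided
  by the probability-mass rule;
* performance-level comparisons use the Mann-Whitney U test with midranks,
  exact when feasible and normal-approximated with tie-corrected variance
  otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint
from statsmodels.stats.power import NormalIndPower
from statsmodels.stats.proportion import proportion_effectsize

from .errors import ValidationError

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "binomial_vs_baserate",
    "exact_binomial_ci",
    "fisher_exact",
    "mann_whitney_u",
    "required_n_two_proportions",
    "format_p",
]


@dataclass(frozen=True)
class TestResult:
    """Uniform test outcome: statistic, one- and two-sided p, method label."""

    statistic: Optional[float]
    p_one_sided: float
    p_two_sided: float
    method: str
    exact: bool

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
            "exact": self.exact,
        }


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d: rows are groups, columns outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table is empty")

    @classmethod
    def from_rates(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from 'k1 of n1 vs k2 of n2'."""
        return cls(k1, n1 - k1, k2, n2 - k2)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def binomial_vs_baserate(successes: int, n: int, p0: float,
                         continuity: bool = False) -> TestResult:
    """Exact one-sided (greater) binomial test of a count against a fixed rate.

    The primary p-value is the exact binomial tail P(X >= successes); the
    z statistic is the normal approximation (optionally continuity-corrected)
    and is descriptive only.
    """
    if not 0 <= successes <= n:
        raise ValidationError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"base rate must lie in (0, 1), got {p0}")
    p_greater = sps.binomtest(successes, n, p0, alternative="greater").pvalue
    p_two = sps.binomtest(successes, n, p0, alternative="two-sided").pvalue
    num = successes - n * p0 - (0.5 if continuity else 0.0)
    z = num / math.sqrt(n * p0 * (1.0 - p0))
    return TestResult(statistic=float(z), p_one_sided=float(p_greater),
                      p_two_sided=float(p_two), method="binomial", exact=True)


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    if not 0 <= successes <= n:
        raise ValidationError(f"need 0 <= successes <= n, got {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    # statsmodels returns nan at the boundaries for the degenerate ends
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return lo, hi


def fisher_exact(t: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    One-sided p is the hypergeometric tail in the direction of the observed
    association (odds ratio above vs below 1); two-sided p sums the
    probabilities of all tables as or less probable than the observed one.
    A degenerate margin admits no association: p = 1.
    """
    table = t.as_array()
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        return TestResult(statistic=None, p_one_sided=1.0, p_two_sided=1.0,
                          method="fisher_exact", exact=True)
    odds = sps.contingency.odds_ratio(table, kind="sample").statistic
    direction = "greater" if t.a * t.d >= t.b * t.c else "less"
    p_one = sps.fisher_exact(table, alternative=direction).pvalue
    p_two = sps.fisher_exact(table, alternative="two-sided").pvalue
    return TestResult(statistic=float(odds), p_one_sided=float(p_one),
                      p_two_sided=float(p_two), method="fisher_exact", exact=True)


_EXACT_MAX_PRODUCT = 400  # exact null enumeration when n1*n2 <= this
_EXACT_TIES_MAX_N = 12    # full permutation enumeration with ties


def _u_and_z(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, bool]:
    """U statistic of x (midranks) and tie-corrected z; flags all-tied data."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 0.0, True
    return float(u1), float((u1 - mu) / math.sqrt(var)), False


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test with midranks.

    Exact null distribution when there are no ties and n1*n2 <= 400; exact
    permutation enumeration for tied samples up to 12 observations total;
    tie-corrected normal approximation otherwise. ``alternative`` refers to
    x relative to y ("less" = x stochastically smaller).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")

    u1, z, all_tied = _u_and_z(x, y)
    if all_tied:
        return TestResult(statistic=u1, p_one_sided=1.0, p_two_sided=1.0,
                          method="mann_whitney_u", exact=True)

    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    n = len(x) + len(y)
    if not has_ties and len(x) * len(y) <= _EXACT_MAX_PRODUCT:
        method, exact = "exact", True
    elif has_ties and n <= _EXACT_TIES_MAX_N:
        method, exact = "permutation", True
    else:
        method, exact = "asymptotic", False

    if method == "permutation":
        one_sided_alt = alternative if alternative != "two-sided" else "less"
        res_one = sps.permutation_test(
            (x, y), lambda a, b, axis=-1: _perm_u(a, b, axis),
            permutation_type="independent", alternative=one_sided_alt, n_resamples=np.inf)
        res_two = sps.permutation_test(
            (x, y), lambda a, b, axis=-1: _perm_u(a, b, axis),
            permutation_type="independent", alternative="two-sided", n_resamples=np.inf)
        p_one, p_two = float(res_one.pvalue), float(res_two.pvalue)
    else:
        kwargs = dict(method="exact" if exact else "asymptotic")
        one_sided_alt = alternative if alternative != "two-sided" else "less"
        p_one = float(sps.mannwhitneyu(x, y, alternative=one_sided_alt, **kwargs).pvalue)
        p_two = float(sps.mannwhitneyu(x, y, alternative="two-sided", **kwargs).pvalue)
    return TestResult(statistic=u1, p_one_sided=p_one, p_two_sided=min(1.0, p_two),
                      method=f"mann_whitney_u/{method}", exact=exact)


def _perm_u(a: np.ndarray, b: np.ndarray, axis: int) -> np.ndarray:
    """Vectorised midrank U of sample ``a`` for scipy's permutation machinery."""
    a = np.asarray(a)
    b = np.asarray(b)
    n1 = a.shape[axis]
    pooled = np.concatenate([a, b], axis=axis)
    ranks = sps.rankdata(pooled, axis=axis)
    r1 = np.take(ranks, np.arange(n1), axis=axis).sum(axis=axis)
    return r1 - n1 * (n1 + 1) / 2.0


def required_n_two_proportions(p1: float, p2: float, power: float = 0.8,
                               alpha: float = 0.05, one_sided: bool = True) -> int:
    """Per-group sample size for a two-proportion comparison (normal approx)."""
    if not (0 < p1 < 1 and 0 < p2 < 1) or p1 == p2:
        raise ValidationError("need distinct proportions strictly inside (0, 1)")
    es = proportion_effectsize(p1, p2)
    n = NormalIndPower().solve_power(effect_size=es, alpha=alpha, power=power,
                                     alternative="larger" if one_sided else "two-sided")
    return int(math.ceil(float(n)))


def format_p(p: float, floor: float = 0.01) -> str:
    """Report-style p formatting: two decimals with a '<0.01' floor."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.2f}"
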