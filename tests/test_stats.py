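import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import dorsalkit as dk
from dorsalkit.errors import ValidationError
from dorsalkit.stats import ContingencyTable2x2


# --- independent oracles ---------------------------------------------------

def fisher_enumeration(a, b, c, d):
    """Brute-force Fisher p-values by enumerating all tables with the margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(r1 + r2, c1)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    greater = sum(p for x, p in probs.items() if x >= a)
    less = sum(p for x, p in probs.items() if x <= a)
    two = sum(p for p in probs.values() if p <= p_obs + 1e-12)
    return greater, less, two


def mwu_enumeration(x, y, u_obs):
    """Exact Mann-Whitney p-values by enumerating group assignments (midranks)."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(idx)].sum()
        us.append(r1 - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    p_less = (us <= u_obs + 1e-9).mean()
    p_greater = (us >= u_obs - 1e-9).mean()
    return p_less, p_greater, min(1.0, 2 * min(p_less, p_greater))


# --- binomial --------------------------------------------------------------

class TestBinomialVsBaseRate:
    def test_exact_tail(self):
        t = dk.binomial_vs_baserate(3, 10, 0.1)
        assert t.p_one_sided == pytest.approx(0.0702, abs=5e-4)

    def test_null_center_large_n(self):
        t = dk.binomial_vs_baserate(200, 1000, 0.2)
        assert 0.4 < t.p_one_sided < 0.6
        assert t.statistic == pytest.approx(0.0)

    def test_observed_rate_far_above_base_rate_is_significant(self):
        t = dk.binomial_vs_baserate(29, 46, 0.196)
        assert t.p_one_sided < 0.01

    def test_equals_complement_of_cdf(self):
        t = dk.binomial_vs_baserate(7, 20, 0.25)
        assert t.p_one_sided == pytest.approx(1 - sps.binom.cdf(6, 20, 0.25))

    def test_monotone_decreasing_in_successes(self):
        ps = [dk.binomial_vs_baserate(k, 20, 0.3).p_one_sided for k in range(21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_base_rate_rejected(self):
        with pytest.raises(ValidationError):
            dk.binomial_vs_baserate(3, 10, 1.0)


class TestExactBinomialCI:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (29, 46, 0.475, 0.768),
        (6, 46, 0.049, 0.263),
    ])
    def test_reproduces_clopper_pearson(self, k, n, lo, hi):
        got = dk.exact_binomial_ci(k, n)
        assert got[0] == pytest.approx(lo, abs=5e-4)
        assert got[1] == pytest.approx(hi, abs=5e-4)

    def test_boundaries(self):
        lo, hi = dk.exact_binomial_ci(0, 12)
        assert lo == 0.0 and 0 < hi < 1
        lo, hi = dk.exact_binomial_ci(12, 12)
        assert hi == 1.0 and 0 < lo < 1

    def test_contains_the_point_estimate(self):
        for k, n in [(1, 11), (5, 9), (40, 41)]:
            lo, hi = dk.exact_binomial_ci(k, n)
            assert lo <= k / n <= hi

    def test_simulated_coverage_at_nominal_level(self):
        """Exact intervals must cover the truth in >= 95% of replicates."""
        rng = np.random.default_rng(0)
        for p, n in [(0.2, 25), (0.5, 12)]:
            ks = rng.binomial(n, p, size=10_000)
            uniq, counts = np.unique(ks, return_counts=True)
            covered = 0
            for k, c in zip(uniq, counts):
                lo, hi = dk.exact_binomial_ci(int(k), n)
                covered += c * (lo <= p <= hi)
            assert covered / 10_000 >= 0.95 - 0.007  # 3 MC SEs below nominal


class TestFisherExact:
    @pytest.mark.parametrize("table,expected_one", [
        ((13, 5, 3, 8), 0.0234),
        ((9, 9, 1, 10), 0.0289),
    ])
    def test_group_comparisons(self, table, expected_one):
        t = dk.fisher_exact(ContingencyTable2x2(*table))
        assert t.p_one_sided == pytest.approx(expected_one, abs=5e-4)

    def test_degenerate_margin_gives_one(self):
        t = dk.fisher_exact(ContingencyTable2x2(0, 5, 0, 5))
        assert t.p_one_sided == 1.0 and t.p_two_sided == 1.0

    def test_one_sided_follows_observed_direction(self):
        pos = dk.fisher_exact(ContingencyTable2x2(8, 2, 2, 8))
        neg = dk.fisher_exact(ContingencyTable2x2(2, 8, 8, 2))
        assert pos.p_one_sided == pytest.approx(neg.p_one_sided)
        assert pos.p_one_sided < 0.05

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(0, 0, 0, 0)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        t = dk.fisher_exact(ContingencyTable2x2(a, b, c, d))
        greater, less, two = fisher_enumeration(a, b, c, d)
        expected_one = greater if a * d >= b * c else less
        assert t.p_one_sided == pytest.approx(expected_one, abs=1e-9)
        assert t.p_two_sided == pytest.approx(two, abs=1e-9)


class TestMannWhitneyU:
    def test_complete_separation_exact(self):
        t = dk.mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert t.statistic == 0
        assert t.p_one_sided == pytest.approx(1 / 20)
        assert t.exact

    def test_identical_samples_centered(self):
        t = dk.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert t.statistic == pytest.approx(8.0)  # n1*n2/2

    def test_tied_small_samples_enumerate_to_one(self):
        t = dk.mann_whitney_u([1, 2], [1, 2])
        assert t.statistic == pytest.approx(2.0)
        assert t.p_two_sided == pytest.approx(1.0)

    def test_all_values_tied(self):
        t = dk.mann_whitney_u([5, 5], [5, 5, 5])
        assert t.p_one_sided == 1.0 and t.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            dk.mann_whitney_u([], [1.0])

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=5),
           st.lists(st.integers(0, 5), min_size=2, max_size=5))
    def test_matches_permutation_oracle_with_ties(self, x, y):
        t = dk.mann_whitney_u(x, y, alternative="less")
        if not t.exact:
            return
        p_less, _, p_two = mwu_enumeration(x, y, t.statistic)
        if len(set(x) | set(y)) == 1:
            return  # degenerate case handled separately
        assert t.p_one_sided == pytest.approx(p_less, abs=1e-9)
        assert t.p_two_sided == pytest.approx(p_two, abs=1e-9)

    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=8, unique=True),
           st.lists(st.integers(-50, 50), min_size=3, max_size=8, unique=True))
    def test_invariant_under_monotone_transform(self, x, y):
        t1 = dk.mann_whitney_u(x, y)
        t2 = dk.mann_whitney_u([math.exp(v / 25) for v in x], [math.exp(v / 25) for v in y])
        assert t1.statistic == pytest.approx(t2.statistic)
        assert t1.p_two_sided == pytest.approx(t2.p_two_sided)


class TestPowerAndFormatting:
    def test_sample_size_routine_is_sane(self):
        n = dk.required_n_two_proportions(0.333, 0.091)
        assert 20 <= n <= 120

    def test_p_formatting(self):
        assert dk.format_p(0.0234) == "0.02"
        assert dk.format_p(0.0001) == "<0.01"
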