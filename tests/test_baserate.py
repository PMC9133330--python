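import numpy as np
import pytest

import dorsalkit as dk
from dorsalkit.baserate import exchangeable_sweep
from dorsalkit.errors import ValidationError


def battery_model(n_tasks=5, rho=0.0):
    functions = {"battery": tuple(f"t{i}" for i in range(n_tasks))}
    corr = dk.exchangeable_correlation(functions, rho_within=rho, rho_between=rho)
    return dk.ReferenceModel(functions=functions, correlation=corr)


class TestClosedFormOracle:
    @pytest.mark.parametrize("marginals,k,expected", [
        ([0.05] * 5, 1, 1 - 0.95 ** 5),                      # 0.22622
        ([0.05] * 5, 2, 1 - 0.95 ** 5 - 5 * 0.05 * 0.95 ** 4),  # 0.02259
        ([0.3], 1, 0.3),
        ([1.0, 1.0, 1.0], 3, 1.0),
        ([0.2, 0.3], 3, 0.0),  # more events than tests
        ([0.5, 0.5], 0, 1.0),
    ])
    def test_poisson_binomial_tail(self, marginals, k, expected):
        assert dk.closed_form_oracle(marginals, k) == pytest.approx(expected, abs=1e-12)

    def test_two_of_three_inclusion_exclusion(self):
        p1, p2, p3 = 0.279, 0.211, 0.168
        expected = p1 * p2 + p1 * p3 + p2 * p3 - 2 * p1 * p2 * p3  # 0.1214
        assert dk.closed_form_oracle([p1, p2, p3], 2) == pytest.approx(expected, abs=1e-12)
        assert dk.closed_form_oracle([p1, p2, p3], 3) == pytest.approx(p1 * p2 * p3, abs=1e-12)

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValidationError):
            dk.closed_form_oracle([0.5, 1.2], 1)


class TestBaseRateCounts:
    def test_independent_battery_matches_oracle(self):
        model = battery_model(5, rho=0.0)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, k_min=1, n_sims=200_000, seed=1)
        est = dk.base_rate_counts(model, q)
        expected = dk.closed_form_oracle([0.05] * 5, 1)
        assert abs(est.proportion - expected) < 4 * est.se

    def test_perfect_correlation_collapses_to_marginal(self):
        model = battery_model(4, rho=1.0)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, k_min=3, n_sims=100_000, seed=2)
        est = dk.base_rate_counts(model, q)
        assert est.proportion == pytest.approx(0.05, abs=4 * est.se)

    def test_criterion_above_battery_size_is_impossible(self):
        model = battery_model(3, rho=0.2)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, k_min=4, n_sims=50_000, seed=3)
        assert dk.base_rate_counts(model, q).proportion == 0.0

    def test_monotone_in_k_on_shared_draws(self):
        model = battery_model(5, rho=0.3)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, n_sims=100_000, seed=4)
        curve = dk.base_rate_curve(model, q, k_values=(1, 2, 3, 4, 5))
        props = [curve[k].proportion for k in (1, 2, 3, 4, 5)]
        assert all(a >= b for a, b in zip(props, props[1:]))

    def test_seeded_reproducibility_bit_exact(self):
        model = battery_model(5, rho=0.3)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, k_min=1, n_sims=50_000, seed=5)
        assert dk.base_rate_counts(model, q).proportion == dk.base_rate_counts(model, q).proportion

    def test_se_formula(self):
        model = battery_model(5, rho=0.3)
        q = dk.BaseRateQuery(z_threshold=dk.Z_5TH, k_min=1, n_sims=50_000, seed=6)
        est = dk.base_rate_counts(model, q)
        assert est.se == pytest.approx(np.sqrt(est.proportion * (1 - est.proportion) / est.n_sims))

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValidationError):
            dk.BaseRateQuery(n_sims=100)


class TestBaseRateFunctions:
    def test_independent_functions_match_inclusion_exclusion(self):
        functions = {"a": ("t0",), "b": ("t1",), "c": ("t2",)}
        corr = np.eye(3)
        model = dk.ReferenceModel(functions=functions, correlation=corr)
        from scipy.stats import norm
        z = norm.ppf([0.279, 0.211, 0.168])
        q = dk.BaseRateQuery(z_threshold=z, grouping=functions, m_min=2,
                             n_sims=400_000, seed=7)
        est = dk.base_rate_functions(model, q)
        assert abs(est.proportion - 0.12141) < 4 * est.se

    def test_m_zero_is_certain(self):
        functions = {"a": ("t0",), "b": ("t1",)}
        model = dk.ReferenceModel(functions=functions, correlation=np.eye(2))
        q = dk.BaseRateQuery(grouping=functions, m_min=0, n_sims=10_000, seed=8)
        assert dk.base_rate_functions(model, q).proportion == 1.0

    def test_empty_function_group_rejected(self):
        functions = {"a": ("t0", "t1")}
        model = dk.ReferenceModel(functions=functions, correlation=np.eye(2))
        q = dk.BaseRateQuery(grouping={"a": ()}, m_min=1, n_sims=10_000, seed=9)
        with pytest.raises(ValidationError):
            dk.base_rate_functions(model, q)

    def test_exchangeable_sweep_is_increasing_for_positive_dependence(self):
        sweep = exchangeable_sweep([0.279, 0.211, 0.168], m_min=2,
                                   rhos=(0.0, 0.5, 0.95), n_sims=100_000, seed=10)
        props = [sweep[r].proportion for r in (0.0, 0.5, 0.95)]
        assert props[0] < props[1] < props[2]
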