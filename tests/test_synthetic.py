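import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dorsalkit as dk
from dorsalkit.errors import ValidationError


class TestReferenceModel:
    def test_default_model_is_valid_and_exchangeable(self, default_model):
        corr = default_model.correlation
        assert corr.shape == (15, 15)
        i = list(default_model.task_names).index
        assert corr[i("gm_coherence"), i("ms_speed")] == pytest.approx(0.3)
        assert corr[i("gm_coherence"), i("beery_vmi")] == pytest.approx(0.1)

    def test_non_psd_matrix_rejected_with_eigenvalue(self):
        functions = {"f": ("a", "b", "c")}
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValidationError, match="eigenvalue"):
            dk.ReferenceModel(functions=functions, correlation=corr)

    def test_asymmetric_matrix_rejected(self):
        corr = np.eye(2)
        corr[0, 1] = 1e-6
        with pytest.raises(ValidationError, match="symmetric"):
            dk.ReferenceModel(functions={"f": ("a", "b")}, correlation=corr)


class TestReferenceScores:
    def test_identity_correlation_pairwise_near_zero(self):
        model = dk.ReferenceModel(functions={"f": tuple("abcde")}, correlation=np.eye(5))
        scores = dk.generate_reference_scores(model, 1_000_000, seed=1)
        corr = np.corrcoef(scores.to_numpy(), rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.005  # ~ 3-4 Monte Carlo SEs at n=10^6

    def test_marginals_standard_normal(self, default_model):
        scores = dk.generate_reference_scores(default_model, 1_000_000, seed=2)
        for col in ("gm_coherence", "l94_vism", "mosaics"):
            d, _ = sps.kstest(scores[col], "norm")
            assert d < 0.01

    def test_perfect_correlation_duplicates_columns(self):
        corr = np.ones((3, 3))
        model = dk.ReferenceModel(functions={"f": ("a", "b", "c")}, correlation=corr)
        scores = dk.generate_reference_scores(model, 100, seed=3).to_numpy()
        assert np.allclose(scores, scores[:, [0]])

    def test_zero_n_rejected(self, default_model):
        with pytest.raises(ValidationError):
            dk.generate_reference_scores(default_model, 0)

    def test_seeded_determinism(self, default_model):
        a = dk.generate_reference_scores(default_model, 50, seed=9)
        b = dk.generate_reference_scores(default_model, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPatientCohort:
    def test_shift_moves_only_affected_tasks(self, default_model):
        spec = dk.ImpairmentSpec(affected_functions=("motion",), shift=3.0,
                                 n_patients=50_000, seed=4)
        scores, affected = dk.generate_patient_cohort(default_model, spec)
        assert affected["gm_coherence"] and not affected["beery_vmi"]
        assert scores["gm_coherence"].mean() == pytest.approx(-3.0, abs=0.05)
        assert scores["beery_vmi"].mean() == pytest.approx(0.0, abs=0.05)

    def test_planted_flag_rate_matches_normal_tail(self, default_model):
        """Shift 3 at the 5th-percentile cutoff flags ~ Phi(-1.645 + 3) = 91.2%."""
        spec = dk.ImpairmentSpec(affected_functions=("motion",), shift=3.0,
                                 n_patients=50_000, seed=5)
        scores, _ = dk.generate_patient_cohort(default_model, spec)
        rate = (scores["gm_coherence"] < dk.Z_5TH).mean()
        expected = sps.norm.cdf(dk.Z_5TH + 3.0)
        se = np.sqrt(expected * (1 - expected) / len(scores))
        assert abs(rate - expected) < 3 * se

    def test_unknown_function_rejected(self, default_model):
        with pytest.raises(ValidationError):
            dk.generate_patient_cohort(default_model, dk.ImpairmentSpec(
                affected_functions=("telepathy",), shift=1.0, n_patients=5))

    def test_determinism(self, default_model):
        spec = dk.ImpairmentSpec(affected_functions=("motion",), shift=1.0,
                                 n_patients=20, seed=6)
        a, _ = dk.generate_patient_cohort(default_model, spec)
        b, _ = dk.generate_patient_cohort(default_model, spec)
        pd.testing.assert_frame_equal(a, b)


class TestObserver:
    def test_asymptotes(self):
        obs = dk.ObserverModel(true_threshold=0.5, slope=4.0, lapse_rate=0.02, guess_rate=0.5)
        assert dk.psychometric_p(obs, 50.0) == pytest.approx(1 - 0.02, abs=1e-3)
        assert dk.psychometric_p(obs, 0.005) == pytest.approx(0.5, abs=1e-3)

    def test_midpoint_at_threshold(self):
        obs = dk.ObserverModel(true_threshold=0.5, slope=4.0, lapse_rate=0.0, guess_rate=0.5)
        # cumulative Gaussian midpoint: F = 0.5 at the threshold parameter
        assert dk.psychometric_p(obs, 0.5) == pytest.approx(0.5 + 0.5 * 0.5)

    def test_monotone_in_level(self):
        obs = dk.ObserverModel(true_threshold=0.5, slope=4.0)
        levels = np.geomspace(0.05, 5.0, 20)
        ps = [dk.psychometric_p(obs, l) for l in levels]
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_convergence_level_solves_the_probability(self):
        obs = dk.ObserverModel(true_threshold=0.5, slope=6.0, lapse_rate=0.01, guess_rate=0.5)
        level = dk.convergence_level(obs)
        assert dk.psychometric_p(obs, level) == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            dk.ObserverModel(true_threshold=0.5, slope=-1.0)
        with pytest.raises(ValidationError):
            dk.ObserverModel(true_threshold=0.5, slope=1.0, lapse_rate=0.5)


class TestSearchRts:
    def test_median_matches_serial_search_model(self):
        df = dk.generate_search_rts(motor_median=1.0, scan_per_item=0.2, n_distracters=9,
                                    n_trials=10_000, seed=7)
        target = 1.0 + 0.2 * (9 + 1) / 2
        assert df["rt"].median() == pytest.approx(target, rel=0.02)

    def test_no_scan_component_matches_motor_median(self):
        df = dk.generate_search_rts(1.0, 0.0, 9, 10_000, seed=8)
        assert df["rt"].median() == pytest.approx(1.0, rel=0.02)

    def test_error_rate_zero_flags_nothing(self):
        df = dk.generate_search_rts(1.0, 0.1, 4, 500, error_rate=0.0, seed=9)
        assert not df["false_alarm"].any()

    def test_error_rate_flags_at_rate(self):
        df = dk.generate_search_rts(1.0, 0.1, 4, 20_000, error_rate=0.1, seed=10)
        assert df["false_alarm"].mean() == pytest.approx(0.1, abs=0.01)
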