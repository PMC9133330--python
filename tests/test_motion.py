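import numpy as np
import pytest

import dorsalkit as dk
from dorsalkit.errors import NotEvaluableError, ValidationError
from dorsalkit.motion import Staircase, StaircaseConfig


class TestStaircaseStepping:
    def test_two_consecutive_correct_step_harder(self):
        """Hand-iterated level sequence for an all-correct run."""
        st = Staircase(dk.GM_CONFIG)
        for _ in range(6):
            st.step(True)
        levels = [lvl for lvl, _ in st.trials]
        assert levels == pytest.approx([1.0, 1.0, 0.67, 0.67, 0.67 * 0.67, 0.67 * 0.67])

    def test_each_error_steps_easier(self):
        cfg = StaircaseConfig(start_level=0.5, scaling_factor=0.33, level_bounds=(1e-9, 10.0))
        st = Staircase(cfg)
        st.step(False)
        assert st.level == pytest.approx(0.5 / 0.67)

    def test_single_correct_does_not_step(self):
        st = Staircase(dk.GM_CONFIG)
        st.step(True)
        assert st.level == 1.0 and not st.reversals

    def test_counter_resets_after_each_step(self):
        # correct, correct (step), correct, correct (step): 2+2, not 2+1+1
        st = Staircase(dk.GM_CONFIG)
        for _ in range(3):
            st.step(True)
        assert st.level == pytest.approx(0.67)  # third correct alone must not step

    def test_reversals_and_termination_on_alternating_runs(self):
        st = Staircase(dk.GM_CONFIG)
        while not st.terminated:
            st.step(True)
            if st.terminated:
                break
            st.step(True)
            if st.terminated:
                break
            st.step(False)
        assert len(st.reversals) == 8
        with pytest.raises(ValidationError):
            st.step(True)

    def test_levels_respect_bounds(self):
        cfg = StaircaseConfig(start_level=1.0, scaling_factor=0.33, level_bounds=(1e-9, 1.0))
        st = Staircase(cfg)
        for _ in range(10):  # errors push easier but the ceiling is 1.0
            if st.terminated:
                break
            st.step(False)
        assert all(lvl <= 1.0 for lvl, _ in st.trials) and st.level <= 1.0

    def test_late_scaling_factor_engages_after_configured_reversal(self):
        """Deterministic observer on the speed task: final steps use 0.25."""
        stair = dk.run_staircase(dk.MS_CONFIG, lambda level: level >= 3.0)
        levels = sorted({round(lvl, 6) for lvl, _ in stair.trials[-6:]})
        # late phase oscillates between L and L/0.75, not L/0.67
        assert any(abs(b / a - 1 / 0.75) < 1e-6 for a in levels for b in levels if b > a)


class TestThreshold:
    def test_mean_of_last_four_reversals(self):
        st = Staircase(dk.GM_CONFIG)
        st.reversals = [(i, lvl) for i, lvl in enumerate([.8, .6, .7, .5, .6, .4, .5, .3])]
        st.terminated = True
        assert dk.staircase_threshold(st).value == pytest.approx(0.45)

    def test_constant_reversals(self):
        st = Staircase(dk.GM_CONFIG)
        st.reversals = [(i, 0.42) for i in range(8)]
        st.terminated = True
        assert dk.staircase_threshold(st).value == pytest.approx(0.42)

    def test_unterminated_rejected_with_reversal_count(self):
        st = Staircase(dk.GM_CONFIG)
        st.step(False)
        with pytest.raises(NotEvaluableError, match="0 of 8"):
            dk.staircase_threshold(st)

    def test_bit_exact_replay(self):
        rng = np.random.default_rng(3)
        obs = dk.ObserverModel(true_threshold=0.4, slope=4.0, lapse_rate=0.02, guess_rate=0.5)
        stair = dk.run_staircase(dk.GM_CONFIG, dk.make_observer_responder(obs, rng))
        replayed = dk.replay_staircase(dk.GM_CONFIG, [c for _, c in stair.trials])
        assert replayed.trials == stair.trials
        assert replayed.reversals == stair.reversals

    def test_simulated_observers_converge_to_the_707_point(self):
        """Replicate staircases center near the 70.7%-correct level."""
        obs = dk.ObserverModel(true_threshold=0.5, slope=6.0, lapse_rate=0.0, guess_rate=0.5)
        target = dk.convergence_level(obs)
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(200):
            stair = dk.run_staircase(dk.GM_CONFIG, dk.make_observer_responder(obs, rng))
            estimates.append(dk.staircase_threshold(stair).value)
        assert np.mean(estimates) == pytest.approx(target, rel=0.10)


class TestMdfScore:
    @pytest.mark.parametrize("conditions,expected,n_conclusive", [
        ([1, 1, 2, 3], 0.625, 4),
        ([1, 1, 1], 1.0, 3),
        ([1, "never", 3], 0.5, 2),   # inconclusive item excluded
        ([3, 3], 0.0, 2),
    ])
    def test_condition_scoring(self, conditions, expected, n_conclusive):
        score, n_ok, _ = dk.mdf_score(conditions)
        assert score == pytest.approx(expected) and n_ok == n_conclusive

    def test_all_inconclusive_not_evaluable(self):
        score, n_ok, n_bad = dk.mdf_score(["never", None])
        assert score is None and n_ok == 0 and n_bad == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            dk.mdf_score([])

    def test_invariant_to_inconclusive_insertion(self):
        base = [1, 2, 2, 3]
        padded = base + ["never"] * 5
        assert dk.mdf_score(padded)[0] == dk.mdf_score(base)[0]
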