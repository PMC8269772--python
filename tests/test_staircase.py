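"""Staircase procedure: range finding, thresholding, scoring, invariants."""

import math

import numpy as np
import pytest

from teleacuity import (ObserverParams, PsychometricObserver, StaircaseConfig,
                        TestStatus as Status, deterministic_observer, letter_score,
                        range_find, run_test, run_thresholding,
                        scripted_observer)
from teleacuity.errors import DomainError, ScriptExhaustedError
from teleacuity.staircase import Phase

T, F = True, False


def sizes_of(trials, phase=None):
    return [t.size_logmar for t in trials
            if phase is None or t.phase is phase]


def line_sizes(trials):
    """Distinct thresholding sizes in presentation order."""
    seen = []
    for t in trials:
        if t.phase is Phase.THRESHOLDING and t.size_logmar not in seen:
            seen.append(t.size_logmar)
    return seen


def smallest_grid_at_or_above(t):
    return round(math.ceil(t * 10 - 1e-9) / 10, 10)


class TestRangeFinding:
    def test_descending_trace(self):
        """Correct iff >= 0.3: 0.8 ok, 0.6 ok, 0.4 ok, 0.2 wrong."""
        rf = range_find(deterministic_observer(0.3))
        assert sizes_of(rf.trials) == [0.8, 0.6, 0.4, 0.2]
        assert rf.smallest_recognized_logmar == 0.4
        assert rf.thresholding_start_logmar == 0.6

    def test_ascending_trace(self):
        rf = range_find(deterministic_observer(0.9))
        assert sizes_of(rf.trials) == [0.8, 1.0]
        assert rf.smallest_recognized_logmar == 1.0
        assert rf.thresholding_start_logmar == 1.2

    def test_always_correct_clamps_to_floor(self):
        rf = range_find(deterministic_observer(-10.0))
        assert rf.smallest_recognized_logmar == -0.3
        assert rf.thresholding_start_logmar == pytest.approx(-0.1)

    def test_never_correct_is_off_scale_high(self):
        rf = range_find(deterministic_observer(10.0))
        assert rf.status is Status.OFF_SCALE_HIGH
        assert sizes_of(rf.trials)[-1] == 1.6  # ascended to the ceiling

    def test_start_clamped_to_ceiling(self):
        rf = range_find(deterministic_observer(1.5))
        assert rf.smallest_recognized_logmar == 1.6
        assert rf.thresholding_start_logmar == 1.6


class TestThresholding:
    def test_clean_descent_terminates_on_five_wrong(self):
        trials, status = run_thresholding(deterministic_observer(0.3), 0.6)
        assert status is Status.OK
        assert line_sizes(trials) == [0.6, 0.5, 0.4, 0.3, 0.2]
        last_line = [t.correct for t in trials if t.size_logmar == 0.2]
        assert last_line == [F] * 5

    def test_scripted_partial_line(self):
        obs = scripted_observer([T] * 5 + [T, T, T, F, F] + [F] * 5)
        trials, status = run_thresholding(obs, 0.4)
        assert status is Status.OK
        va, anchor, below = letter_score(trials)
        assert (va, anchor, below) == (0.34, 0.4, 3)

    def test_first_line_errors_ascend_then_reuse_on_descent(self):
        """Errors at 0.5 trigger an ascent; after the clean 0.6 line the
        descent reuses the recorded 0.5 responses and resumes at 0.4."""
        obs = scripted_observer(
            [T, T, F, F, T] + [T] * 5 + [T] * 5 + [F] * 5)
        trials, status = run_thresholding(obs, 0.5)
        assert status is Status.OK
        assert line_sizes(trials) == [0.5, 0.6, 0.4, 0.3]  # 0.5 not repeated
        assert sum(t.size_logmar == 0.5 for t in trials) == 5
        va, anchor, below = letter_score(trials)
        assert anchor == 0.6
        assert below == 3 + 5 + 0  # letters at 0.5, 0.4, 0.3
        assert va == pytest.approx(0.44)

    def test_ascent_to_ceiling_without_clean_line_is_off_scale(self):
        trials, status = run_thresholding(deterministic_observer(10.0), 1.4)
        assert status is Status.OFF_SCALE_HIGH

    def test_floor_line_completion_ends_test(self):
        trials, status = run_thresholding(deterministic_observer(-10.0), -0.1)
        assert status is Status.OK
        assert line_sizes(trials) == [-0.1, -0.2, -0.3]


class TestLetterScore:
    def test_perfect_descent_scores_threshold(self):
        obs = scripted_observer([T] * 20 + [F] * 5)
        trials, _ = run_thresholding(obs, 0.6)
        assert letter_score(trials) == (0.30, 0.6, 15)

    def test_partial_credit(self):
        obs = scripted_observer([T] * 5 + [T, T, T, F, F] + [F] * 5)
        trials, _ = run_thresholding(obs, 0.4)
        assert letter_score(trials) == (0.34, 0.4, 3)

    def test_full_credit_to_floor_reaches_floor_exactly(self):
        trials, _ = run_thresholding(deterministic_observer(-10.0), 0.0)
        va, anchor, below = letter_score(trials)
        assert anchor == 0.0 and below == 15
        assert va == pytest.approx(-0.3)

    def test_no_clean_line_scores_none(self):
        obs = scripted_observer([T, T, T, T, F] * 3 + [F] * 10)
        trials, status = run_thresholding(obs, 1.4)
        assert status is Status.OFF_SCALE_HIGH
        assert letter_score(trials) == (None, None, None)


class TestRunTest:
    @pytest.mark.parametrize("threshold, expected", [
        (0.3, 0.30), (0.25, 0.30), (0.9, 0.90), (-0.14, -0.10), (1.06, 1.10),
    ])
    def test_deterministic_observer_recovers_grid_threshold(
            self, threshold, expected):
        result = run_test(deterministic_observer(threshold))
        assert result.ok
        assert result.va_logmar == pytest.approx(expected)

    def test_brute_force_threshold_sweep(self):
        """Perfect-observer recovery over a fine threshold grid: measured
        VA is the smallest 0.1-grid size at or above the threshold."""
        for k in range(-20, 141):
            t = k / 100
            result = run_test(deterministic_observer(t))
            assert result.ok
            assert result.va_logmar == pytest.approx(
                smallest_grid_at_or_above(t)), f"threshold {t}"

    def test_monotone_in_threshold(self):
        vas = [run_test(deterministic_observer(k / 100)).va_logmar
               for k in range(-30, 141)]
        assert vas == sorted(vas)

    def test_scoring_identity_and_quantization(self):
        """Every ok result: va is a multiple of 0.02 and equals
        anchor - 0.02 x letters_below."""
        for seed in range(50):
            obs = PsychometricObserver(ObserverParams(
                threshold_logmar=float(np.random.default_rng(seed).uniform(-0.1, 1.0)),
                slope=8.0, seed=seed))
            r = run_test(obs)
            if not r.ok:
                continue
            assert round(r.va_logmar / 0.02, 6) == pytest.approx(
                round(r.va_logmar / 0.02))
            assert r.va_logmar == pytest.approx(
                r.anchor_logmar - 0.02 * r.letters_correct_below_anchor)
            assert -0.3 - 0.1 - 1e-9 <= r.va_logmar <= 1.6 + 1e-9

    def test_five_scored_letters_per_thresholding_size(self):
        for seed in range(20):
            obs = PsychometricObserver(ObserverParams(0.4, slope=10, seed=seed))
            r = run_test(obs)
            per_size = {}
            for t in r.trials:
                if t.phase is Phase.THRESHOLDING:
                    per_size.setdefault(t.size_logmar, []).append(t)
            assert all(len(v) == 5 for v in per_size.values())

    def test_termination_bound(self):
        """Any observer terminates within the line-presentation budget."""
        max_lines = (1.9 / 0.1) + (1.9 / 0.2) + 2
        for seed in range(30):
            obs = PsychometricObserver(ObserverParams(
                0.5, slope=2.0, guess_rate=0.4, lapse_rate=0.3, seed=seed))
            r = run_test(obs)
            n_range = sum(t.phase is Phase.RANGE_FINDING for t in r.trials)
            n_lines = len({t.size_logmar for t in r.trials
                           if t.phase is Phase.THRESHOLDING})
            assert n_range + n_lines <= max_lines

    def test_off_scale_high_carried_in_result(self):
        r = run_test(deterministic_observer(5.0))
        assert r.status is Status.OFF_SCALE_HIGH
        assert r.va_logmar is None


class TestRefresh:
    def test_single_lapse_refreshed_matches_clean_run(self):
        """One attention lapse at 0.6, answered correctly on refresh,
        leaves the score identical to the lapse-free run."""
        cfg = StaircaseConfig(refresh_enabled=True)
        clean = run_test(deterministic_observer(0.3), cfg)
        lapse_script = ([T, T, T, F]                      # range finding
                        + [T, F, T, T, T] + [T]           # 0.6 + refresh
                        + [T] * 15 + [F] * 5)             # 0.5..0.3, 0.2
        lapsed = run_test(scripted_observer(lapse_script), cfg)
        assert lapsed.va_logmar == clean.va_logmar == 0.30
        refreshed = [t for t in lapsed.trials if t.refreshed]
        assert len(refreshed) == 1 and refreshed[0].correct

    def test_refresh_disabled_by_default(self):
        script = ([T, T, T, F]
                  + [T, F, T, T, T] + [T] * 15 + [F] * 5)
        r = run_test(scripted_observer(script))
        assert not any(t.refreshed for t in r.trials)
        # without refresh the first-line error triggers an ascent to a
        # clean 0.7 line: anchor 0.7, credit 4 + 5 + 5 letters below it
        assert r.va_logmar == pytest.approx(0.42)
        assert r.anchor_logmar == pytest.approx(0.7)

    def test_refresh_never_applies_to_all_wrong_lines(self):
        cfg = StaircaseConfig(refresh_enabled=True)
        r = run_test(deterministic_observer(0.3), cfg)
        assert r.va_logmar == 0.30
        assert not any(t.refreshed for t in r.trials)


class TestConfigValidation:
    def test_scoring_identity_enforced(self):
        with pytest.raises(DomainError):
            StaircaseConfig(score_increment=0.05)

    def test_start_must_sit_inside_grid(self):
        with pytest.raises(DomainError):
            StaircaseConfig(start_logmar=2.0)

    def test_off_grid_values_rejected(self):
        with pytest.raises(DomainError):
            StaircaseConfig(start_logmar=0.803)


def test_exhausted_script_raises_fixture_error():
    with pytest.raises(ScriptExhaustedError):
        run_test(scripted_observer([T, T]))
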