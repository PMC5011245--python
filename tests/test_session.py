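import re

import numpy as np
import pytest

from coadapt.session import (
    ADVANCE_C,
    CONTINUE_U,
    END_SESSION,
    RESET_T,
    ArmState,
    SessionConfig,
    SessionState,
    TrialEvent,
    c_accuracy,
    controller,
    run_c_repetition,
    run_session,
    run_t_module,
    run_u_repetition,
)
from coadapt.synthetic import SyntheticUser, SyntheticUserSpec, simulate_closed_loop

from conftest import ScriptedSource

RIGHT, LEFT = "right", "left"


def small_config(**kw):
    base = dict(seed=0)
    base.update(kw)
    return SessionConfig(**base)


@pytest.fixture(scope="module")
def t_state():
    state = SessionState(config=small_config())
    run_t_module(state, ScriptedSource())
    return state


class TestConfig:
    def test_t_schedule_duration_under_three_minutes(self):
        c = SessionConfig()
        assert c.t_duration_s == pytest.approx(14 * 12.5) == pytest.approx(175.0)
        assert c.t_duration_s < 180.0

    def test_invalid_criterion_ordering_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(reset_level=0.8, advance_level=0.7)


class TestArm:
    def test_steps_and_clamps(self):
        arm = ArmState(angle_deg=175.0, min_deg=0, max_deg=180, step_deg=5.0)
        assert arm.step(+1) == 180.0
        assert arm.step(+1) == 180.0  # clamped
        assert arm.step(-1) == 175.0


class TestTModule:
    def test_collects_238_balanced_portions(self, t_state):
        t_events = [e for e in t_state.events if e.module == "T"]
        assert len(t_events) == 238
        assert sum(e.cue == RIGHT for e in t_events) == 119
        assert sum(e.cue == LEFT for e in t_events) == 119
        assert all(not e.feedback_given and e.predicted is None for e in t_events)

    def test_fits_filter_store_classifier(self, t_state):
        assert t_state.spatial_filter is not None
        assert len(t_state.store) == 238
        assert t_state.bank.count() == 238
        assert t_state.classifier is not None
        assert t_state.phase == "U"

    def test_same_seed_replays_identically(self):
        runs = []
        for _ in range(2):
            state = SessionState(config=small_config(seed=7))
            run_t_module(state, ScriptedSource())
            runs.append(state)
        a, b = runs
        assert [e.cue for e in a.events] == [e.cue for e in b.events]
        assert np.array_equal(a.spatial_filter.weights, b.spatial_filter.weights)


@pytest.fixture(scope="module")
def u_state():
    state = SessionState(config=small_config())
    src = ScriptedSource()
    run_t_module(state, src)
    run_u_repetition(state, src)
    return state


@pytest.fixture(scope="module")
def c_state():
    state = SessionState(config=small_config())
    src = ScriptedSource()
    run_t_module(state, src)
    for _ in range(6):
        run_u_repetition(state, src)
    run_c_repetition(state, src)
    return state


class TestURepetition:
    def test_processes_170_portions(self, u_state):
        u_events = [e for e in u_state.events if e.module == "U"]
        assert len(u_events) == 170
        assert len(u_state.u_records[0]) == 170
        assert u_state.u_history and u_state.u_total == 1

    def test_scripted_source_decoded_perfectly(self, u_state):
        assert u_state.u_history[0] == 1.0

    def test_gated_feedback_moves_arm_five_degrees(self, u_state):
        u_events = [e for e in u_state.events if e.module == "U"]
        prev = u_state.config.arm_start_deg
        for e in u_events:
            if e.feedback_given:
                expected = np.clip(prev + (5.0 if e.predicted == RIGHT else -5.0), 0.0, 180.0)
                assert e.arm_angle == pytest.approx(expected)
            else:
                assert e.arm_angle == pytest.approx(prev)
            prev = e.arm_angle

    def test_thresholds_accumulate_only_in_u(self, u_state):
        assert u_state.thresholds.counts[RIGHT] + u_state.thresholds.counts[LEFT] == 170


class TestController:
    def _state_with_history(self, history, u_total=None, **kw):
        state = SessionState(config=small_config(**kw))
        state.u_history = list(history)
        state.u_total = len(history) if u_total is None else u_total
        return state

    def test_reset_when_last_three_below_40(self):
        assert controller(self._state_with_history([0.35, 0.38, 0.39])) == RESET_T

    def test_advance_when_last_six_above_70(self):
        assert controller(self._state_with_history([0.2] * 4 + [0.75] * 6)) == ADVANCE_C

    def test_continue_otherwise(self):
        assert controller(self._state_with_history([0.5, 0.6, 0.55])) == CONTINUE_U

    def test_end_after_max_u(self):
        assert controller(self._state_with_history([0.5] * 16)) == END_SESSION

    def test_boundaries_are_strict(self):
        # dyadic criterion levels make the means exactly representable
        at_reset = self._state_with_history([0.375] * 3, reset_level=0.375, advance_level=0.75)
        assert controller(at_reset) == CONTINUE_U
        at_advance = self._state_with_history([0.75] * 6, reset_level=0.375, advance_level=0.75)
        assert controller(at_advance) == CONTINUE_U


class TestCRepetition:
    def test_parameters_frozen(self, c_state):
        w_before = c_state.spatial_filter.weights.copy()
        model_w = c_state.classifier.weight_vector.copy()
        thr = (c_state.thresholds.threshold(RIGHT), c_state.thresholds.threshold(LEFT))
        run_c_repetition(c_state, ScriptedSource())
        assert np.array_equal(c_state.spatial_filter.weights, w_before)
        assert np.array_equal(c_state.classifier.weight_vector, model_w)
        assert (c_state.thresholds.threshold(RIGHT), c_state.thresholds.threshold(LEFT)) == thr
        assert c_state.thresholds.frozen

    def test_five_targets_per_repetition(self, c_state):
        trials = {e.trial_id for e in c_state.events if e.module == "C" and e.repetition == 0}
        assert len(trials) == 5

    def test_labels_point_toward_target(self, c_state):
        cur = c_state.config.arm_start_deg
        for e in c_state.events:
            if e.module == "C":
                expected = RIGHT if e.target_deg > cur else LEFT
                assert e.cue == expected
            if e.arm_angle is not None:
                cur = e.arm_angle

    def test_perfect_user_reaches_all_targets(self, c_state):
        assert c_state.c_targets_reached == 5 * c_state.c_reps_done
        assert all(e.scored for e in c_state.events if e.module == "C")

    def test_timeout_scores_first_60_decisions(self):
        # stubborn source always produces "left": with the arm confined to
        # [90, 180] and targets strictly above, it never reaches any target
        state = SessionState(
            config=small_config(arm_min_deg=90.0, arm_start_deg=90.0, timeout_s=120.0)
        )
        src = ScriptedSource()
        run_t_module(state, src)
        run_u_repetition(state, src)
        state.arm.angle_deg = 90.0  # park at the lower limit: all targets above
        stubborn = ScriptedSource(fixed_class=LEFT)
        run_c_repetition(state, stubborn)
        c_events = [e for e in state.events if e.module == "C"]
        per_trial = {}
        for e in c_events:
            per_trial.setdefault(e.trial_id, []).append(e)
        assert state.c_targets_reached == 0
        for events in per_trial.values():
            assert len(events) == 237  # decisions at 2.0, 2.5, ..., 120.0 s
            assert sum(e.scored for e in events) == 60
            assert all(e.scored for e in events[:60])
            assert not any(e.scored for e in events[60:])


class TestCAccuracy:
    @staticmethod
    def ev(cue, predicted, scored=True, trial=0, offset=2.0):
        return TrialEvent("C", 0, trial, offset, cue, predicted=predicted,
                          distance=1.0, scored=scored)

    def test_reached_trial_all_windows(self):
        events = [self.ev(RIGHT, RIGHT, offset=2.0 + 0.5 * k) for k in range(20)]
        assert c_accuracy(events) == 1.0

    def test_timeout_trial_counts_scored_only(self):
        events = [self.ev(RIGHT, RIGHT if k < 30 else LEFT, scored=k < 60, offset=2.0 + 0.5 * k)
                  for k in range(240)]
        assert c_accuracy(events) == pytest.approx(0.5)

    def test_pooled_mixture(self):
        reached = [self.ev(RIGHT, RIGHT, trial=0, offset=2.0 + 0.5 * k) for k in range(10)]
        timeout = [self.ev(LEFT, RIGHT if k < 20 else LEFT, scored=k < 60,
                           trial=1, offset=2.0 + 0.5 * k) for k in range(100)]
        # scored: 10 correct (reached) + 60 of timeout of which first 20 wrong
        assert c_accuracy(reached + timeout) == pytest.approx((10 + 40) / 70)

    def test_no_scored_windows_rejected(self):
        with pytest.raises(ValueError):
            c_accuracy([self.ev(RIGHT, RIGHT, scored=False)])


class TestFullSession:
    def test_skilled_scripted_session_advances_to_c(self):
        state = run_session(small_config(), ScriptedSource())
        assert state.u_total == 6  # perfect accuracy -> advance at first chance
        assert state.c_reps_done == 3
        assert state.phase == "done"

    def test_phase_sequence_grammar(self):
        # T (U+ (T U+)*) C{0,3}; checked over randomized synthetic users
        for s in range(4):
            cfg = SessionConfig(seed=1000 + s, max_u=6, advance_window=3,
                                reset_window=2, arrows_t=4, arrows_per_u=4,
                                arrow_duration_s=4.0, c_repetitions=2, targets_per_c=2,
                                timeout_s=20.0, timeout_scored_s=10.0)
            user = SyntheticUser(SyntheticUserSpec(erd_depth=0.5, seed=2000 + s), cfg.sample_rate)
            state = run_session(cfg, user)
            seq = "".join(
                e.module for i, e in enumerate(state.events)
                if i == 0 or state.events[i - 1].module != e.module
            )
            assert re.fullmatch(r"T(UT)*UC?", seq), seq
            assert state.u_total <= cfg.max_u
            assert state.c_reps_done <= cfg.c_repetitions

    def test_event_log_window_counts(self):
        cfg = SessionConfig(seed=3, max_u=3, advance_level=1.01, reset_level=0.0,
                            arrows_t=4, arrows_per_u=4, arrow_duration_s=4.0)
        user = SyntheticUser(SyntheticUserSpec(erd_depth=0.5, seed=4), cfg.sample_rate)
        state = run_session(cfg, user)
        t_events = [e for e in state.events if e.module == "T"]
        assert len(t_events) == 4 * 5  # 4 arrows x 5 windows of a 4-s trial
        for rep in range(state.u_total):
            assert sum(1 for e in state.events if e.module == "U" and e.repetition == rep) == 4 * 5

    def test_full_session_bit_identical_replay(self):
        logs = []
        for _ in range(2):
            state = simulate_closed_loop(
                SyntheticUserSpec(erd_depth=0.7, seed=11),
                SessionConfig(seed=12, max_u=4, advance_window=3),
            )
            logs.append(
                [
                    (e.module, e.repetition, e.trial_id, e.offset_s, e.cue,
                     e.predicted, e.distance, e.feedback_given, e.arm_angle, e.scored)
                    for e in state.events
                ]
            )
        assert logs[0] == logs[1]
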