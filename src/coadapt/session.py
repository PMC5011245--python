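"""The T/U/C session state machine with flexible-session control.

A session starts with a short no-feedback calibration block (T: 14 balanced
cue trials, 238 portions, first fit of W and the SVM), then iterates
feedback-with-updating repetitions (U: 10 cue trials each, adaptive
thresholds, selective W/SVM updates, cue imbalancing), and — once the
running accuracy criterion is met — freezes all parameters and tests target
reaching (C).  The controller implements the flexibility rules: reset to T
when the mean accuracy of the last 3 U repetitions drops below 40%, advance
to C when the mean of the last 6 exceeds 70%, hard stop after 16 U
repetitions.

Feedback is the flexion/extension of a 1-DOF modelled arm: each
above-threshold decision moves the shoulder angle by +/-5 degrees
(up-arrow = right hand = flexion by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptation import (
    CovarianceBank,
    ImbalanceSchedule,
    PortionRecord,
    ThresholdState,
    balance_best,
    gate_feedback,
    schedule_arrows,
    select_best,
    u_accuracy,
    update_classifier,
    update_spatial_filter,
    update_threshold,
)
from .classification import ClassifierModel, TrainingStore, classify, train
from .csp import (
    LEFT,
    RIGHT,
    SpatialFilter,
    compute_csp,
    extract_features,
    normalized_covariance,
)
from .preprocessing import RawSegment, bandpass, car_rereference, drop_channel, extract_windows

__all__ = [
    "SessionConfig",
    "ArmState",
    "TrialEvent",
    "SessionState",
    "run_t_module",
    "run_u_repetition",
    "run_c_repetition",
    "controller",
    "run_session",
    "replay_session",
    "c_accuracy",
    "RESET_T",
    "ADVANCE_C",
    "CONTINUE_U",
    "END_SESSION",
]

RESET_T = "reset_t"
ADVANCE_C = "advance_c"
CONTINUE_U = "continue_u"
END_SESSION = "end"


@dataclass
class SessionConfig:
    """All timing, criterion and geometry constants of a session.

    Defaults are the reference protocol: 14 calibration arrows of 10 s with
    2.5 s rest; 10 arrows per U repetition (so 170 portions each); at most
    16 U repetitions; 40%/3 reset and 70%/6 advance rules; 3 C repetitions
    of 5 targets with a 120 s timeout of which the first 30 s are scored;
    2-s windows every 0.5 s; thresholds at 60% of the mean correct
    distance; 5-degree feedback steps.
    """

    arrows_t: int = 14
    arrow_duration_s: float = 10.0
    rest_s: float = 2.5
    arrows_per_u: int = 10
    max_u: int = 16
    reset_window: int = 3
    reset_level: float = 0.40
    advance_window: int = 6
    advance_level: float = 0.70
    c_repetitions: int = 3
    targets_per_c: int = 5
    timeout_s: float = 120.0
    timeout_scored_s: float = 30.0
    pause_s: float = 5.0
    feedback_step_deg: float = 5.0
    threshold_fraction: float = 0.6
    window_s: float = 2.0
    step_s: float = 0.5
    band_low_hz: float = 8.0
    band_high_hz: float = 30.0
    n_csp: int = 2
    sample_rate: float = 128.0
    arm_min_deg: float = 0.0
    arm_max_deg: float = 180.0
    arm_start_deg: float = 90.0
    reach_tol_deg: float = 2.5
    right_direction: int = +1  # right hand -> flexion (+5 deg); configurable
    reference_channel: str | None = "REF"  # included in CAR, dropped before decoding
    adaptation_enabled: bool = True
    keep_windows: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reset_level >= self.advance_level:
            raise ValueError("reset_level must be below advance_level")
        for name in ("arrows_t", "arrows_per_u", "max_u", "c_repetitions", "targets_per_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def t_duration_s(self) -> float:
        """Scheduled duration of the calibration block (arrows + rests)."""
        return self.arrows_t * (self.arrow_duration_s + self.rest_s)

    @property
    def windows_per_trial(self) -> int:
        from .preprocessing import n_windows

        return n_windows(self.arrow_duration_s, self.window_s, self.step_s)


@dataclass
class ArmState:
    """1-DOF modelled arm: shoulder angle on a 5-degree lattice, clamped."""

    angle_deg: float = 90.0
    min_deg: float = 0.0
    max_deg: float = 180.0
    step_deg: float = 5.0

    def step(self, direction: int) -> float:
        self.angle_deg = float(np.clip(self.angle_deg + direction * self.step_deg, self.min_deg, self.max_deg))
        return self.angle_deg


@dataclass
class TrialEvent:
    """One logged decision (or T-phase portion) of the session."""

    module: str
    repetition: int
    trial_id: int
    offset_s: float
    cue: str
    predicted: str | None = None
    distance: float | None = None
    feedback_given: bool = False
    arm_angle: float | None = None
    scored: bool = True
    target_deg: float | None = None

    @property
    def correct(self) -> bool | None:
        return None if self.predicted is None else self.predicted == self.cue


@dataclass
class SessionState:
    """Everything the engine mutates while a session runs."""

    config: SessionConfig
    rng: np.random.Generator = None  # type: ignore[assignment]
    phase: str = "T"
    u_history: list[float] = field(default_factory=list)  # since last T reset
    u_total: int = 0
    n_resets: int = 0
    thresholds: ThresholdState = None  # type: ignore[assignment]
    bank: CovarianceBank = field(default_factory=CovarianceBank)
    store: TrainingStore | None = None
    spatial_filter: SpatialFilter | None = None
    classifier: ClassifierModel | None = None
    arm: ArmState = None  # type: ignore[assignment]
    events: list[TrialEvent] = field(default_factory=list)
    next_schedule: ImbalanceSchedule | None = None
    u_records: list[list[PortionRecord]] = field(default_factory=list)
    c_targets_reached: int = 0
    c_reps_done: int = 0
    _trial_counter: int = 0

    def __post_init__(self) -> None:
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)
        if self.thresholds is None:
            self.thresholds = ThresholdState(fraction=self.config.threshold_fraction)
        if self.arm is None:
            c = self.config
            self.arm = ArmState(c.arm_start_deg, c.arm_min_deg, c.arm_max_deg, c.feedback_step_deg)


def _preprocess(state: SessionState, raw: RawSegment) -> RawSegment:
    """CAR (including any recorded reference channel, which is then dropped
    so the retained channels stay linearly independent), then band-pass."""
    c = state.config
    seg = car_rereference(raw)
    if c.reference_channel:
        seg = drop_channel(seg, c.reference_channel)
    return bandpass(seg, c.band_low_hz, c.band_high_hz)


def _get_trial(state: SessionState, source, cue: str, duration_s: float) -> tuple[RawSegment, str]:
    """Fetch one trial.  Replay-style sources that carry their own cue
    schedule (``provides_cues`` truthy) override the requested cue."""
    if getattr(source, "provides_cues", False):
        raw, actual = source.next_trial(duration_s)
        return raw, actual
    return source.trial(cue, duration_s), cue


def run_t_module(state: SessionState, source) -> SessionState:
    """Calibration: balanced no-feedback cue block; first fit of W and SVM.

    Presents ``arrows_t`` cues (half right, half left, seeded random
    order), collects 17 portions per trial, initializes the covariance
    bank, computes W from the class-mean covariances, fills the training
    store and trains the first classifier.  No decisions are made and no
    feedback is given.
    """
    c = state.config
    cues = [RIGHT] * (c.arrows_t // 2) + [LEFT] * (c.arrows_t - c.arrows_t // 2)
    state.rng.shuffle(cues)
    covs = []
    rep = state.n_resets
    for cue in cues:
        raw, cue = _get_trial(state, source, cue, c.arrow_duration_s)
        seg = _preprocess(state, raw)
        wins = extract_windows(seg, c.window_s, c.step_s, label=cue, trial_id=state._trial_counter)
        for w in wins:
            covs.append(normalized_covariance(w))
            state.events.append(
                TrialEvent(
                    module="T",
                    repetition=rep,
                    trial_id=state._trial_counter,
                    offset_s=w.offset_s,
                    cue=cue,
                )
            )
        state._trial_counter += 1
    state.bank.extend(covs)
    state.spatial_filter = compute_csp(
        state.bank.class_mean(RIGHT), state.bank.class_mean(LEFT), m=c.n_csp
    )
    state.store = TrainingStore(capacity=len(covs))
    for cov in covs:
        state.store.add(cov, cov.label, extract_features(cov, state.spatial_filter))
    state.classifier = train(state.store)
    state.phase = "U"
    state.next_schedule = schedule_arrows(0, 0, c.arrows_per_u, rng=state.rng)
    return state


def run_u_repetition(state: SessionState, source) -> SessionState:
    """One feedback-with-updating repetition.

    Presents the scheduled (possibly imbalanced) cues, classifies every
    portion with the current W/SVM, gates arm feedback on the adaptive
    thresholds (updated continuously from correct decisions), and at the
    end performs the selective update: B -> BB -> bank -> W_new -> remapped
    and refreshed store -> retrained SVM.  Appends the repetition accuracy
    to the history and schedules the next repetition's cue split from the
    per-class misclassification counts.
    """
    if state.phase != "U" or state.classifier is None:
        raise RuntimeError("run_u_repetition requires a trained state in phase U")
    c = state.config
    sched = state.next_schedule or schedule_arrows(0, 0, c.arrows_per_u, rng=state.rng)
    rep = state.u_total
    records: list[PortionRecord] = []
    for cue in sched.order:
        raw, cue = _get_trial(state, source, cue, c.arrow_duration_s)
        seg = _preprocess(state, raw)
        wins = extract_windows(seg, c.window_s, c.step_s, label=cue, trial_id=state._trial_counter)
        for w in wins:
            cov = normalized_covariance(w)
            feat = extract_features(cov, state.spatial_filter)
            dec = classify(state.classifier, feat)
            rec = PortionRecord(
                covariance=cov, cue=cue, decision=dec, window=w if c.keep_windows else None
            )
            gated = gate_feedback(state.thresholds, rec)
            if gated:
                state.arm.step(c.right_direction if dec.predicted == RIGHT else -c.right_direction)
            update_threshold(state.thresholds, rec)
            records.append(rec)
            state.events.append(
                TrialEvent(
                    module="U",
                    repetition=rep,
                    trial_id=state._trial_counter,
                    offset_s=w.offset_s,
                    cue=cue,
                    predicted=dec.predicted,
                    distance=dec.distance,
                    feedback_given=gated,
                    arm_angle=state.arm.angle_deg,
                )
            )
        state._trial_counter += 1
    acc = u_accuracy(records)
    state.u_history.append(acc)
    state.u_total += 1
    state.u_records.append(records)
    mis_right = sum(1 for r in records if r.cue == RIGHT and not r.correct)
    mis_left = sum(1 for r in records if r.cue == LEFT and not r.correct)
    if c.adaptation_enabled:
        bb = balance_best(select_best(records))
        if bb:
            w_new = update_spatial_filter(state.bank, bb, state.spatial_filter, m=c.n_csp)
            state.classifier = update_classifier(state.store, w_new, bb)
            state.spatial_filter = w_new
    state.next_schedule = schedule_arrows(mis_right, mis_left, c.arrows_per_u, rng=state.rng)
    if hasattr(source, "advance_learning"):
        source.advance_learning()
    return state


def controller(state: SessionState) -> str:
    """Flexible-session transition rule, applied after every U repetition.

    Advance to C once the mean of the last ``advance_window`` accuracies
    (since the last reset) exceeds ``advance_level``; reset to T when the
    mean of the last ``reset_window`` falls below ``reset_level``; end the
    session after ``max_u`` total repetitions; otherwise continue U.
    """
    c = state.config
    h = state.u_history
    if len(h) >= c.advance_window and float(np.mean(h[-c.advance_window :])) > c.advance_level:
        return ADVANCE_C
    if len(h) >= c.reset_window and float(np.mean(h[-c.reset_window :])) < c.reset_level:
        return RESET_T
    if state.u_total >= c.max_u:
        return END_SESSION
    return CONTINUE_U


def _reset_to_t(state: SessionState) -> None:
    """Clear all adapted state (bank, store, W, SVM, thresholds, history)."""
    state.bank.clear()
    state.store = None
    state.spatial_filter = None
    state.classifier = None
    state.thresholds.reset()
    state.u_history = []
    state.n_resets += 1
    state.phase = "T"


def run_c_repetition(state: SessionState, source) -> SessionState:
    """One frozen-parameter target-reaching repetition (5 targets).

    Thresholds, W and the classifier are no longer updated.  Each 0.5 s a
    portion is classified; above-threshold decisions move the arm 5 degrees.
    The per-window "correct" label is the direction toward the target
    (flexion if the target is above the current angle).  A target is
    reached when the arm is within half a feedback step; otherwise the
    trial times out after 120 s.  Reached trials are fully scored; timeout
    trials are scored on their first 30 s only.
    """
    if state.classifier is None or state.spatial_filter is None:
        raise RuntimeError("C requires trained parameters")
    c = state.config
    state.phase = "C"
    state.thresholds.frozen = True
    rep = state.c_reps_done
    lattice = np.arange(c.arm_min_deg, c.arm_max_deg + 1e-9, c.feedback_step_deg)
    max_decisions = int(round((c.timeout_s - c.window_s) / c.step_s)) + 1
    scored_decisions = int(round(c.timeout_scored_s / c.step_s))
    for _ in range(c.targets_per_c):
        candidates = lattice[np.abs(lattice - state.arm.angle_deg) > c.reach_tol_deg]
        target = float(candidates[state.rng.integers(len(candidates))])
        trial_events: list[TrialEvent] = []
        reached = False
        for k in range(max_decisions):
            offset = c.window_s + k * c.step_s
            label = RIGHT if (target - state.arm.angle_deg) * c.right_direction > 0 else LEFT
            raw, _ = _get_trial(state, source, label, c.window_s + 2.0)
            seg = _preprocess(state, raw)
            wins = extract_windows(seg, c.window_s, c.step_s, label=label, trial_id=state._trial_counter)
            w = wins[len(wins) // 2]  # central window, clear of filter edges
            feat = extract_features(normalized_covariance(w), state.spatial_filter)
            dec = classify(state.classifier, feat)
            rec = PortionRecord(covariance=None, cue=label, decision=dec)
            gated = gate_feedback(state.thresholds, rec)
            if gated:
                state.arm.step(c.right_direction if dec.predicted == RIGHT else -c.right_direction)
            trial_events.append(
                TrialEvent(
                    module="C",
                    repetition=rep,
                    trial_id=state._trial_counter,
                    offset_s=offset,
                    cue=label,
                    predicted=dec.predicted,
                    distance=dec.distance,
                    feedback_given=gated,
                    arm_angle=state.arm.angle_deg,
                    target_deg=target,
                )
            )
            if abs(state.arm.angle_deg - target) <= c.reach_tol_deg:
                reached = True
                break
        if reached:
            state.c_targets_reached += 1
        else:
            for ev in trial_events[scored_decisions:]:
                ev.scored = False
        state.events.extend(trial_events)
        state._trial_counter += 1
    state.c_reps_done += 1
    return state


def c_accuracy(events: list[TrialEvent]) -> float:
    """Pooled C-phase accuracy over scored decisions (reached trials in
    full, the first 30 s of timeout trials)."""
    scored = [e for e in events if e.module == "C" and e.scored and e.predicted is not None]
    if not scored:
        raise ValueError("no scored C-phase decisions")
    return sum(e.correct for e in scored) / len(scored)


def run_session(config: SessionConfig, source) -> SessionState:
    """Drive a complete flexible session: T, U repetitions under the
    controller, and (if reached) the C repetitions.  Returns the final
    state with the full event log."""
    state = SessionState(config=config)
    run_t_module(state, source)
    while True:
        run_u_repetition(state, source)
        action = controller(state)
        if action == CONTINUE_U:
            continue
        if action == RESET_T:
            if state.u_total >= config.max_u:
                state.phase = "done"
                break
            _reset_to_t(state)
            run_t_module(state, source)
            continue
        if action == ADVANCE_C:
            for _ in range(config.c_repetitions):
                run_c_repetition(state, source)
            state.phase = "done"
            break
        state.phase = "done"
        break
    return state


def replay_session(config: SessionConfig, source) -> SessionState:
    """Run the decoding pipeline over a recorded session (replay source).

    The recorded cue schedule drives the trials: T on the first
    ``arrows_t`` recorded trials, then as many full U repetitions as the
    recording provides, honoring the controller's reset rule.  C is not
    replayed (its trajectory depended on the original closed loop).
    """
    state = SessionState(config=config)
    run_t_module(state, source)
    while len(source) >= config.arrows_per_u and state.u_total < config.max_u:
        run_u_repetition(state, source)
        action = controller(state)
        if action == RESET_T and len(source) >= config.arrows_t + config.arrows_per_u:
            _reset_to_t(state)
            run_t_module(state, source)
        elif action in (ADVANCE_C, END_SESSION):
            break
    state.phase = "done"
    return state
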