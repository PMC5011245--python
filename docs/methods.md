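# Methods

This note documents the models, algorithms and design choices implemented
in `coadapt`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the bundled simulator does and does not emulate.

## 1. Decoding pipeline

### Preprocessing

Continuous multichannel EEG (reference protocol: 11 sensorimotor channels
at 128 Hz) is processed as:

1. **Common average reference (CAR).** Each sample's cross-channel mean is
   subtracted. Exact CAR leaves the all-ones vector in the null space of
   the channel covariance, which would make the CSP eigenproblem singular.
   Recording setups avoid this by including the reference electrode's
   signal in the average and analysing only the scalp channels;
   `coadapt` reproduces that convention: if a channel named by
   `SessionConfig.reference_channel` (default `"REF"`) is present, it
   enters the average and is then dropped. With plain CAR and no reference
   channel, linear independence of the retained channels is the caller's
   responsibility, and a rank-deficiency error names the offending
   channel.
2. **Band-pass 8–30 Hz**, covering the mu (8–13 Hz) and beta (13–30 Hz)
   rhythms. The filter is a 4th-order Butterworth. Default realization is
   zero-phase (`sosfiltfilt`, effective order 8), appropriate for offline
   replay and simulation; a causal forward-only variant is selectable
   (`zero_phase=False`) when closed-loop latency realism matters. Both
   meet the stated band: passband gain within [0.9, 1.1] and stopband
   gain ≤ 0.1 on steady-state sinusoids (tested).
3. **Windowing.** 2-s portions every 0.5 s, the first ending 2 s after
   trial onset; sample alignment is half-open `[end−w, end)` with 0-based
   indices, so a 10-s trial yields exactly 17 portions, a 14-trial
   calibration block 238, and a 10-trial U repetition 170.

### CSP features

Per-portion covariance is the trace-normalized outer product
C = XXᵀ/tr(XXᵀ) (Ramoser convention). Portions are not mean-centered
first: the band-passed signal is essentially zero-mean, and the pure
outer-product form lets features be recomputed exactly from stored
covariances (this choice changes numbers only at the ~4th decimal).
Class-mean covariances are unweighted means over individually normalized
matrices, so every selected portion counts equally regardless of when it
was recorded.

The spatial filter solves the generalized symmetric eigenproblem
`C̄_right w = λ (C̄_right + C̄_left) w` (scipy `eigh`). Eigenvalues lie in
[0, 1] and the two classes' per-row eigenvalues sum to 1. Rows of W are
sorted by descending right-class eigenvalue; because eigenvector sign is
not identified, each row's sign is fixed so its largest-magnitude entry is
positive, making W reproducible across runs and platforms. Eigen-ordering
by the right class is a convention; ordering by the left class selects the
same component set.

Features are log-normalized variances of the m = 2 most discriminative
rows from each end of the spectrum: for selected row p,
v_p = (W C Wᵀ)_pp and f_p = log(v_p / Σ_q∈selected v_q). The denominator
runs over the selected components only, so features are computable from
the selected rows alone, are invariant to positive rescaling of the
window, and satisfy Σ exp(f) = 1.

### Classifier

A linear soft-margin SVM with misclassification cost C = 1 (libsvm via
scikit-learn, tolerance 1e-6; "soft margin equal to 1" is read as the
standard cost parameter). Decisions carry the signed perpendicular
distance d = (w·f + b)/‖w‖, positive toward "right". A portion exactly on
the boundary (d = 0) is assigned to "right" — an arbitrary but fixed,
documented tie-break.

## 2. The adaptive loop

### Adaptive thresholds

Two independent per-class thresholds gate feedback. Each starts at 0 and
tracks 60% (`threshold_fraction`) of the running mean absolute distance of
*correctly classified* portions of that class, accumulated from the start
of the session. Details fixed here because they change the numbers:

- Accumulation starts with the first U portion — the calibration block
  produces no classifier outputs, hence no distances.
- The comparison is strict (`|d| > threshold`) against the threshold of
  the **predicted** class, and a portion's own distance enters the running
  mean only *after* it has been gated, so the threshold applied to a
  portion reflects strictly prior evidence (causal and reproducible).
- In the C phase the thresholds are frozen; on a calibration reset they
  are cleared to 0 with the rest of the adapted state (the protocol does
  not specify this case; resetting everything restores the "start of
  session" semantics of the running mean).

### Selective updating (B → BB → W_new → SVM_new)

At the end of each U repetition: portions both correct and above threshold
form the B list; B is balanced by removing majority-class elements with
the smallest |d| first (keeping the clearest examples), yielding BB. BB
covariances join the session-wide covariance bank (calibration portions
plus every previous BB); W_new is the CSP of the bank's per-class means,
so W stabilizes as the bank grows. The SVM training set (fixed capacity,
238 entries, stores covariances not raw signals) is remapped under W_new,
BB portions replace the **oldest same-class** entries (class-matched
oldest-first eviction keeps the store size and class balance constant,
matching the constant-retraining-cost motivation for replacement; the
original system's exact eviction rule is not documented), and the SVM is
retrained. An empty B (or BB) skips the update entirely — W, store and
classifier are untouched — but the repetition's accuracy is still
recorded.

### Cue imbalancing

The next repetition's cue split is proportional to the per-class
misclassification shares: `arrows_right = floor(10·mis_R/(mis_R+mis_L))`,
clipped to [3, 7] of 10; zero misclassifications gives 5:5. The floor
(rather than round-half-up) realizes the monotone map consistent with the
worked splits (20:10 errors → 6:4). Presentation order is a seeded
permutation.

## 3. Session state machine

Constants live in `SessionConfig` (defaults = the reference protocol):
T = 14 arrows × (10 s + 2.5 s rest) = 175 s of scheduled calibration;
U repetitions of 10 arrows; `max_u` = 16; reset when the mean accuracy of
the last `reset_window` = 3 repetitions (since the last reset) is below
`reset_level` = 0.40; advance to C when the mean of the last
`advance_window` = 6 exceeds `advance_level` = 0.70; both comparisons
strict. C = 3 repetitions × 5 targets, 120-s timeout per target,
parameters frozen.

Feedback is a 1-DOF arm: shoulder angle on a 5° lattice clamped to
[0°, 180°], `+5°` for an above-threshold "right" decision (right hand =
flexion; the hand→direction mapping is configurable, the display geometry
is not part of the protocol). A target counts as reached when the angle is
within 2.5° (half a feedback step — guarantees reachability on the
lattice). The per-portion "correct" label in C is the direction toward the
target evaluated before the portion's feedback; portions after reach are
not scored. Decisions run every 0.5 s in all phases. C accuracy pools
reached-target trials in full plus the first 60 decisions (30 s) of
timeout trials — beyond that, a user who has given up invalidates the
label derivation.

Sessions replay bit-identically given the config seed and a deterministic
EEG source; `coadapt simulate` writes a manifest sufficient to reproduce
every output byte-for-byte.

## 4. Evaluation statistics

- **Chance level** from the confusion-matrix marginals:
  p₀ = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)]/N², robust to imbalanced cue
  presentation (which the imbalancing module makes the norm).
- **Adjusted accuracy and confidence bound**: p̂ = (TP+TN+2)/(N+4),
  p_l = p̂ − z₁₋α/₂ √(p̂(1−p̂)/(N+4)) with z₀.₉₇₅ = 1.959964 (double
  precision, not 1.96, for bit-stable tests); the accuracy is significant
  iff p₀ < p_l.
- **ITR**: Wolpaw two-class formula,
  bits/decision = 1 + p·log₂p + (1−p)·log₂(1−p), times 120 decisions/min
  (one decision per 0.5 s). 120/min reproduces the published per-session
  rates from their printed accuracies to within 0.05 bits/min. Accuracy
  below 0.5 reports 0 with a warning.
- **Peak accuracy**: the maximum over within-trial time points of the
  across-trial accuracy at that offset.
- **r² maps**: one modified periodogram (Blackman–Harris window) per 2-s
  portion, no sub-segmentation; bin power sums the ordinates whose
  frequencies fall in half-open 2-Hz intervals tiling 8–30 Hz (11 bins);
  r² is the squared Pearson correlation between per-portion bin power and
  a ±1 class dummy. Constant-power cells define r² = 0 with a warning.

## 5. The synthetic user

`SyntheticUserSpec` defines a generative model of two-class motor-imagery
EEG, built to exercise exactly the structure the decoder exploits and
nothing more:

- **Sources.** Two lateralized sensorimotor sources (C3-like at channel
  index 2.5, C4-like at 7.5 of 11) emit mu (10 ± 1.5 Hz) plus beta
  (20 ± 3 Hz) band-limited Gaussian noise, mixed to the montage through
  smooth unimodal (Gaussian) topographies.
- **ERD.** Imagery multiplies the *contralateral* source's amplitude by
  (1 − `erd_depth`): right-hand imagery suppresses the C3-like source.
  `erd_depth` = 0 makes the class distributions identical (chance-level
  user); 0.8 is an easily decodable skilled user; ~0.4 gives the
  mid-range accuracies where thresholds and imbalancing actually engage.
- **Amplitude dynamics.** Each source is modulated by a slow log-normal
  envelope (correlation time 3 s, log-sd 0.5) and a per-trial log-normal
  gain (log-sd 0.5), emulating the waxing/waning and the factor-2–3
  trial-to-trial power variability of real sensorimotor rhythms. This is
  what gives simulated sessions realistic *trial-level* decision
  correlation: without it, 170 near-independent window decisions per
  repetition concentrate accuracy unrealistically tightly around its
  mean, and chance-level sessions would essentially never trip the 40%
  reset rule that real chance-level users do trip.
- **Background.** Four 1/f (pink) noise sources mixed through fixed smooth
  random topographies, scaled to `noise_level` (default 1.0) times the
  unattenuated rhythm power — computed from the *reference* (no-ERD)
  rhythms so the background carries no class information. Per-channel
  white amplifier noise (`sensor_noise` = 0.05 of rhythm power) keeps the
  channel covariance full rank, as real amplifiers do.
- **Reference channel.** An ear-lobe-like `REF` channel (background +
  amplifier noise, no rhythm content) is appended by default and consumed
  by the CAR-with-reference convention above.
- **Nonstationarities.** `drift` migrates the source topographies along
  the channel axis per trial (slow spatial nonstationarity; used to
  demonstrate the benefit of adaptation over a frozen decoder).
  `learning_rate` increments `erd_depth` after each U repetition,
  emulating a user improving under feedback. `artifact_rate` injects
  Hanning-windowed 20–60 Hz broadband bursts (~0.3 s, 10× rhythm RMS)
  with random channel weights.
- In the C phase the simulator generates an independent 2-s segment per
  decision with the class currently pointing toward the target (the
  desired direction can flip after overshoot, so fixed 10-s cue trials do
  not apply).

**What the simulator does not emulate** — and hence what passing tests do
not establish about real recordings: volume-conduction from a realistic
head model, ocular and cardiac artifacts, resting-state alpha intrusions,
non-Gaussian burst statistics, inter-subject montage variability, and any
genuine user-learning dynamics beyond the scripted ERD ramp. Results on
synthetic sessions validate the *machinery* (bookkeeping, update algebra,
controller logic, statistics), not clinical performance.

## 6. Numerical choices and degenerate inputs

- Covariance symmetry is enforced (`(C+Cᵀ)/2`) before eigendecomposition;
  the composite's positive-definiteness is checked at relative tolerance
  1e-12 and violations raise naming the dominant channel of the null
  direction.
- All-zero windows (zero trace) and zero selected variance raise
  degenerate-input errors rather than producing NaNs.
- Window counts use an epsilon (1e-9 s) guard so exact-fit durations are
  not lost to float rounding.
- Incoming update batches larger than a class's store capacity keep the
  newest and warn.
- Problem sizes in the test suite are scaled to the structure being
  verified: short sessions (4-arrow blocks, 4-s trials) exercise the state
  machine; full-size (14/10-arrow, 10-s) runs verify the 238/170 portion
  arithmetic and the closed-loop properties; stochastic properties
  (resets under chance, adaptation benefit under drift) are majority
  votes over 10 fixed seeds.

## 7. Known limitations

- The replay mode follows the recorded cue schedule, so the cue-imbalance
  scheduler's *requests* are overridden by the recording (a replay cannot
  re-run the closed loop); C phases are not replayed for the same reason.
- No artifact detection or rejection, matching the original protocol; the
  sample covariance is correspondingly artifact-sensitive, and the
  simulator's `artifact_rate` exists precisely to probe that sensitivity.
- Regularized covariance estimation, nonlinear kernels, probability
  calibration and multiclass extensions are out of scope.
- No EDF writer is bundled (reading requires `mne`); fixtures are written
  as CSV + JSON schedules.
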