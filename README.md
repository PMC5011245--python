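# coadapt

A co-adaptive, cue-paced motor-imagery brain–computer interface (BCI)
engine. It decodes two-class sensorimotor EEG (left- vs right-hand motor
imagery) with common spatial patterns (CSP) and a linear support-vector
machine, and wraps that decoder in the full closed-loop training protocol
of an adaptive BCI: adaptive feedback thresholds, selective parameter
updating, cue imbalancing, and a flexible Training / Training-and-Updating /
Classification (T/U/C) session state machine. A synthetic ERD/ERS EEG
generator simulates users of any skill level, so the entire online
protocol can be exercised, tested and evaluated offline.

## Who it is for

Researchers developing or benchmarking adaptive sensorimotor-rhythm BCIs
who need a tested, scriptable implementation of the classic
CSP + SVM co-adaptive loop — for replaying recorded sessions (EDF or CSV),
for simulation studies of adaptation rules, or as a baseline decoder.

## The method

**Decoding.** EEG is re-referenced to the common average (including the
recorded reference electrode, so the scalp channels stay linearly
independent), band-pass filtered to 8–30 Hz, and cut into 2-s portions
every 0.5 s. For each portion the trace-normalized covariance
C = XXᵀ/tr(XXᵀ) is computed. CSP finds the projection W by simultaneous
diagonalization of the class-mean covariances (generalized eigenproblem
C̄_R w = λ(C̄_R + C̄_L) w); features are the log-normalized variances of the
first and last m = 2 rows of Z = WX. A linear soft-margin SVM (C = 1)
classifies the feature vector; the signed perpendicular distance to the
hyperplane drives feedback.

**Adaptation (U phase).** Feedback (±5° of a 1-DOF modelled arm) is given
only when the distance exceeds a per-class adaptive threshold — 60% of the
running mean distance of correctly classified portions. At the end of each
10-arrow repetition (170 portions), the correctly classified,
above-threshold portions (B list) are class-balanced by dropping the
weakest majority examples (BB list); their covariances join the session
bank, W is recomputed from the bank means, the SVM training set is
remapped under the new W, the BB portions replace the oldest same-class
entries, and the SVM is retrained. Cue presentation for the next
repetition is biased (up to 7:3) toward the class most misclassified.

**Flexible session.** One T block (14 balanced arrows, 238 portions, first
fit of W/SVM), then up to 16 U repetitions: mean accuracy of the last 3
below 40% resets to T; mean of the last 6 above 70% advances to the C
phase (3 repetitions of 5 reaching targets, 120-s timeout, all parameters
frozen).

**Evaluation.** Confusion-matrix chance level
p₀ = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)]/N², adjusted accuracy
p̂ = (TP+TN+2)/(N+4) with confidence lower bound
p_l = p̂ − z₁₋α/₂ √(p̂(1−p̂)/(N+4)) (significant iff p₀ < p_l), Wolpaw
information transfer rate at 120 decisions/min, per-time-point peak
accuracy curves, and channel × frequency-bin r² discriminability maps
(Blackman–Harris periodogram, 2-Hz bins over 8–30 Hz).

## Worked example

Simulate two training sessions of a moderately skilled synthetic user
(ERD depth 0.7) and print the session report:

```sh
$ coadapt simulate --seed 7 --sessions 2 --erd-depth 0.7 --out runs/
session 1: phase=done u_reps=6 resets=0 c_reps=3
session 2: phase=done u_reps=6 resets=0 c_reps=3
 session  u_peak_pct  u_mean_pct  u_p0_pct  u_significant  u_itr_bits_per_min  c_mean_pct  c_p0_pct  c_significant  c_itr_bits_per_min
       1   86.666667   79.803922 49.558824           True           32.900115   82.283465 50.372001           True           39.139624
       2   96.666667   90.882353 51.156863           True           67.153850   86.505190 50.155051           True           51.497537
```

Both sessions pass the 70% criterion after the minimum six U repetitions
and advance to the C phase. Columns mirror the standard report: peak and
mean U-phase accuracy (%), the confusion-matrix chance level (≈50% here
because cue presentation stayed near-balanced), significance of the
accuracy–chance difference at α = 0.05, and the information transfer rate
in bits/min at 120 decisions/min; the last four columns repeat the
statistics for the frozen-parameter C phase. `runs/` also receives one
line-delimited JSON event log per session and a `manifest.json` that
reproduces the run bit-identically.

The same engine is importable as a library (sklearn-style estimators
included):

```python
from coadapt import CspSvmDecoder, SyntheticUserSpec, simulate_closed_loop

state = simulate_closed_loop(SyntheticUserSpec(erd_depth=0.8, seed=3))
print(state.u_history)        # per-repetition U accuracies
```

Other commands: `coadapt replay` (run the decoder over a recorded EDF/CSV
session), `coadapt evaluate` (summary table from logs), `coadapt r2map`,
`coadapt make-fixtures`.

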