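# Methods

This note records the models implemented by `fleximu`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Orientation estimation

Roll and pitch are estimated by a first-order discrete complementary
filter. Accelerometer tilt (`atan2(ay, az)` for roll,
`atan2(−ax, √(ay²+az²))` for pitch) is trustworthy at low frequency but
noisy during motion; integrated gyro rates are smooth but drift. The
filter blends them with a constant `A ∈ [0, 1]`:

    roll[n] = A·(roll[n−1] + gx[n]·ΔT) + (1−A)·roll_raw[n]

- `A` defaults to 0.98 and is configurable. At 21 Hz this corresponds to
  a crossover time constant of roughly `A·ΔT/(1−A) ≈ 2.3 s`: faster
  attitude changes are tracked by the gyro, slower ones by gravity.
- ΔT comes from the sample time stamps (ms → s), not a nominal rate.
- The first sample initializes roll/pitch to the raw accelerometer
  angles, so a static pose starts unbiased. Whether the original device
  initialized to zero or to the first reading is unknowable from the
  outside; initializing from the reading avoids a startup transient that
  would contaminate the first windows of every session.
- A numerically zero acceleration vector (free fall) has no defined
  tilt; the filter then keeps the previous filtered angles and warns.
  `raw_angles` on an exactly zero vector raises instead, because there
  is no previous state to fall back on.
- Under zero angular velocity and a constant raw angle θ the filter
  output follows the closed form `(1 − Aⁿ)·θ`; the test suite pins this
  to 1e−9 and uses it as the correctness oracle for both the streaming
  and the vectorized (lfilter-based) implementations, which agree to
  1e−10 per sample.

Yaw is deliberately absent: with the rotation axis parallel to gravity,
the accelerometer carries no heading information, and no magnetometer is
modeled.

## Features and the smoothed-difference kernel

The per-sample feature vector is
`[ax, ay, az, f1, f2, gx, gy, gz, roll, pitch]`; flex channels stay raw
ADC counts (no resistance→angle calibration — the classifiers only need
a monotone correlate of flexion). Classifier inputs are `Ns×10` windows
(row `i` is `v[n−Ns+i]`, oldest first) scaled per channel by
`(x − xmin)/(xmax − xmin)` with bounds from training data only; a
degenerate channel (`xmax = xmin`) maps to 0. Test-set values may fall
outside [0, 1] by construction; that leakage-free behavior is asserted,
not "fixed".

The flex-smoothing kernel is derived, not hard-coded: a 3-tap Gaussian
with σ = 0.9 normalized to unit sum, fully convolved with the difference
filter [−1, 1], scaled by −2, rounded half-away-from-zero to one
decimal. This yields `[0.5, 0.4, −0.4, −0.5]` (unrounded:
±0.519, ±0.443). Normalizing before differencing and rounding
half-away-from-zero are the two choices that reproduce those
coefficients exactly; both are configurable off for analysis. The kernel
sums to zero (constants are annihilated) and is antisymmetric, so
reversing it only flips signs and leaves `Sflex` unchanged.

`Sacc` is the summed L1 norm of acceleration over the window. `Sflex`
convolves `f1 + f2` (convolution is distributive, so this equals the sum
of the filtered channels) at fully-overlapping positions only — no
boundary padding is invented — and sums absolute responses. The lower
summation limit of the criteria is read as `n − Ns` (the window length);
the streaming implementation computes both criteria for all window
positions with moving sums and is tested against the scalar definitions
at 1e−12.

## Classifiers

**Two-criteria tree.** `DecisionTreeClassifier` (scikit-learn) on
`(Sacc, Sflex)` with gini impurity, best-split strategy, max depth 3.
Trees train on consecutive non-overlapping fragments of the training
files and are tested on single-sample-shifted fragments, mirroring how
the windowed classifiers are evaluated. Ties at a split threshold go to
the ≤ (left) branch.

**Temporal CNN.** Input `Ns×10` (channels last), then
conv(16 filters, width 3, ReLU) → max-pool(2) →
conv(8 filters, width 3, ReLU) → global average pool → dense(16, ReLU) →
head. The exercise head is a 6-way softmax; the anomaly head a 1-unit
sigmoid (1 = correct exercising, binarized at 0.5 with ties counting as
correct). Both heads share the trunk, so the anomaly model can
warm-start from exercise weights; the tests check the warm start is
never worse than cold start at equal budget (median over 5 seeds). The
network is implemented directly in numpy (im2col convolutions, explicit
backward pass verified against finite differences at 1e−4, Adam with
lr 0.001 and the task-matched cross-entropy loss). At `Ns = 21` the
model holds 1,134 parameters; a 5,000-parameter cap is enforced to stay
within a microcontroller-class memory footprint.

Training batches are assembled the way the evaluation protocol
fragments data: each matrix comes from a uniformly random training file
at a uniformly random valid start offset. One master seed fans out (via
`SeedSequence`) to the weight-init and batch generators, so equal seeds
give bitwise-identical loss traces. Default schedule: batch 64, 50
epochs × 100 steps; the study-scale acceptance checks use 30 epochs ×
100 steps, which is past the point where the qualitative orderings
stabilize on the synthetic data.

## Scoring

`SCORE(n)` counts the binary per-instant classifications from the first
full window onward; the display shows
`floor(numstars/(fs·p·Tmax)·SCORE(n))` stars. The margin of error
`p = 0.8` means 80% correct time earns the maximum. Because more than
`p` of a session can be correct, the raw floor can exceed `numstars`;
the display clamps at `numstars = 5` (a perfect score is five stars,
never six). Star count is therefore monotone non-decreasing within a
session. Star updates are evaluated per classified sample and displayed
per second by the CLI.

## Synthetic data generator

The generator is the package's stand-in for the original four-person
recording study and defines the conditions under which the evaluation
harness is exercised: 4 subjects, 292 sessions of which 96 are
anomalous, durations uniform in 79 ± 19 s, 21 Hz sampling.

Each exercise class is a periodic kinematic template: attitude
(roll/pitch) oscillations at a class frequency (0.45–0.8 Hz — slow,
assisted movements), a yaw-rate waveform, a gravity-consistent
accelerometer model (gravity rotated into the sensor frame by the
instantaneous attitude, plus a linear-motion term at twice the movement
frequency), and class-specific flexion waveforms quantized to integer
ADC counts. Attitude is synthesized directly and differentiated for the
gyro channels, so the complementary filter has a recoverable ground
truth. Noise is additive Gaussian: σ = 0.2 m/s² (accel), 0.02 rad/s
(gyro), 8 counts (flex). Gravity is 9.81 m/s². The six templates are
pairwise distinguishable — for every pair of classes at least one
channel's per-session amplitude differs by ≥ 3 pooled standard
deviations under the default subject variation (the weakest pair sits
near 5) — which is what makes high pooled cross-validation accuracy
achievable at all.

Two design choices matter most and were made deliberately:

- **Anomalies.** "Rest" holds the subject's resting pose with sensor
  noise only. "Low motion" models a patient who is *not doing the
  prescribed exercise* but still moves: residual amplitude is drawn per
  session from U(0.15, 0.7) of the class template, and the rhythm is
  aimless — attitude and flexion get independent random frequencies and
  phases instead of the template's coupled waveform. A pilot version
  that scaled the intact class waveform to a fixed 10% made the
  two-criteria tree nearly perfect (the anomaly boundary collapsed onto
  the two summed magnitudes) while being maximally hostile to a
  waveform-reading classifier — the opposite of how the two models
  compare on real recordings. Overlap in summed magnitude with broken
  channel coupling restores the realistic contrast: the sums are
  ambiguous, the shape is not.
- **Subject individuality.** Each subject carries fixed multipliers for
  amplitude groups and frequency (spread `subject_variation = 0.12`,
  clipped), a resting pose offset, a flex-baseline shift (σ = 300
  counts), and a habitual phase. Correct sessions additionally draw a
  vigor factor U(0.8, 1.15). These are what make leave-one-subject-out
  evaluation genuinely harder than pooled 5-fold: the tests verify that
  raising the variation degrades LOSO accuracy strictly and faster than
  pooled accuracy.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: flex-sensor nonlinearity and step-response
decay, sensor drift and dropped samples, the actual spectral content of
human exercise (pure sinusoids plus white noise is far cleaner than real
movement), tremor and spasticity, within-session fatigue, and the real
anomalous-behavior catalogue beyond the two canonical modes. Absolute
accuracies on synthetic data are therefore optimistic; only the
qualitative orderings (CNN > tree on anomalies, 5-fold > LOSO, ablation
effects) are treated as meaningful, and those are what the acceptance
tests assert.

## Evaluation protocol

Files are the unit of splitting; windows never cross file boundaries.
5-fold plans shuffle files with a seed and partition them (sizes differ
by at most one); LOSO plans have one fold per sorted subject id. The
split is not stratified by class or subject. Per fold, the scaler and
model see training files only (a file-identity guard raises on leakage);
testing uses stride-1 overlapping windows of every test file. Exercise
experiments use correct sessions only (a whole-file exercise label on a
rest-mode anomaly would be meaningless); anomaly experiments use all
files with the binary correctness label, the positive class being
"correct exercise". Ablation physically narrows the input matrix and
retrains from scratch — the sensor is absent at training time, as a
simplified glove would be. The tree only consumes `(Sacc, Sflex)`, so
ablations that do not touch acceleration or flex leave it unchanged;
`noaccel`/`noimu` reduce it to `Sflex` alone.

Metrics follow the standard definitions (precision, recall, f1,
accuracy), support-weighted across classes for the 6-way task; fold
aggregation reports the sample mean and (n−1)-denominator standard
deviation. Confusion matrices are row-normalized by true-class
cardinality; zero-support rows are emitted as zeros with a warning
rather than NaN.

Problem sizes in the packaged checks: the study-scale acceptance tests
run the full default dataset (292 sessions) for three seeds at 30×100
training steps; the subject-variation ordering test uses 48-session
datasets at three variance settings. Both report medians across seeds.

## Known limitations

- The exact layer parameters of the original on-device networks are not
  recoverable from the available description; the architecture here is a
  faithful small default under the published footprint, not a replica.
- The two-criteria tree's published weakness relative to the CNN is
  reproduced through the anomaly model's design (magnitude overlap with
  broken coupling); a different anomaly catalogue could change the gap's
  size, though not the direction under these conditions.
- `read_session` accepts only the package's own CSV dialect; no
  compatibility reader for external deposits is included.
- Scores stream per sample; the original device's display cadence
  (sample vs second) is unknown, so the CLI displays per second while
  evaluating per sample.
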