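# Methods

This note records the models implemented in `walkrec`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Signal model and preprocessing

The input is a 6-axis stream (tri-axial accelerometer, m/s²; tri-axial
gyroscope, rad/s) at a nominal 100 Hz. `validate_rate` reports the median
inter-sample interval and the fraction of gaps deviating from 10 ms; the
pipeline does not resample irregular input, it only flags it.

Attitude is tracked by a unit quaternion q mapping sensor-frame vectors
into an ENU Earth frame (z up; a face-up resting device reads +g). Each
step blends gyro integration with a normalized gradient step on the
gravity-alignment objective:

q_t = q_{t−1} + γ(−μ∇f/‖∇f‖) + (1−γ)·½ q_{t−1} ⊗ (0, ω_t) Δt, renormalized.

* **γ (default 0.05)** — convex correction weight. Small values reproduce
  conventional complementary-filter behavior: the gyro dominates at sample
  rate while the accelerometer slowly pins roll/pitch. γ=0 is pure
  integration, γ=1 pure gradient descent (used in tests for convergence
  checks).
* **μ (default adaptive)** — gradient step size. When unset, μ_t =
  max(Δt·‖ω‖, 0.01): proportional to the angular rate so the correction
  keeps pace with fast motion, floor-capped at 0.01 so a static device
  still converges (a 60° initial tilt corrects in roughly ten seconds at
  the default γ). The gradient term is not additionally scaled by Δt; any
  such scaling is absorbed into μ.
* **Initial attitude** — identity by default; the pipeline uses the
  accelerometer bootstrap (`q_init="accel"`: align the first accelerometer
  sample with +z), which removes the long convergence transient that
  otherwise corrupts the first windows of every record. Yaw is
  unobservable without a magnetometer and is left arbitrary; the vertical
  channel does not depend on it.
* The accelerometer vector is normalized inside the gradient (the
  objective compares directions); the raw magnitude is kept for
  projection. The quaternion is renormalized after every step. A zero
  gradient (aligned, or zero accelerometer reading) skips the correction
  instead of dividing by zero. The exact 180° misalignment is a stationary
  point of the objective — a measure-zero configuration the integration
  term immediately perturbs away from.

The 9-channel signal (a, a_E = q⊗a⊗q*, ω) is low-pass filtered with a
10th-order Butterworth at 3 Hz (body-motion energy sits below 3 Hz),
realized in second-order sections — a direct-form filter of order 10 is
numerically ill-conditioned. Filtering is causal by default because the
system predicts in real time; zero-phase filtering is available behind a
flag for offline work. Filtering happens after projection, so the
projected channels are filtered like the raw ones.

DC centering subtracts the trailing mean of the previous N=250 samples
(strictly t−1…t−N). During warm-up the mean of the available history is
used and the first sample passes through unchanged, keeping output aligned
with input rather than dropping samples.

Windows are 250 samples (2.5 s) with 50% overlap — a prediction every
1.25 s. A window is labeled with its majority class only if that class
covers ≥ 75% of samples, otherwise discarded; start/stop transitions are
therefore excluded from training and scoring, matching how ambiguous
windows blur both classes.

## Features

21 per-window features. Time domain: mean of a_{E,z}; mean and variance of
‖ω‖; per-axis standard deviations of a and a_E (sample, n−1);
zero-crossing rate of the centered ‖a‖; peak counts of ‖a‖ and a_{E,z}
(strict 3-sample local maxima, optional prominence floor — the same peak
definition used by the peak-valley baseline); Joanes–Gill *type-3* skewness
and kurtosis (b₁ = g₁((n−1)/n)^{3/2}, b₂ = (g₂+3)((n−1)/n)² − 3).
Frequency domain: statistics of the one-sided FFT magnitude spectra of
‖a‖ and a_{E,z} over the rectangular (untapered) window, DC bin excluded
since the signal is centered — amplitude-weighted mean and spread, median
(first bin reaching half the cumulative amplitude), mode (argmax, ties
toward the lower frequency for determinism), and the type-3 kurtosis of
the amplitude sequence.

Two deliberate readings of ambiguous definitions, both recorded here:
the "energy" features are plain means as defined (a signed mean for
a_{E,z}), with a `energy_squared` switch offering the conventional
sum-of-squares form; the "standard deviation of the mean frequency" is
implemented as the amplitude-weighted spectral spread around the mean
frequency (the alternative reading — variability of the mean across
windows — is not a per-window quantity). The zero-crossing rate is
computed on the ‖a‖ channel after removing its window mean: the norm is
non-negative, so an uncentered zero-crossing count would be identically
zero; the window mean is used rather than the trailing moving average
because inside a single window the trailing filter is almost entirely
warm-up.

## Elastic distances

Full DTW uses the symmetric step pattern with closed endpoints and
absolute-difference local cost, returning the accumulated optimal cost
P(π) with its path; the mean-per-step score is used only when comparing
paths. Subsequence DTW (SDTW) is a separate dynamic program: asymmetric
step pattern — steps (1,0), (1,1), (1,2) in (query, reference), so each
query element is consumed exactly once — with open begin and end on the
reference. The accumulated cost is divided by the query length, the
asymmetric pattern's natural normalization, giving per-query-sample
distances comparable across prototypes. Queries are the first 125 samples
of a 250-sample training pattern (a `middle` option exists); at normal
cadence 1.25 s spans a bit more than one full step cycle, which is what a
prototype should represent. The DP is iterative, O(n·m) per pair, and the
batched variant runs one query against many references simultaneously
(vectorized over the reference axis), which is what makes the n×n distance
tables and the mapping affordable.

## Prototype selection

All three strategies return *real* training patterns, halved into queries,
with distinct source indices:

* **SVM support vectors** — an RBF SVM on the raw 250-sample patterns
  under Euclidean geometry; the support vectors are the margin patterns.
* **PAM k-medoids** — classical Kaufman–Rousseeuw build (greedy
  cost-minimizing additions) and swap (exchange while total assignment
  cost strictly decreases) phases over the asymmetric SDTW table
  D[i,l] = d_SDTW(pattern_i as reference, half of pattern_l as query).
  Clustering is global (label-blind); a per-class run is a caller choice.
* **Supervised summarization** — maximize F(S̃) = #{patterns whose
  best-matching prototype shares their class}. Exhaustive enumeration for
  tiny k (guarded at 10⁶ subsets); breadth-first hill climbing over the
  one-swap neighborhood (deterministic given the start, F non-decreasing);
  or simulated annealing with acceptance min(1, exp(ΔF/T)), geometric
  cooling α=0.95, 50·k proposals per temperature, initial T set so a
  unit-score drop accepts with probability ≈0.8, best-ever state returned,
  fully seeded. The schedule defaults are ordinary SA practice; nothing in
  the method depends on them finely.

Ties (nearest prototype, medoid choice, equal-F subsets) always break
toward the lowest pattern index, making every search deterministic given
its inputs.

## Classifiers, ensembles, CNNs

Classical models (random forest, RBF/linear SVM, gradient boosting, kNN,
Gaussian naive Bayes, and a boosted-decision-tree stand-in for C5.0 —
exact C5.0 is proprietary; AdaBoost over depth-3 trees has comparable
semantics) are fit with grid search under stratified 10-fold CV, features
standardized inside the pipeline. The decision threshold is fixed at 0.5.

Training sets are balanced before fitting: undersampling keeps 70% of the
negative windows plus an equal number of positives (with the published
class counts — 1730 negatives of 7886 windows — this reproduces the
2422-instance, 30.7% training split); the CNN oversampling mode regrows
windows at 75% overlap and resamples the minority class to parity.

The two CNN architectures are fixed: valid-padding stride-1 conv1d + ReLU,
non-overlapping max-pooling, dropout 0.2, dense layers
(a: 3×10 conv, 3×10 conv, pool, dense 128, dense 2 — 158,176 parameters;
b: 3×5 conv, pool, 3×10 conv, pool, dense 1024, dense 2 — 627,894).
Parameter accounting is (kernel·in_channels+1)·out_channels for
convolutions and (in+1)·out for dense layers, and the instantiated
network's array sizes must agree with the accounting. Training is softmax
cross-entropy with Adam at 10⁻³ (the study fixes epochs 64, batch 128 and
dropout 0.2 but not the optimizer; Adam at its conventional rate is the
unsurprising choice), seeded He-normal initialization, implemented
directly in numpy — the networks are small enough that a framework is not
needed, and the forward/backward passes are exercised by the tests.

Ensembles: weighted averaging p_e = w_RF·p_RF + w_SVM·p_SVM with
w_i = |c_i|/(|c_RF|+|c_SVM|) from logistic-regression coefficients fit on
out-of-fold probabilities; stacking fits an arbitrary top-layer model on
the same two-column table. Bottom-layer predictions must carry fold
identifiers — their absence is treated as evidence of in-fold leakage and
rejected.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not biomechanics. Walking: vertical Earth-frame acceleration as a
3-harmonic comb at the step frequency (drawn uniformly 1.5–2.5 Hz unless
fixed) with decaying weights and common phase — giving the peaky
heel-strike morphology — with amplitude 2–6 m/s², horizontal sway at half
the step rate, white accelerometer noise (0.3 m/s² default). The device
orientation follows a band-limited random-walk angular rate (10°/s RMS
default, tripled during gesticulation) integrated with the exact
quaternion exponential; the gyroscope output is that same body rate, so
the attitude problem posed to the estimator is solvable and the stored
true quaternions allow direct tracking-error assertions. Gesticulation:
low-pass-filtered Gaussian acceleration below 3 Hz at walking-like
amplitude but with no sustained harmonic comb — the classic false-positive
hazard for peak-valley step counters, which the baseline test
demonstrates. Records concatenate walking/gesture/static segments with
stop-and-go transitions so the 75% purity rule and the discarded class are
exercised.

Not emulated: per-person gait idiosyncrasy beyond seed jitter, changes of
carrying position mid-record, sensor bias/temperature drift, and real
pocket dynamics. Passing the pipeline tests on this generator shows the
machinery is correct and that the two routes separate structurally
periodic from aperiodic motion; it does not certify accuracy figures on
recorded human data.

## Problem sizes and runtime choices

The end-to-end evaluation uses 60 synthetic records (two to four 5–15 s
segments each, ≈1000–1100 usable windows), a 70/30 train/test split by
windows, and the balanced training rule above. Prototype selection for the
shape route runs on a pool of at most 300 balanced training patterns (the
pairwise SDTW table is quadratic; enlarging the pool was verified not to
change the outcome materially), and the default prototype strategy is the
support-vector route, the strongest of the three here as in the original
study. These sizes keep the whole evaluation within a few minutes on one
CPU while leaving every stage statistically meaningful.

## Known limitations

* Yaw is unobservable (no magnetometer); only roll/pitch-dependent
  quantities are meaningful downstream.
* The causal Butterworth and trailing centering introduce ~0.5–2.5 s of
  transient at record starts and activity transitions; transition windows
  that survive the 75% rule are genuinely ambiguous and dominate the
  residual error of both routes.
* SDTW's elastic matching absorbs tempo differences by design, which also
  makes slow smooth gestures partially confusable with gait — the
  perceptual-aliasing ceiling of the shape route; the feature route does
  not share it.
* The C5.0 stand-in and the unspecified-by-the-study CNN optimizer are
  documented approximations, not re-implementations.
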