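# Methods

This note records the models, assumptions, parameter choices and
numerical conventions behind `myoknn`, in the spirit of the methods
documentation of packages like statsmodels or msprime: what the code
computes, what the defaults mean, and what a passing test does and does
not establish.

## Signal model and the linear envelope

The controller consumes 8-channel sEMG sampled at 200 Hz. The only
feature used is the linear envelope: per-channel absolute value (window
length 1, i.e. no windowed aggregation) followed by a second-order
low-pass Butterworth filter with 1 Hz cut-off. The discrete filter is
obtained by bilinear transform (`scipy.signal.butter`), which pre-warps
so the −3 dB point falls exactly at the cut-off; filtering is causal
with zero initial conditions, matching a streaming real-time
implementation. Consequences tests rely on: unity DC gain, magnitude
1/√2 at 1 Hz, ≈ 0.0100 at 10 Hz (closed form 1/√(1+(f/f_c)⁴)), and a
start-up transient of a few hundred milliseconds — all steady-state
assertions skip the transient. Channels are filtered independently with
identical coefficients.

## Instance-based classification

A model is a labelled reference matrix plus (k, metric, weighting).
Supported metrics: Manhattan, Euclidean, Chebyshev (Minkowski p = 1, 2,
∞) and Mahalanobis with the inverse of the *pooled* (not per-class) 8×8
sample covariance. Weightings: uniform or w = d^(−e), e ∈ {½, 1, 2, 3};
the class with the largest weight sum over the k nearest references
wins. With k = 1 the sort is replaced by a minimum search; the two paths
are label-equivalent by construction and by property test.

Conventions the literature leaves open, fixed here once:

- **Zero distance under inverse weighting** — an exact-match neighbour
  wins outright; several disagreeing exact matches resolve by unweighted
  majority among themselves, then label-alphabet order. This avoids
  division by zero while preserving exact-match intuition.
- **Vote ties** — smallest summed distance among tied classes, then
  label-alphabet order.
- **Ties at the k-th rank** — stable data order keeps the first seen.
- **Ill-conditioned covariance** (condition number > 1e12) — ridge
  1e−6 · trace/8 added to the diagonal with a warning (1e−6 when the
  trace vanishes); pseudo-inverse as last resort.

## Proportional control

Intensity is assumed proportional to the envelope magnitude, defined as
the arithmetic mean over the 8 channels. Training (full-intensity
exertions only) yields the rest baseline t₀ = mean rest magnitude and
per-class maxima m_max[c] = mean class-c magnitude; the mean is the
implemented aggregator throughout (median/max would be alternatives).
Prediction: magnitude m ≤ t = g·t₀ → rest with scale 0; otherwise the
query is divided by its magnitude (shape normalization — the signal
shape is assumed intensity-invariant within a gesture) and classified
against *normalized non-rest* references, because an above-threshold
query may only receive a non-rest label. The scale is the linear map
s(m) = (m − m₀)/(m_max − m₀) clamped to [0, 1], with offset m₀ = t/v
(v = ∞ disables the offset). Offline cross-validation, by contrast,
keeps rest as an ordinary class and skips normalization: it scores
full-intensity classification only.

Choices worth flagging: the scaling magnitude is taken from the raw
query, not the normalized one (normalization exists solely to make
classification magnitude-invariant); s is clamped rather than
extrapolated above m_max; t₀ = 0 (perfectly silent rest) disables the
threshold with a warning. Defaults g = 2.5 and v = 5 are the values
carried into online use after pilot tuning; both are plain config keys.

## Prototype reduction

DSM and LVQ3 generate exactly M prototypes — memory determinism is the
point, so |output| = M holds for every dataset, order and seed.
Initialization: one prototype per class at the class centroid (classes
in sorted label order), remaining M − C slots filled round-robin over
classes, drawn uniformly without replacement within each class from a
seeded generator (with replacement, plus a warning, if a class is too
small). The correction phase runs I full passes in stable dataset order
(an optional seeded shuffle exists for order-robustness testing) with
the standard competitive-learning updates reward(p, x): p += α(x − p)
and penalize(p, x): p −= α(x − p), α = 0.01 fixed.

Per sample: DSM penalizes the nearest prototype if its label differs
and rewards the nearest same-label prototype (if any); agreement changes
nothing. LVQ3 takes the two nearest (p₀, p₁): both matching → both
rewarded at ε·α (ε = 0.1); exactly one matching *and* the sample inside
the relative-distance window min(d₀/d₁, d₁/d₀) > (1−w)/(1+w), w = 0.3 →
reward the match, penalize the other. w and ε are the classic LVQ3
values; neither is prescribed by the method definition. Nearest-
prototype ties keep the first in stable order; coincident zero distances
count as inside the window.

Distances use squared-Euclidean minimum searches (no sorting), so a run
evaluates exactly I·N·M prototype distances — an instrumented counter
asserts this identity, making the linear-in-N complexity an exact count
rather than a benchmark.

## Validation

Leave-one-group-out over repetition blocks: one fold per block, the
Mahalanobis covariance refit per fold on training data only, and a
leakage assertion that no block id crosses the split. k may not exceed
n minus the largest block size. Grid search returns the full tidy fold
table plus the argmax configuration; ties prefer the smallest k, then
the metric order euclidean, manhattan, chebyshev, mahalanobis (declared
convention). DSM-kNN evaluation reduces each fold's training split
individually before classifying the held-out block.

Baselines: ridge regression on one-hot targets scaled by training
intensity (closed-form solve, λ = 1.0 default, intercept included and
penalized), and RR-RFF with the classic random Fourier feature map
z(x) = √(2/D)·cos(Wx + b), W ~ N(0, σ⁻²), b ~ U[0, 2π), D = 200,
σ from the median pairwise-distance heuristic. These are deliberately
plain reference implementations, not tuned competitors.

## Synthetic world

The generator emulates the capture protocol: per gesture, R repetitions
of 400 samples (2 s at 200 Hz), each (class, repetition, intensity)
capture one block; default 5 classes × 3 repetitions at full intensity
= 6000 training vectors. A sample is i·a_c plus per-channel Gaussian
noise rectified at zero (envelopes are non-negative; this is a
rectified, not renormalized-truncated, Gaussian — a log-normal option
exists). Each default pattern a_c has a dominant channel pair with small
cross-talk; power grasp and pointing share a dominant channel so the
plausible confusion structure is present. Pattern magnitudes ≈ 0.45 with
σ = 0.1 keep one-third-intensity exertions above the default rest
threshold, so all three protocol levels are reachable, while raising g
reproduces the misclassification-as-rest failure mode at low intensity.

What this world does *not* contain: motion-unit dynamics, fatigue,
electrode shift, limb-position effects, or inter-subject variability.
Green tests therefore establish algorithmic correctness and the claimed
internal identities (reduction rate, operation counts, accuracy
preservation on separable data), not human-subject performance; the
simulated study's success rates are qualitative (instance-based methods
above the regression baselines, low intensity hardest) and are not
comparable to published human numbers.

The raw-signal generator amplitude-modulates unit Gaussian noise by
i·a_c, so rectify + low-pass recovers i·a_c·√(2/π) in steady state —
used to exercise the envelope path end to end.

## Protocol simulation

Schedules enumerate every (gesture, level, method, repetition)
combination once — 4·3·4·2 = 96 and 6·3·3·2 = 108 in the canonical
configurations — and spread each (method, level) cell round-robin over
the four session quarters (seeded rotation, shuffled within quarter), so
method and level counts per quarter are exactly balanced whenever the
cell size divides 4, and nearest-balanced with a warning otherwise. The
trial loop scores success when the controller's (label, scale) matches
the target gesture with |scale − level| ≤ margin continuously for the
dwell time before timeout. Dwell 1.5 s, timeout 10 s and margin 0.2 are
package defaults — the criterion's shape is standard, its constants are
not prescribed — and the margin is defined in scale space. The simulated
user's interface exposes only (gesture, level, n_samples), so controller
identity cannot leak into user behaviour (double-blind surrogate); its
execution noise combines a per-trial intensity wobble with per-sample
channel noise.

## Known limitations

- The synthetic world is far more separable than real sEMG; absolute
  accuracies near 1.0 say nothing about real electrodes.
- Mahalanobis uses a single pooled covariance; class-conditional
  covariances are out of scope.
- kNN regression, windowed/frequency-domain features, IMU compensation
  and simultaneous multi-DOF control are deliberately not implemented.
- The LVQ3 window/epsilon and all protocol constants are declared
  conventions; results depending on them should be read as properties of
  this implementation, not of the method family.
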