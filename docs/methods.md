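# Methods

This note records the models, parameter choices and numerical conventions
behind `pilotmind`, and what the synthetic benchmark does and does not show.

## Synthetic EEG generator

Each mental state (NE, CA, DA, SS) contributes one contiguous block of
signal. A block is a fixed linear mixture of spatially whitened sources with
a 1/f^a temporal spectrum (default a = 1), plus a small white sensor-noise
floor (1 µV std). The sources are *exactly* whitened per block — empirical
covariance equal to the identity — so the block's spatial covariance equals
the configured class covariance by construction rather than only in
expectation. This was chosen deliberately: 1/f temporal correlation leaves
few effective samples, so sample covariances of merely variance-normalized
sources converge slowly (≈15 % relative Frobenius error after 300 s), and
exact imposition makes the generator's ground truth unambiguous.

Default class covariances share one fixed orthogonal mixing basis; each
non-NE state boosts a disjoint block of 5 sources by a factor e^0.6 ≈ 1.8 in
power. Under the affine-invariant metric this puts every pair of class
covariances at distance ≥ √5·0.6 ≈ 1.34, i.e. the classes are separable by
covariance geometry alone — the structure the tangent-space pipeline
assumes. CA/DA/SS consequently carry elevated mean power relative to NE.
Default durations (NE 240 s, others 20 s each) reproduce the ~80 % NE
imbalance of multi-pilot flight-task recordings. Defaults: 20 channels
(10-20 names, Fp1 first) at 256 Hz, both config-overridable.

Artifacts are injected per one-second epoch with the configured
probabilities and annotated (type, channels, onset):

| type   | default rate | default amplitude | shape |
|--------|-------------:|------------------:|-------|
| blink  | 0.15 | 120 µV | 300 ms squared half-sine, frontally weighted |
| muscle | 0.05 | 40 µV  | 200 ms high-frequency burst on 3 channels |
| spike  | 0.03 | 900 µV | 20 ms biphasic transient on one channel |
| flat   | 0.01 | 0.05 µV | channel replaced by near-zero noise for the epoch |

Spikes default above the 700 µV gate so their ground truth is unambiguous.
The generator does not attempt biophysical forward modelling, ocular
dipoles, inter-subject variability, or non-stationary background dynamics.
Passing the synthetic benchmark therefore demonstrates that the pipeline
recovers covariance-coded class structure and annotated artifacts under
realistic amplitudes and imbalance — not that it reaches any particular
accuracy on real recordings.

## Preprocessing

* FIR band-pass: windowed-sinc (Hamming), order from the 3.3/Δf rule with
  transition width max(low, 2 Hz), odd length, applied forward–backward
  (zero phase, squared magnitude response). Rationale: epoch labels must
  stay aligned with the signal, so linear phase alone is not enough.
* Epoching: one-second non-overlapping windows; majority per-sample label,
  ties broken toward the label appearing earlier in the window; trailing
  partial windows discarded so every epoch has identical shape.
* Amplitude gate: an epoch is dropped iff *any* channel's peak-to-peak
  exceeds 700 µV or falls below 1 µV (per-channel-any, not channel-averaged;
  this choice changes drop counts and is the stricter reading).
* Undersampling: every class reduced to the minority count by seeded uniform
  sampling without replacement, original epoch order preserved.

## Rejection-threshold learning

Per channel, candidate thresholds from a grid are scored by k-fold CV
(default 5): the mean time course of training epochs passing the candidate
is compared (MSE) with the pointwise median time course of validation
epochs; scores sum over folds. A candidate admitting no training epoch
scores infinite. The landscape is piecewise constant in the candidate (only
the admitted set matters) and shallowly noisy between plateaus, so the
selected threshold is the *largest* candidate scoring within 5 % (relative)
of the minimum — keep the most data unless rejecting clearly helps. Grid
search replaces Bayesian optimization: on the coarse grids used here it is
exhaustive, deterministic, and directly testable.

Applying a model: channels with peak-to-peak above their threshold are bad;
if the bad fraction exceeds the consensus κ = 0.5 the epoch is dropped,
otherwise the worst min(n_bad, ρ = 4) channels are interpolated
(inverse-square-distance weights over the good channels' montage positions)
and the epoch kept. Every epoch receives exactly one logged decision
(kept / repaired / dropped). The full cleaning chain is gate → reject/repair
→ blink removal → reject/repair, with thresholds re-learned in the second
pass by default (the cleaned data distribution has changed; re-learning is
the conservative option, and reusing the first model is supported).

## Blink removal

Epochs are concatenated in time and decomposed with seeded FastICA
(components = channels, unit-variance whitening, tol 1e-4, max 1000
iterations). Components whose absolute Pearson correlation with the Fp1 time
course is ≥ 0.8 are zeroed and the signal reconstructed, then re-split into
epochs. EEG backgrounds are nearly Gaussian, so the full unmixing is only
weakly identifiable and FastICA routinely stops at the iteration cap even
though the strongly non-Gaussian ocular component is already separated; the
default therefore proceeds with a warning (`strict=True` raises instead).
Residual frontal correlation with the injected blink time course is < 0.05
in the tests, versus ~0.7 before removal.

## SPD geometry

All matrix functions (square root, log, exp) go through symmetric
eigendecompositions with an eigenvalue floor of 1e-12; for symmetric input
this is exact up to round-off and avoids the balancing issues of general
matrix-function algorithms. The Fréchet mean is the standard fixed-point
iteration in the whitened frame, initial step 1.0, halved whenever the
gradient norm increases, tolerance 1e-8 (relative, Frobenius), max 50
iterations starting from the arithmetic mean. Tangent coordinates are taken
in the whitened convention vec(logm(G^{-1/2} P G^{-1/2})) — the metric at
the base point is then Euclidean, so tangent distances approximate manifold
distances near the mean (verified to < 5 % within radius 0.3).
Vectorization uses the √2 off-diagonal weighting, making it an isometry
between the Frobenius and Euclidean norms.

Epoch covariances use the sample estimator blended with a scaled-identity
target: (1−γ)C + γ·(tr C/n)·I, default γ = 0.05 for the super-trial
matrices, which guarantees positive definiteness.

## Feature pipeline

Order: xDawn fit → super-trial covariances → Fréchet mean → tangent mapping
→ Fisher geodesic filtering → PCA → ANOVA selection. Fisher filtering is
defined in tangent coordinates, so a single tangent mapping serves both it
and the classifier features. All stages are fitted on training folds only
and applied unchanged to validation folds; anything else leaks labels
through the reference mean, the Fisher basis, or the component selection.

* xDawn: per class, filters are the top generalized eigenvectors of
  (P_c P_cᵀ/L, C_x) — evoked-prototype variance against total signal
  variance — stored with unit-norm rows; nfilter = 6 so that the
  super-trial covariance has side 2·K·nfilter = 48 for K = 4 and the
  tangent dimension is 48·49/2 = 1176.
* Fisher geodesic filtering: top K−1 generalized eigenvectors of (S_b,
  S_w^reg), orthonormalized, applied as project-and-back (idempotent). The
  within scatter is shrunk as (1−α)S_w + α(tr S_w/d)I with α = 0.9. The
  heavy default is deliberate: at d = 1176 with a few hundred training
  rows, a lightly regularized S_w inverse memorizes noise directions and
  collapses held-out accuracy (measured: 67 % vs 99 % macro F1 under
  fold-honest CV); with heavy shrinkage the basis is dominated by the
  well-estimated class means.
* Selection: PCA to 60 components (full SVD, deterministic), one-way ANOVA
  F per component, keep the top 40 in original component order. Both
  dimensions are config-exposed; the defaults keep ~all class-mean
  separation while cutting the tree ensembles' input width.

## Classification and scoring

Stratified 5-fold CV (seeded); a group-aware variant by recording identity
is available via the plan object for multi-subject data. Models:
RandomForest(200, entropy), ExtraTrees(200, entropy),
GradientBoosting(100 stages; the friedman_mse split criterion is the
library default), AdaBoost with library defaults, and the soft vote —
argmax of the unweighted mean of RF/ERT/GTB probability outputs, exact ties
resolved toward the lowest class index. Metrics are computed from explicit
one-vs-rest TP/FP/TN/FN counts: precision TP/(TP+FP), recall TP/(TP+FN),
F1 their harmonic mean, overall accuracy the pooled fraction correct, macro
averages unweighted over classes; the per-class F1 standard error is the
across-fold sample standard deviation over √k. Reports keep full precision;
integer-percent display is a formatting choice. Per-class accuracy is not
reported separately — the row-normalized confusion diagonal carries that
information.

## Spectral summaries

Welch PSD with one Hann-windowed segment per one-second epoch, averaged over
the epochs of the requested state; band power integrates PSD bins over
delta (0–4), theta (4–8), alpha (8–12), beta (12–30) and gamma (30–45 Hz)
by rectangle sums over bins in (lo, hi] — the detrended DC bin belongs to no
band, which keeps per-Hz densities comparable across bands — and converts
to dB as 10·log10(power/µV²). Absolute dB values depend on the recording
and reference and are not comparison targets; the module computes maps, not
publication graphics.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: benchmark
4 × 200 one-second epochs at 20 channels/256 Hz (stratified 5-fold,
~1–2 min on one core); artifact-recovery runs on a 220 s recording; the
geometry suite uses 200 random SPD pairs per run. The full multi-pilot
archive (~89k epochs) runs through the identical code path but takes hours,
not minutes.

## Known limitations

* The rejection learner assumes artifacts are amplitude-expressed; low
  amplitude artifacts (e.g. subtle drifts) pass it.
* Near-flat channels caused by hardware dropouts are caught by the 1 µV
  gate only before filtering smears energy into them.
* Inverse-distance interpolation ignores scalp curvature conduction
  (spherical splines would be better on real montages).
* FastICA blink removal needs the blink component to be expressed in the
  surrogate channel; independent ocular channels are not modelled.
* AdaBoost over decision stumps is a weak baseline on these features and is
  reported as such.
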