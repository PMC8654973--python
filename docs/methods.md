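# Methods

`icumotion` implements an analysis pipeline for decoding motor states and
functional outcomes of severely brain-injured ICU patients from wearable
triaxial accelerometry. Because clinical recordings of this kind are not
openly shareable, the package pairs the analysis stack with a synthetic
cohort generator whose ground truth is known; every empirical statement
below is computed by the test suite or `scripts/acceptance.py`.

## Signal model and feature set

Raw streams are sampled at 10 Hz from six extremity sensors (elbows,
wrists, ankles: RE, LE, RW, LW, RA, LA) and one bed-frame sensor, with a
±16 g measurement range. Each axis is passed through a causal 4th-order
Butterworth high-pass filter at f_c = 0.2 Hz to remove the gravity
baseline, then cut into non-overlapping 5-s windows (N ≈ 50 samples).
Seven features are computed per window and root-sum-of-squares (RSS)
levelled across axes:

- **SMA** — trapezoidal mean absolute acceleration,
  `(Δt / (2·5 s)) Σ_{n=1}^{N−1} (|x_{n+1}|+|y_{n+1}|+|z_{n+1}|+|x_n|+|y_n|+|z_n|)`.
  A constant 1 g on all axes gives 0.01·49·6 = 2.94 g at N = 50.
- **HLF_h / HLF_l** — RSS of per-axis medians after 4th-order Butterworth
  high-/low-pass filtering at 2.5 Hz within the window.
- **MFR** — RSS of per-axis median frequencies: the smallest one-sided DFT
  bin frequency at which cumulative power reaches half the total. The
  one-sided spectrum uses raw `|X_k|²` without interior-bin doubling; the
  half-power scan is insensitive to this for tonal content and the
  convention is fixed by the oracle tests. An all-zero axis contributes 0.
- **FDE** — spectral entropy of the full-length DFT power distribution per
  axis, `H = |Σ p log₂ p|`, RSS across axes and scaled by 1/log₂N, so a
  perfectly flat spectrum on all axes attains √3.
- **BPW** — band power over 0.3–3.5 Hz per axis (rectangle rule over bins
  whose center lies in band; at 10 Hz / N = 50 the bins are 0.4–3.4 Hz),
  RSS, scaled by 1/(3.2 Hz).
- **WVL** — summed squared level-2..6 detail coefficients of the db5
  discrete wavelet transform (symmetric extension), RSS across axes. With
  50-sample windows only 2 levels are fully supported; deeper levels are
  boundary-dominated and computed anyway, with a one-time logged warning.
- **PDA** — proportion of 5-s windows whose SMA is at or above the
  0.135 g static/dynamic threshold, one value per sensor per observation
  window, computed at matrix-assembly time.

Filtering is single-pass causal (a zero-phase switch exists); filter state
resets at every missing-data gap, and the start-of-record transient is
accepted. A window overlapping any missing sample yields missing features.

## Bed-motion correction

Where the bed sensor's SMA exceeds 0.135 g and an extremity spike follows
within K = 2 windows (extremity SMA above its trailing rolling median by
3 rolling MADs; 24-window history), the bed values of SMA, HLF and the
energy features are subtracted from the extremity values and the bed MFR
and FDE are added. Corrections falling outside a feature's static
activity range are replaced by seeded uniform draws from that range. The
static ranges are estimated per fit as [0, 97.5th percentile] of each
feature over windows where every extremity sensor is below 0.135 g, and
are serialized with the model; the spike heuristic (K, MAD multiplier,
history length) is configurable. Correction runs on the feature series
before imputation.

## Multiple imputation

Missing features (sensor dropouts, interventions, transport; the
generator's default is ~1.6% per sensor as contiguous gaps) are imputed
m = 9 times per patient under a multivariate-normal model. Columns (7
features × 7 sensors) are made positive with a small shift, Box-Cox
transformed with per-column profile-ML λ, standardized, and augmented with
one lag and one lead copy of every column — the temporal device that lets
a cross-sectional Gaussian model borrow autocorrelation. Each completion
bootstraps the window rows, runs EM for the mean and covariance under MAR
(patterns grouped, ridge 1e-4 on the covariance diagonal), and draws
missing entries from their conditional normal. Observed values are never
altered; back-transformed draws are clipped to the nonnegative domain,
and a sub-1e-6 uniform jitter breaks ties among exact zeros before the
transform (it only affects fitting — observed cells pass through exactly).
EM non-convergence after 100 iterations falls back to conditional draws
with a 10× ridge, logged.

## Models

For each clinical evaluation with sufficient history, an observation row
flattens the preceding window of features: 6 sensors × 7 features × T
timesteps, plus 6 PDA columns (6·7·T + 6 columns). The default ladder of
19 observation windows spans 3 min–24 h (3, 6, 9, 12, 18, 27, 36, 48 min;
1, 1.5, 2, 3, 4, 6, 9, 12, 16, 20, 24 h); the ladder includes the
durations that matter for the case studies (notably 27 min and 6 h) and
is fully configurable.

Columns are normalized with statistics pooled per placement-feature
combination (48 combinations). The default is classical mean/SD
z-scoring: the robust median/IQR alternative (retained as a switch) proved
unstable on zero-inflated burst features, whose near-degenerate IQR
amplifies rare movement windows by orders of magnitude and lets them
dominate the projection. The normalized matrix is reduced with a
supervised linear optimal low-rank projection (LOL): the first direction
is the difference of class means, directions 2..d the leading right
singular vectors of the class-mean-centered data, orthonormalized in
order; d ∈ [2, 20] is a hyperparameter. For designs wider than 64 the
truncated SVD is computed with a seeded randomized algorithm. Components
are made marginally Gaussian by element-wise Yeo-Johnson transforms
(profile-ML λ, then standardization) and classified with unpenalized
maximum-likelihood logistic regression (IRLS); detected separation or
non-convergence triggers a ridge (1e-4) refit, flagged. The positive
class boundary is inclusive at p = 0.5. Endpoints are binary thresholds
of GCSm (> 1..> 5), GOSE at discharge (> 1..> 5) and GOSE at 12 months
(> 1..> 7).

Because smaller-d LOL directions are a prefix of larger-d ones and the
Yeo-Johnson transform is element-wise, the grid evaluator fits the
normalizer, projection and component transforms once per
(split, window, threshold) at the largest d and reuses prefixes, repeating
only the logistic fit — identical results to fitting each d separately
(asserted on exact-SVD designs).

## Evaluation

Patients are partitioned 25 times (5 repeats × 5 stratified folds;
largest-remainder allocation with seeded tie-breaks). GCSm endpoints
stratify by each patient's median observed score (halves rounded up);
outcome endpoints by GOSE. One of the m imputations is drawn with
replacement per split. Out-of-fold probabilities are pooled into a
prediction store feeding: Mann-Whitney AUC with tie half-credit,
confusion-matrix metrics at 0.5 (precision reported as 0 and flagged when
no positive predictions exist), the no-information rate, precision-recall
curves with step-sum average precision, and a flexible calibration curve —
a lowess (local-linear, fraction 2/3, no robustness iterations) smooth of
outcomes on predictions evaluated at the observed predictions, giving the
integrated calibration index (mean |curve − identity|, prediction-density
weighted by construction) and E_max (maximal deviation).

Selection optimism is removed with bootstrap bias-corrected
cross-validation (BBC-CV): 1000 patient-level resamples each select the
best (window, d) on in-bag patients' pooled predictions and score it on
out-of-bag patients; the estimate is the resample mean with a
bias-corrected (BC, no acceleration) percentile 95% interval, the
correction anchored at the metric of the full-data-selected configuration.
Resamples with a single-class out-of-bag set are redrawn up to 10 times,
then dropped and counted. Weighted-rank arithmetic makes the resampled
AUC exactly equivalent to replication. Ties in configuration selection
break toward the shorter window, then smaller d.

## Interpretation

Feature significance of a fitted configuration: per split and LOL
component k, each of the 48 sensor-feature cells scores the mean absolute
loading of its columns times |β_k|; components are aggregated by
summation (preserving the additivity of the linear predictor; a
max-over-components switch exists), then averaged over splits, with
1000-resample bootstrap intervals over splits.

The sliding monitor replays a recording through two detection bundles
(27-min and 6-h windows by default) at 10-min steps anchored to the
recording start, predicting per imputation and bootstrapping a 95%
interval across the m per-imputation predictions (10,000 resamples at
full scale). Crossings of 0.5 are debounced — runs shorter than 2 steps
are absorbed into the preceding state — and paired with the nearest
clinical crossing of the GCSm > 4 boundary to report signed lead times.

## Synthetic cohort generator

Each patient carries a latent continuous-time GCSm trajectory: a ±1-step
semi-Markov chain with exponential dwell times (default mean 3 h),
reflecting bounds at levels 1 and 6, initial level drawn from the
emulated admission distribution. Conditional on level, extremity streams
are a slowly drifting unit-norm gravity orientation (spherical random
walk, ~10-min knots) plus Poisson-scheduled movement bursts plus white
noise (σ = 0.01 g); the bed sensor carries only patient-independent bursts
(2/h, 0.45 g), and an optional coupling constant (default 0) leaks bed
bursts into extremity streams for correction studies.

Bursts are exponentially damped sinusoids (duration 0.5–3 s, τ = dur/2).
The state signal lives in the burst **rate** (5, 15, 40, 100, 250,
600 /h for levels 1..6) and frequency band (0.3–0.8 Hz up to 1.5–4 Hz,
wrists ×1.3 at levels 5–6), while amplitudes are nearly constant
(0.30–0.50 g, non-decreasing): clinically, impaired patients move *less
often*, not proportionally *weaker*, and this design makes the proportion
of dynamic activity the dominant discriminative channel, consistent with
the generator's role of providing a PDA-driven ground truth. No
published per-level activity magnitudes exist for this population, so
these are free parameters fixed once for clear level separability.

GCSm evaluations arrive as a Poisson process (default 9.25/day, the
emulated clinical median) and record the latent level at the evaluation
instant. GOSE outcomes are drawn from a proportional-odds model whose
cutpoints reproduce the emulated cohort's marginal distributions at zero
link strength; the linear predictor is the link strength times the
patient's standardized latent activity (time-weighted mean of
rate×amplitude). Missingness deletes contiguous exponential-length gaps
(mean 5 min), placement- and time-of-day-independent (MAR), capped at 3×
the target fraction. All randomness derives one `SeedSequence` stream per
(patient, purpose), so enlarging a cohort never perturbs existing
patients and identical (config, seed) yields identical cohorts.

What the generator does **not** emulate: biomechanically realistic limb
kinematics, sedation and intervention effects, circadian structure,
orientation calibration error, and EHR idiosyncrasies. Passing tests
therefore demonstrate that the pipeline recovers the structures the
generator encodes — state-dependent activity, MAR gaps, activity-linked
ordinal outcomes — not clinical performance on real patients.

## Scaled study sizes

The desk-scale studies in the test suite and acceptance script use: null
calibration — 100 cohorts of 40 patients, 0.5-h recordings, a dense
evaluation schedule (192/day), a 3-window (3/6/9 min) × 3-d (2/5/8)
GOSE > 3 grid, 2×5 CV splits, 1000 BBC-CV resamples; signal recovery — one
cohort of 60 patients, 2-h recordings, 96 evaluations/day, 9/18/27-min
windows, 5×5 splits; monitor case study — 12 training patients at 14 h and
one case patient with a persistent level-6→2 transition at 8 h, 100
bootstrap resamples. The dense evaluation schedules are the scaled
substitute for multi-day stays: they give each short recording several
usable evaluation points. Imputation recovery uses a 300×49
equicorrelated (ρ = 0.8) log-scale matrix with 5% masking and m = 9.

## Numerical choices and edge cases

Box-Cox/Yeo-Johnson round-trips are exact to 1e-8; zero-variance columns
fall back to λ = 1 and are flagged. Conditional draws outside the Box-Cox
domain invert to the domain floor (0). All-zero axes contribute 0 to MFR
and FDE (avoiding 0/0); an all-zero window yields 0, not an error.
Logistic separation is declared at runaway standardized coefficients
(|β| > 10) or IRLS non-convergence. Zero pooled spread in a normalizer
combination sets its scale to 1, flagged. Empty or all-missing PDA input
yields a missing marker.

## Known limitations

The monitor's lead-time pairing uses the nearest clinical transition,
which can mis-pair when transitions cluster within the debounce scale.
The BC interval anchor (full-data selection) is one of several defensible
choices for BBC-CV. The EM imputer models columns jointly as Gaussian
after Box-Cox; heavily zero-inflated features violate this and are only
protected by the jitter and domain clipping. The calibration smoother's
bandwidth is a documented constant rather than a data-driven plug-in.
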