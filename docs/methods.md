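# Methods

`physofr` implements a complete analysis chain for trial-based olfactory
psychophysiology: from continuous multichannel recordings to a hierarchical
scalar-on-function regression that attributes perceptual ratings to odor
identity, individual rating tendencies, and group-level versus
participant-specific physiological effect patterns.  This note documents
the model, the synthetic study generator, the numerical choices, and the
known limitations.

## The model

For each perceptual dimension (valence, temperature, intensity) the
per-trial score is modeled as

    y_i = a + alpha_{o(i)} + gamma * 1{half_i = 2} + u_{p(i)}
          + sum_c  INT_0^6  x_{ic}(t) [ beta_c(t) + b_{p(i),c}(t) ] dt  + eps_i

where `o(i)` is the trial's odor (categorical fixed effect,
reference-coded), `half_i` the temporal half of the session, `u_p` a
ridge-penalized participant intercept (the "individual rating tendency"),
`x_{ic}(t)` the preprocessed 5 Hz signal of channel `c` (respiration,
respiration-corrected heart rate, corrugator EMG envelope, zygomaticus EMG
envelope) over the 6 s window after odor onset, `beta_c(t)` the group-level
coefficient function, and `b_{p,c}(t)` the participant's smooth deviation
from it (a factor-smooth interaction, centered across participants).

Coefficient functions live on a low-rank thin-plate regression spline basis
(Wood's eigen-truncated construction; a cubic B-spline with derivative
penalty is available via config).  The integral enters the design matrix by
rectangle-rule quadrature on the 30-point grid of 0.2 s bin midpoints
(`row_k = sum_t dt * x(t) * B_k(t)`).

### Penalties and identifiability

* group smooth per channel: second-derivative penalty, unpenalized
  2-dimensional null space (constant + linear), one smoothing parameter per
  channel.  The unpenalized null space gives every group smooth an
  effective-degrees-of-freedom floor of 2, matching how such terms are
  conventionally reported.
* individual smooths: one block per channel containing all participants'
  deviations, expressed on an orthonormal sum-to-zero contrast so the
  deviations average to zero at every time point.  The penalty is the basis
  penalty plus the identity on its null space ("fs"-style), so the whole
  block shrinks to zero as its single shared smoothing parameter grows —
  individual deviations are random effects.
* participant intercepts: ridge (identity) penalty with its own smoothing
  parameter; the global intercept stays unpenalized.
* odor is reference-coded; marginal per-odor estimates are reconstructed
  after fitting and are invariant to the choice of reference.

With 4 channels this yields 9 smoothing parameters (4 group + 4 individual
+ 1 ridge).

### REML estimation

Smoothing parameters minimize the profiled Gaussian restricted-likelihood
criterion

    V(rho) = (n - M_p) log(RSS + pen) + log|X'X + S_lambda| - sum_j r_j rho_j

with `rho_j = log lambda_j`, `M_p` the number of unpenalized coefficient
directions and `r_j` the penalty ranks.  Gradients are analytic
(`d/d rho_j = (n-M_p) lambda_j beta'S_j beta / RSS_pen + lambda_j
tr(A^{-1}S_j) - r_j`); optimization is L-BFGS-B on log-lambda with
multi-start from {1e-3, 1, 1e3} (the criterion is genuinely multimodal on
some data sets) and a dense log-grid fallback for problems with at most two
penalties.  A numerical ridge of `1e-8 * mean diag(X'X)` is added when the
unpenalized design alone is rank-deficient (p > n), far below any
statistical scale.  The final coefficient solve gets one step of iterative
refinement.  Reported quantities follow the penalized-regression standard:
`sigma^2 = RSS/(n - edf)`, Bayesian covariance `V_beta = sigma^2 (X'X +
S_lambda)^{-1}`, per-block edf as the trace of the corresponding block of
`(X'X + S_lambda)^{-1} X'X`.  By default `V_beta` additionally carries the
smoothing-parameter-uncertainty correction (`J Cov(log lambda) J'` with
`J_j = -lambda_j A^{-1} S_j beta` and `Cov` from the inverse restricted-
likelihood Hessian — the "unconditional" intervals of Wood, Pya & Säfken);
it can be disabled via `fit_reml(..., smoothing_uncertainty=False)`.

### Inference

* Whole-smooth Wald-like test: `f' V_f^- f / r` against
  `F(r, n - edf_total)`, where `f = X_b theta` is the term's contribution
  to the fitted values and `V_f^-` a rank-r eigen pseudo-inverse of its
  Bayesian covariance `X_b V_b X_b'` (computed through the equivalent
  K-dimensional eigenproblem).  Working on the fitted-value scale matters:
  the nonzero eigenvalues of `V_f` are `sigma^2` times the per-direction
  shrinkage factors, so rank truncation keeps exactly the directions where
  the penalized fit retains freedom.  A parameter-space truncation keeps
  the weakly-informed wiggly directions instead and was measured to have
  essentially no power against strong simulated effects.  The rank follows
  the established rounding rule for penalized smooths, `r = floor(edf) + 1`
  only when the fractional part exceeds 0.05; taking the ceiling dilutes
  the statistic with a fully-shrunken direction (a 200-replicate null
  simulation rejected at 0.01 instead of the nominal 0.05 with that
  variant).
* Nested model comparison: analysis-of-deviance F statistic
  `[(RSS_r - RSS_f)/(edf_f - edf_r)] / [RSS_f/(n - edf_f)]` with smoothing
  parameters re-optimized for every reduced model.
* Variance decomposition: components are removed in the fixed sequence —
  all individual physiological effects, all group-level physiological
  effects, the individual rating tendency, the odor term — reporting the
  adjusted-R-squared change and the F test at each step.  Adjusted R-squared
  uses the effective degrees of freedom: `1 - (1 - R^2)(n-1)/(n - edf)`.
  The deltas do not sum to the full model's R-squared (intercept and the
  half covariate remain throughout).
* Marginal odor estimates: prediction at the odor of interest with every
  other term averaged over the training data — test half at equal weights,
  participants at equal weights, functional terms at the mean observed
  signal (the emmeans convention).  Zeroing the functional terms instead
  would shift all estimates off the outcome scale whenever the signals have
  a nonzero mean, so estimates are best read as contrasts between odors.
* AIC/BIC use `n log(RSS/n) + penalty * (edf + 1)`, i.e. edf-based
  effective parameter counts, the standard choice for penalized smoothers.
* No multiple-testing correction is applied across the smooth tests (raw
  p-values are reported); a Bonferroni option exists but is off by default.

## Preprocessing

Channel-specific conditioning of the 500 Hz recordings, all zero-phase
(forward-backward) filtering so event-locked timing is preserved:

* ECG: 0.5 Hz high-pass 5th-order Butterworth, 50 Hz notch.  R peaks by
  thresholded local maxima with a 0.25 s refractory constraint;
  instantaneous heart rate is 60/IBI anchored at each interval's closing
  peak, linearly interpolated with constant extrapolation.  A direct
  heart-rate channel can bypass peak detection entirely (the default in
  synthetic mode).
* Respiration: linear detrend, 2 Hz low-pass 5th-order Butterworth.
* EMG: linear detrend, 20-50 Hz band-pass 2nd order, 50 Hz notch,
  rectification followed by a 4 Hz low-pass linear envelope (cutoff is
  config), clipped at zero.

Epochs span [-1, 14) s around odor onset (time 0 = onset, half-open
intervals throughout; onsets too close to a recording edge are dropped with
a log entry).  Respiration and heart rate are baseline-corrected by the
[-1, 0) s mean; EMG is not.  Heart rate is then respiration-corrected: per
participant, pooling trials, OLS of concurrent heart rate on concurrent and
one-sample-lagged respiration (lag = 1 frame at the 500 Hz pre-downsampling
rate, a config knob), keeping the residuals.  Downsampling to 5 Hz is by
non-overlapping 100-sample block means (alias-safe for every channel; the
grid is re-anchored to block midpoints so the first post-onset sample
summarizes [0, 0.2) s).  Finally each (participant, channel) is divided by
its pooled SD across time and trials, preserving within-participant shape.

Stage tags (raw, filtered/epoched, corrected, downsampled, normalized) are
enforced: each operation refuses inputs at the wrong stage.

## Functional QC

Within each channel, every trial curve receives the Fraiman-Muniz depth
`mean_t [1 - |1/2 - F_t(x_i(t))|]` over the pooled trial collection, the
`floor(0.01 n)` least-deep curves are flagged (stable tie-break by trial
order), and a trial flagged in any channel is removed entirely — trials are
the modeling unit, and per-channel missingness would break the design row.
Participants retaining fewer than 8 trials for any odorant are then
discarded.  The depth cut is applied per channel pooled across all
participants.  Note the removal rule operates on the emulated 6-odorant
design; `min_trials` is configurable.

## Perceptual dimensions (EFA)

Each trial rates exactly one of the 8 properties, so the item matrix is
formed at the (participant, odor, repetition) level — 8 property ratings
per row, collected across that cell's 8 presentations — and each trial
inherits its cell's factor scores.  Suitability is checked with Bartlett's
sphericity test and the KMO index; the factor count is the modal vote of
parallel analysis (95th-percentile random-data envelope), the Kaiser
eigenvalue rule, and the scree acceleration factor, with ties broken toward
parallel analysis (default config pins k = 3).  Extraction is minres
(uniquenesses optimized by L-BFGS-B with analytic gradients on the eigen
formulation; ML optional), rotation varimax with Kaiser normalization,
factors ordered by explained variance with the largest-|loading| item
positive.  Scores are regression (Thurstone) scores on standardized items;
when used inside the train/test workflow the standardization constants come
from the training data.

The EFA is fitted on all retained trials (matching the narrative order of
the emulated protocol: dimension reduction precedes the model split); a
leakage-free variant would fit it on training cells only.

## The synthetic study generator

The generator emulates the full study design: 41 participants by default,
96 trials each (6 odorants x 8 properties x 2 repetitions), odors split
into two fixed blocks of 3 with block order randomized per participant,
fully randomized order within block, test half = temporal half of the
session, self-paced ISI fixed at its 15 s minimum (config).

Ground truth per dimension: odor effects fixed at the study's reported
marginal-estimate pattern; half effect; participant intercepts
`N(0, sd_dim^2)`; group coefficient functions as Gaussian-bump mixtures
placed at the observed response landmarks (respiration bump at 1.9 s for
valence, late negative respiration bump and positive EMG bumps for
intensity, none for temperature); individual coefficient-function
deviations as smooth random functions (5-bump basis, i.i.d. normal
coefficients, centered across participants).  Signals are canonical
per-channel shapes (inhalation peak ~1.9 s, heart-rate peak ~1.3 s then
deceleration, corrugator maximum ~2.8 s, zygomaticus late rise) with mild
odor-specific amplitude modulation, a per-participant smooth idiosyncrasy,
a per-trial smooth response-variability component, low-frequency random
drift, and white noise at 500 Hz.  EMG is emitted by default as a 20-50 Hz
carrier amplitude-modulated by the activity envelope (a "direct" mode emits
the envelope itself, used by noiseless end-to-end checks).

The latent score integral uses the 5 Hz block means of the emitted signal
itself, so an independent quadrature over the stored epochs and truth
functions reproduces the emitted scores exactly.  Ratings map a property's
loading-weighted latent vector onto the VAS as
`clip(50 + 20 z, 0, 100)`.  The 8x3 loading truth gives each factor at
least three salient items (a two-item orthogonal factor is not identified
from correlations alone), uses strong loadings for the mirror-pair items
(pleasantness/disgust, warm/cold), and is snapped to its varimax-stationary
orientation so the rotated estimand coincides with the generating truth.
Seeding expands one integer into independent per-participant substreams.

Two emission paths exist: `simulate_trials` (full 500 Hz epochs, exercised
by the preprocessing chain) and `simulate_model_data` (draws the 5 Hz
model-window signals directly, with white-noise variance scaled by the
block size — equivalent in distribution and used for model-level studies).

Amplitude modulation is deliberately mild (about 0.1-0.15 of the effect
size) and trial-level functional variability deliberately substantial
(SD 0.35, matching the wide per-trial scatter of real recordings): if the
signals re-encode odor identity nearly noiselessly, the functional terms
can absorb the odor fixed effect and no decomposition attributes variance
sensibly — a collinearity regime real data does not exhibit.

### What the generator does not emulate

Realistic ECG waveform morphology (a direct heart-rate channel is the
default), respiratory-cardiac coupling beyond the linear correction the
pipeline removes, artifact morphology (spikes, electrode drop-outs) beyond
what the depth screen needs, rater drift over the session, and oblique
factor structure.  Passing tests therefore demonstrate correctness of the
estimation machinery under the assumed generative model, not robustness to
every artifact class in field recordings.

## Problem sizes used by the validation studies

* Coefficient-function recovery: 40 participants x 96 trials, K = 10,
  outcome-noise ladder at {2, 1, 0.25} x the default SD, fitting all three
  dimension models; the integrated squared error summed over the 12 group
  curves must fall monotonically, and the truth must lie inside the 95%
  pointwise band at >= 90% of grid points (pooled over the 12 curves) at
  the lowest noise.  Pooling matters for the stability of the measurement:
  errors within one curve are strongly correlated, so the per-model pooled
  coverage of a single fit has a standard deviation of about 0.07 across
  data realizations, versus about 0.02 for the 12-curve pool.
* Wald null calibration: 200 refits at 10 participants x 32 randomly
  subsampled trials, K = 8, testing the heart-rate group smooth.  The
  tested block's truth is fully null — the group curve is zero and that
  channel's individual-deviation SD is set to zero too, since
  finite-sample leakage of individual deviations into the group smooth is
  a real nonzero effect, not a type-I error.
* Decomposition regimes: 10 participants, K = 6; dominant-intercept
  (participant SD 1.0, odor effects x 0.3) versus dominant-odor
  (SD 0.15, x 1.5) configurations.
* EFA recovery: 2000 rows from the default loading truth.
* Pipeline determinism: two complete runs at 3 participants, byte-compared
  decomposition and marginal-estimate tables.

## Known limitations

* The thin-plate basis is the eigen-truncated 1-D construction, not the
  exact eigenbasis of any particular external implementation; smoothing
  parameter values are therefore not comparable across packages, though
  fitted curves are.
* The REML surface is multimodal in log-lambda for some data sets;
  multi-start mitigates but does not guarantee the global optimum.
* Marginal odor estimates depend on the covariate-averaging convention
  (documented above); only their contrasts are convention-free.
* Real-data mode supports long-format CSV recordings plus a design table;
  it has not been validated against any deposited dataset.
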