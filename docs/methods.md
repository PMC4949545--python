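# Methods

## The SITAR model

pysitar fits the SITAR (super-imposition by translation and rotation)
shape-invariant growth model.  On the analysis scale (raw height; sqrt
IGF-1; log sex steroids) the measurement of subject *i* at age *t_ij* is

    y_ij = alpha_i + h((t_ij - c - beta_i) * exp(gamma_i)) + e_ij

with `h` a natural cubic regression spline, `c` a fixed centring age
(default: the mean observed age), and per-subject random effects
(alpha_i, beta_i, gamma_i) ~ N(0, Sigma) (unstructured 3x3 Sigma) and
residuals e_ij ~ N(0, sigma^2):

* **size** alpha — vertical offset, transformed-outcome units;
* **tempo** beta — timing offset in years; negative = early puberty.
  A subject's age at peak velocity (APV) is the population APV plus
  their tempo;
* **velocity** gamma — log age-scale factor about `c`.  `exp(gamma)`
  multiplies the age scale, so positive gamma means faster passage
  through puberty and a peak velocity scaled up by `exp(gamma)`.  The
  opposite sign convention (division by `exp(gamma)`) exists in the
  literature; with this package's convention, correlations involving
  the velocity effect flip sign relative to implementations that use
  the divisor form.

The spline has `df` basis columns (default 5 for height, 3 for
hormones) built from the truncated-power natural-spline construction:
interior knots at equally spaced quantiles of the centred ages,
boundary knots at their extremes, linear continuation outside the
boundary knots.  Linear tails matter because the subject-shifted,
time-scaled ages routinely leave the observed window.

Ordinal Tanner stages use a modified model: the mean curve is a
logistic from stage 1 to 5, `S(t) = 1 + 4/(1 + exp(-k (t - m)))`, with
tempo and velocity effects only (no size: every child traverses the
same five stages), asymptotes fixed at 1 and 5 for identifiability, and
stages treated as numeric with Gaussian residuals.  The population mean
age in stage 3 is `m` — the stage analogue of APV — and subject *i*'s
timing is `m + beta_i`.  A cumulative-ordinal likelihood is a
deliberate non-goal.

## Estimation

Parameters are estimated by maximum likelihood with the per-subject
random effects integrated out by the Laplace approximation: an inner
batched Gauss-Newton search finds each subject's posterior mode, and
the marginal likelihood uses a second-order expansion there with the
Gauss-Newton Hessian.  The approximation is exact when the model is
linear in the random effects (size-only), which the test suite
exploits as a closed-form oracle; a nonlinear one-subject toy is
checked against adaptive Gauss-Hermite quadrature.

The outer problem alternates, Lindstrom-Bates style:

1. **PNLS step** — penalized nonlinear least squares jointly updating
   the spline coefficients (a linear solve, since the model is linear
   in them given the modes) and the per-subject modes;
2. **LME step** — the model is linearized in the random effects around
   the modes and the resulting linear mixed model is maximized
   *exactly*: the fixed coefficients and sigma^2 are profiled out in
   closed form and a small quasi-Newton search with an analytic
   gradient runs over the log-Cholesky factor of Sigma/sigma^2.

Because the LME step maximizes the linearized rather than the Laplace
likelihood, each proposed variance update is passed through a
backtracking line search on the true Laplace log likelihood; a step
with no uphill component terminates the alternation.  Convergence is
declared when the Laplace log likelihood is stationary to 1e-7
(relative); the default cap is 60 alternations.  A short EM-style
warm-up (closed-form moment updates of Sigma and sigma from the modes
and their Laplace posterior covariances) precedes the alternation.
ML rather than REML is used throughout so that log likelihoods and
variance-explained values are comparable across fixed-effect
structures.

**Identifiability and recentring.**  The likelihood is nearly flat
along directions that trade a common shift of the random effects
against the fixed curve (mean size vs intercept, mean tempo vs a
translation of `h`, mean velocity vs a rescaling of its age axis).
Whenever the mode means drift beyond 2% of their SDs, the drift is
absorbed into the spline — exactly, since a natural cubic spline
composed with an affine age map is again a natural cubic spline on the
mapped knots — and the optimizer re-runs warm-started.  Fitted random
effects therefore come out centred (|mean| well under 0.1 SD).  Knots
are additionally refreshed once on the subject-adjusted age scale
after initial convergence, then frozen; refitting the knots every
iteration is unstable.

Starting values: spline from the pooled cross-sectional OLS fit;
random effects zero; Sigma diagonal at ((0.5 x cross-sectional
residual SD)^2, (0.5 y)^2, 0.1^2); sigma at one fifth of the
cross-sectional residual SD.  A random effect whose fitted SD
collapses (below 1e-4 of the largest) is dropped with a warning and
the model refit.  Subjects with fewer than `min_obs_per_subject`
(default 4) observations are excluded with a logged count.  Bootstrap
replicates warm-start from the full fit's parameters and knots.

## Derived quantities

* **Variance explained** = 1 - (sigma / s_cross)^2, where s_cross is
  the residual SD of a single pooled spline fit ignoring subject
  identity (denominator n - df - 1).  Both SDs live on the transformed
  scale.
* **APV / peak velocity** — the back-transformed mean curve's velocity
  (analytic spline derivative with the chain rule: identity h'; sqrt
  2hh'; log h'e^h) is maximized on a 0.01-y grid with local quadratic
  refinement.  The search window is the intersection of the knot span
  and the observed ages, shrunk 0.25 y at each end to avoid spline
  edge artefacts.  An interior maximum must exceed both window-end
  values by at least 2.5% of the curve's range — measured separation
  between genuine (smoothed) IGF-1 level peaks (prominence >= 4%) and
  noise wiggles on the sex steroids' flat tails (< 2%) — otherwise the
  curve is flagged as monotone/boundary (expected for testosterone and
  oestradiol, which keep rising into adulthood).  Finite differences
  are retained only as a test oracle.
* **Individual APV** = mean APV + tempo_i (the SITAR construction);
  per-subject re-maximization of the subject's own curve, which
  differs when gamma_i != 0, is exposed as the diagnostic
  `individual_apv_remaximized`.  The SD of individual APVs is by
  definition the tempo SD.
* **Bootstrap SE of APV** — nonparametric bootstrap resampling
  *subjects* with replacement (respecting the hierarchical design;
  residual resampling would understate between-subject uncertainty),
  default 200 replicates; replicates that fail to converge or hit a
  boundary peak are dropped and more than 10% failures raises an
  error.
* **Tempo correlations** — per-subject tempo effects from separate
  fits aligned by subject id, Pearson correlations on
  pairwise-complete cells (the hormone subsample leaves missing
  cells), two-sided p-values from the t transform with n - 2 df, no
  multiple-testing correction.

## The synthetic cohort generator

No raw data accompany the study design this package implements, so all
testing runs on synthetic cohorts that emulate its structure: 54 boys /
70 girls measured every 6 months from 8.5 to 16 y (visit ages jittered
±0.05 y so no two subjects share exact ages), with blood hormones in a
24/27-subject subsample.  Parametric curve families provide analytic
ground truth that the spline pipeline never sees:

* **Height** — Preece-Baines model 1 with the classic published rate
  constants (boys s0=0.1124, s1=1.2397; girls 0.1108, 1.1798); the
  spurt amplitude is solved at run time so the analytic peak velocity
  is 9.9 (boys) / 8.0 (girls) cm/y, and theta is translated so the
  grid-oracle APV is exactly 13.9 / 12.3 y.  Additive noise SD 0.3 cm
  (≈0.2 cm technical error of measurement plus day-to-day biological
  variation).
* **IGF-1** — double logistic (rise minus decline) on the sqrt scale,
  baseline ≈144 µg/L rising to ≈480 µg/L: amplitudes and slopes chosen
  so the pubertal rise is sharp enough for individual timing to be
  identifiable from 6-monthly visits, as the per-subject curves of the
  study show; the decline spacing is solved so the level peaks 1.3 y
  (boys) / 1.8 y (girls) after peak velocity (14.5/13.8 vs 13.2/12.0),
  and the rise midpoints are translated for exact APV calibration.
  Multiplicative lognormal noise, CV 12% (the assay's interassay
  precision).
* **Sex steroids** — single logistic on the log scale calibrated to
  APV 13.5 y (testosterone) / 12.7 y (oestradiol), with the adult
  asymptote high enough that levels still rise at age 16 (no interior
  level peak); noise CV 9%, plus extra post-APV lognormal noise (SD
  0.30 log units) for girls, emulating menstrual-cycle variability.
* **Tanner stages** — latent logistic in (t - m - tempo) exp(velocity)
  with midpoints 13.1 (genitalia), 13.5/12.8 (pubic hair), 12.3
  (breast), rate 1.4/y, plus Gaussian rater noise (SD 0.4 stages),
  rounded and clamped to 1..5.

A single latent timing T_i per subject drives every outcome's tempo
through loadings lambda (tempo = sd.(lambda T + sqrt(1-lambda^2) eps)),
so the cross-outcome tempo correlation is lambda_1.lambda_2 in closed
form; boys' loadings are set for the ≈0.9 height-IGF-1-testosterone
regime and girls' lower (oestradiol lowest), reproducing the boys >
girls contrast.  Random-effect draws are *moment-matched*: each
cohort's sampled effects are re-centred to mean zero, which is exactly
the model's own assumption and makes every cohort's mean true APV
equal the calibrated target rather than wandering by the ±0.13 y
sampling noise of a 54-subject mean.  All sampling is deterministic
given (spec, seed).

What the generator does **not** emulate: secular trends, informative
dropout, assay batch effects, true ordinal rater behaviour (noise is
Gaussian-plus-rounding), or the unknown fine structure of real growth
curves — the families are smooth three-to-seven-parameter curves, so
passing recovery tests shows the estimation machinery works under the
stated noise and design, not that real data would be fitted equally
well.  Hormone residual SDs on the transformed scale are calibrated to
assay CVs, so synthetic variance-explained values bracket rather than
match values obtainable on real cohorts.

## Numerical choices and problem sizes

Inner mode search: per-subject step tolerance 1e-8 with an
active-subject set so warm-started calls touch only stragglers.  Peak
grids 0.01 y (analysis) and 0.001 y (generator oracles).  Default
seed 20150108.  A full three-effect height fit (54 subjects, 864
observations) takes a few seconds on one core; the test suite runs
its recovery checks on the study-sized cohorts (n=54/70, 16 visits),
5 seeds for height recovery, 10 for the null-correlation check, and
100 bootstrap replicates, chosen to keep the whole suite in the
ten-minute range.

## Known limitations

* The df=5 regression spline resolves the height velocity peak to
  roughly ±0.1 y: the projection of a sharp spurt onto a 5-df natural
  spline pulls the velocity maximum slightly toward the heavier
  (pre-peak) side.  The recovery tests bound this bias; it is a
  property of the published analysis convention, not of the optimizer.
* Ordinal stages are treated as numeric; rater noise plus
  rounding/clamping slightly compresses the latent curve near stages
  1 and 5, which the fixed asymptotes absorb into the rate parameter.
* The Laplace approximation is not checked against quadrature beyond
  two random effects; with 16 observations per subject its error is
  far below sampling noise in all tested regimes.
* Correlations among empirical-Bayes modes (e.g. IGF-1 size vs
  velocity) are noisy at hormone-subsample size (n≈24) and can sit far
  from the latent correlation in any one cohort; only their regime
  (strongly positive vs null) is tested.
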