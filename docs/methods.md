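# Methods

## The model

A single-component cosinor describes a periodic signal over one cycle
of length τ (24 h for circadian data):

    Y(t) = M + A · cos(2πt/τ + φ) + e(t)

with MESOR M (the rhythm-adjusted mean), amplitude A (half the
peak-to-trough extent, in response units) and acrophase φ (the phase
angle of the peak; the peak occurs at clock time −φτ/2π).  The model
is nonlinear in (A, φ) but linearizes exactly under the recoding
x = cos(2πt/τ), z = sin(2πt/τ):

    Y(t) = M + β·x + γ·z + e(t),      β = A·cos φ,   γ = −A·sin φ,

and the inverse map is A = √(β² + γ²), φ = atan2(−γ, β).

For longitudinal data — many sparse, non-uniformly timed observations
per subject, as produced by wearable devices — the linear form extends
to a mixed model.  For subject *i* at time *t*, with categorical
covariates C (treatment coded) entering both as main effects and
crossed with the rhythm regressors:

    Y_it = M + α₀·C_i + (β + α₂·C_i)·x_it + (γ + α₃·C_i)·z_it
           + W_it·θ_i + e_i(t),

θ_i ~ N(0, Σ) subject-level random effects, e ~ N(0, s) residual
noise.  Two random-effect designs W are supported: a random MESOR
(`1 | id`) and random MESOR plus rhythm coefficients
(`1 + x + z | id`) with a full, correlated Σ.  Every covariate that
enters the model is crossed with x and z, so each factor level can
shift the MESOR, the amplitude and the acrophase.

Estimation is REML (ML optional) through statsmodels `MixedLM`,
optimizer L-BFGS with conjugate-gradient and Powell fallbacks,
maximum 500 iterations.  The fit is deterministic given the data.

## Marginal means and contrasts

Group-level parameters are estimated marginal means (EMMs) in the
emmeans sense.  For a grid formula `~F` or `~F1|F2`, each grid cell
fixes the named factors at their levels and averages the linear
predictor's three components (intercept-scale, x-scale, z-scale) over
the levels of every other model factor — equal weights per level by
default, observed-frequency weights optionally.  Each cell's
(M_g, β_g, γ_g) is therefore an exact linear combination L·b of the
fixed effects, which makes the construction invariant to the choice
of treatment-coding reference levels.  The nonlinear triple
(M_g, A_g, φ_g) follows by the inverse map.  Cells for factor
combinations never observed in the data are still produced (the model
defines them) but flagged extrapolated.

## Bootstrap inference

A and φ are nonlinear in the coefficients, so confidence intervals
and tests use a bootstrap rather than the delta method.  Default
scheme is parametric: each replicate simulates responses from the
fitted model (fixed effects X·b̂, random effects drawn from Σ̂ via its
symmetric square root — Σ̂ may sit on the PSD boundary — and residual
noise at variance ŝ), refits the same design, recomputes the EMM grid
and the nonlinear triples, and forms all pairwise differences within
each conditioning stratum.  Subject-level (cluster) resampling is
available as an alternative scheme; it resamples whole subjects with
replacement and rebuilds the design, so replicates can fail when a
factor level drops out.  Failed refits are skipped and counted, never
retried; a run with more than 10 % failures is flagged unreliable and
a run with none successful is an error.  Replicates are warm-started
at the full-data parameters, falling back to a cold start once before
counting a failure.  Default replicate count: 500; default level 95 %.

Intervals are equal-tailed percentile intervals (type-7 quantiles).
Acrophase is circular: plain quantiles are meaningless near the branch
cut, so acrophase draws are first unwrapped onto the branch nearest
the full-data estimate (adding the wrapped draw−estimate difference to
the estimate); the interval lives on that branch and may extend
outside (−2π, 0].  If the unwrapped draw range exceeds π the interval
is flagged wide; if any draw has zero amplitude the acrophase interval
is reported undefined.

Contrast p-values use the two-sided add-one sign count,
p = 2·min(#{d ≤ 0}+1, #{d ≥ 0}+1)/(B+1), capped at 1 — never exactly
zero and monotone in the evidence.  Significance labels: ***, **, *, +
for p < 0.001, 0.01, 0.05, 0.1 (strict inequalities).  No multiplicity
adjustment is applied across pairwise contrasts; users comparing many
pairs should adjust downstream.  Acrophase contrasts are wrapped to
(−π, π] (boundary ties resolve to +π) and co-reported as peak-time
differences in hours wrapped to (−τ/2, τ/2].

Hypotheses that are linear in the coefficients (any weighted sum of
the α's, β, γ) do not need the bootstrap and are served by a Wald
z-test from the fixed-effect covariance; Satterthwaite or
Kenward-Roger degree-of-freedom corrections are not implemented.

## Conventions and numerical choices

- Acrophase is reported in (−2π, 0], so peak time −φτ/2π is in
  [0, τ).  Zero amplitude leaves φ undefined; it is set to 0 and
  flagged degenerate, and the flag propagates to interval reports.
- Times are used modulo the period; hours assumed; period default 24,
  user-settable.  No date or timezone arithmetic.
- Missing responses or times are dropped with a logged count
  (available-case analysis).  Mixed models remain valid under missing
  at random, so no imputation is attempted; with heavy missingness a
  sensitivity analysis is the user's responsibility.
- Rank-deficient fixed designs raise an error naming the aliased
  columns (pivoted QR).  Factors need at least two observed levels.
- The design matrix orders coefficients in three equal blocks
  (MESOR scale, :x, :z) with reference levels first and levels
  alphabetical within factors, so fits are reproducible down to
  column order.
- `fit(..., zero_random_variance=True)` pins Σ at 1e−10·I (exact zero
  is a singular point of the optimizer); the fit then agrees with
  ordinary least squares to ~1e−10, which is how the package's
  least-squares-limit checks are run.

## The synthetic-data generator

`simulate_dataset` draws from exactly the model above: subjects are
allocated to group cells by largest-remainder rounding of the cell
proportions (as balanced as the proportions allow), random effects are
Gaussian on the linear (M, β, γ) scale — matching the fitted model, so
subject-level A and φ follow a derived non-Gaussian distribution —
and residuals are Gaussian.  Observation times are uniform on
[0, τ) or, with `clustered_daytime`, drawn from a two-component
normal mixture peaked mid-morning and late afternoon (wrapped onto the
cycle) to emulate wearable app check-ins concentrated in waking hours.
Missingness deletes each planned observation independently with the
given rate (MAR by construction).

What the generator does **not** emulate: within-day autocorrelation,
non-Gaussian or heteroscedastic residuals, informative (MNAR)
missingness, day-to-day drift in rhythm parameters, and device-level
measurement artifacts.  Passing the validation battery therefore shows
the estimator and bootstrap are correct *under the model's own
assumptions*; it does not certify robustness to these real-data
features.

## Validation battery and study sizes

`cosinormixed.validation` contains the reproducible studies the test
suite and `scripts/acceptance.py` run:

- **Algebra**: round-trip identity over 10,000 random (M, A, φ)
  triples (observed error ~1e−14) and unit-circle recoding.
- **Least-squares limit**: 20 random two-group designs with Σ pinned
  at ~0; mixed fixed effects vs closed-form (XᵀX)⁻¹XᵀY.
- **Recovery**: the reference design — 100 subjects × 10 observations,
  two equal groups, MESOR 60, amplitudes 10 vs 6, acrophase offset
  0.5 rad, random-MESOR sd 6, residual sd 5 — with every group-level
  (M, A, φ) estimate required within 3 bootstrap SEs of truth.
- **Coverage and type-I error**: 100 study replicates of a
  20-subject × 6-observation version of the same design, each analyzed
  with B = 199 parametric bootstrap replicates (≈ 40,000 model fits
  per study; sizes chosen to keep the battery in the minutes range on
  one core while staying inside the bootstrap's operating regime).
  Coverage of the 95 % contrast CIs is required in 88–99 %; the null
  rejection rate at 0.05 must fall in the exact binomial 99 % interval.
- **Equivariance**: shifting all times by 3 h must rotate every fitted
  acrophase by −2π·3/24 (observed error ~1e−16) and leave M and A
  unchanged.
- **Worked configurations**: the additive sex + infection model with
  random MESOR, and the full sex × BMI interaction model with random
  rhythm coefficients, end to end on one simulated cohort.

## Known limitations

- Only categorical covariates may interact with the rhythm terms;
  continuous moderators of amplitude/acrophase are out of scope.
- Single-component (one-harmonic) cosinor only.
- Random structures beyond `1|id` and `1+x+z|id` (nested, crossed,
  autocorrelated residuals) are not supported.
- Percentile intervals only (no BCa/studentized); unadjusted pairwise
  p-values.
- Wald tests use the normal reference, adequate for the many-subject
  settings the package targets.
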