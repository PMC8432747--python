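# Methods

This note records the statistical models implemented in `famvc`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Kinship and pedigree structure

Expected additive relationships are computed by the recursive tabular
method: founders are non-inbred and mutually unrelated, `φ_ii = ½(1+F_i)`,
and for a non-founder *j* with parents *f*, *m*, `φ_ij = ½(φ_if + φ_im)`
processed in generation order.  The matrix used throughout is `K = 2φ`,
block-diagonal by family; it is positive semidefinite by construction.
When only one parent is recorded, an anonymous founder is materialized so
the recursion stays valid.  Relationship classes are assigned by pedigree
path for first/second-degree pairs (which share kinship values:
sibling vs parent-offspring at 2φ = 0.5; half-sibling, avuncular and
grandparent-grandchild at 0.25) and by kinship degree
`round(−log2 2φ)` for third- to fifth-degree pairs; anything else is
reported under "other" rather than dropped.  There is no support for
founder inbreeding coefficients or marker-based relatedness.

## Quantitative polygenic model

`y = m + Xb + g + e`, `g ~ N(0, σ²g K)`, `e ~ N(0, σ²e I)`, fitted by
maximum likelihood (not REML — the sporadic-vs-polygenic LRT presumes
comparable ML log-likelihoods).  Each family block of K is eigendecomposed
once (`K = U D U'`); in the rotated basis observations are independent with
variances `σ²t (h² d + 1 − h²)`, so `b` and the total variance σ²t are
profiled out in closed form and the likelihood is maximized over the single
parameter h² ∈ [0, 0.9999] by bounded scalar optimization (with explicit
endpoint comparison, since the profile can peak on the boundary).  This is
an exact reformulation of the block multivariate-normal likelihood, chosen
because replicate-heavy validation (hundreds of fits) then costs seconds.
Wald standard errors come from a central finite-difference Hessian
(step 1e-4) of the (h², log σ²t) surface with b profiled; profiling yields
the correct Schur-complement curvature.  Intervals for h² are truncated to
[0, 1].  Boundary fits (ĥ² = 0) carry SEs of limited meaning and are
flagged.

The heritability LRT refers `2(ℓ₁ − ℓ₀)` to the boundary mixture
`½χ²₀ + ½χ²₁`: p = ½·P(χ²₁ > stat), hence p = 0.5 exactly when the
statistic is 0.  A polygenic log-likelihood below the sporadic one beyond
1e-6 raises an optimization-failure error rather than reporting a negative
statistic.

## Liability-threshold model for binary traits

Affection indicates a latent liability `L = m + Xb + a` above 0, with
`a ~ N(0, h²K + (1−h²)I)` — total residual variance fixed at 1, the
conventional liability scale, so the fitted intercept maps to a prevalence
through `Φ(m)` (equivalently `Φ(−m)` in the threshold convention used for
reporting).  Each family's likelihood is the rectangle probability of its
affection pattern under the family's liability correlation matrix,
evaluated by Genz separation-of-variables with scrambled-Sobol randomized
QMC.  Each family's QMC point set is drawn once per fit from a seed derived
deterministically from the run seed and the family index, so the objective
is smooth in the parameters and fits are exactly reproducible.  The default
budget is 256 points per family during optimization (the standalone kernel
default is 8192 points in 8 independently scrambled batches, whose spread
provides the reported Monte Carlo standard error, typically ≤1e-4).
Families beyond 25 members exceed the rectangle-dimension cap and must be
split or the cap raised; quantitative fits have no such cap.  Optimization
is L-BFGS-B over (m, b, h²) warm-started from an independent probit
regression, with restarts from h² ∈ {0.05, 0.5, 0.9}.

### Ascertainment correction

With probands supplied, each family's likelihood is divided by the marginal
probability of its probands' observed affection status — the classic
proband (single-ascertainment) conditional likelihood.  This correction is
consistent when families enter the sample with probability proportional to
their number of affected members (each affected member an independent,
rare, potential proband).  It is *not* the matching correction for
"keep every family with ≥1 affected" (complete ascertainment), where it
over-corrects — we verified this numerically, recovering 0.21 instead of a
true prevalence of 0.35 under complete ascertainment, versus 0.35 under
single ascertainment.  The generator's default `single-proband` mode
therefore implements genuine single ascertainment (retention probability
proportional to the affected count, proband a random affected member); a
`complete` mode is available for sensitivity analyses.  Under random
sampling with arbitrarily designated probands the correction only discards
the probands' marginal information, so corrected and uncorrected estimates
agree up to sampling noise.

## Association and reporting transforms

Trait-disease association uses the liability model with inverse-normalized
traits as covariates; the per-trait p-value constrains that coefficient to
0 and refers `2Δℓ` to χ²₁ (an interior constraint, unlike the h² boundary).
Screening is two-stage: all candidate traits enter a joint model, those
with constraint p below the threshold (default 0.1) are refitted, and the
final model reports odds ratios per SD.  An iterated one-at-a-time backward
elimination is not the default because the two-stage screen-then-refit is
what the reporting format implies; sensitivity to that choice can be probed
by chaining calls with updated trait lists.

Odds ratios use the reporting convention `OR = exp(π·β*)` with β* oriented
risk-positive; a `reporting-negative` flag accommodates software that
returns negative probit coefficients for positively associated covariates.
Note the textbook probit-to-logit scale factor is `π/√3 ≈ 1.814`, not π;
`odds_ratio_probit_to_logit` computes the textbook version so the
discrepancy between conventions (about 73% larger log-OR under π) can be
quantified.  Prevalence from a fitted threshold is `Φ(−m)` — an inverse-CDF
symbol sometimes appears for this transform in the literature, but only the
CDF mapping takes a threshold to a probability.  Bonferroni correction is
`min(1, p·m)` with m defaulting to the number of traits tested in the run.

## Bivariate decomposition

For traits i, j the stacked covariance is `G ⊗ K + E ⊗ I` with 2×2
component matrices parameterized by (σ²g_i, σ²g_j, ρG) and (σ²e_i, σ²e_j,
ρE).  The same eigen-rotation decouples the likelihood into independent
2-dimensional normals with covariance `d·G + E` per eigenvalue d, with
(b_i, b_j) profiled by GLS inside the objective.  Correlations are
parameterized as `0.999·tanh(z)` to keep boundaries finite; |ρ̂| > 0.995 is
flagged as a boundary fit.  The implied phenotypic correlation is
`ρP = ρG√(h²ᵢh²ⱼ) + ρE√((1−h²ᵢ)(1−h²ⱼ))`, and the pleiotropy test fixes
ρG = 0 and uses χ²₁.  Quantitative × binary pairs keep the quantitative
trait on its observed scale and the disease on the liability scale; each
family contributes the Gaussian density of the quantitative vector times
the conditional rectangle probability of the affection pattern.  Matrices
of pairs are fitted independently pair by pair; no joint ≥3-trait model is
attempted.

## Heritability curves

A quantitative trait is dichotomized at each cutoff of a grid (default: 25
equally spaced points between the 5th and 95th percentiles; "affected"
means strictly greater than the cutoff), a liability model is fitted per
cutoff, and the estimates are loess-smoothed.  Cutoffs leaving either class
under 5% of the non-missing values are skipped and logged — this
operationalizes "a clinically meaningful range".  The loess is local-linear
with tricube weights over the nearest `⌈bandwidth·n⌉` neighbors (bandwidth
0.4 by default), applied to the raw per-cutoff estimates without SE
weighting; an SE-weighted variant exists but is off by default, and
smoothed values are clipped to [0, 1].  Per-cutoff rectangle seeds derive
from the run seed and cutoff index, so curves are reproducible.  When the
fitted grid is too small for the bandwidth to give ≥3 neighbors, the
unsmoothed estimates are returned.  Since dichotomizing a Gaussian
polygenic trait yields a liability model that is exactly correct with the
trait itself as liability, a homogeneous generating model produces a flat
curve at the generating h² — the calibration the tests exploit.

## Factor analysis

Principal-factor extraction iterates communalities (starting from squared
multiple correlations) on the reduced correlation matrix, retaining factors
whose eigenvalue exceeds 1 (tolerance 1e-8), for at most 50 iterations;
a communality above 1 (Heywood case) stops at the last valid step and flags
the solution.  Derived ratio/composite traits should be excluded by the
caller — near-deterministic functions of other traits are the classic
Heywood trigger.  Varimax rotation is orthogonal, so communalities,
uniqueness and total variance explained are invariant; factors are
re-signed (dominant loading positive) and reordered by explained variance
for a canonical orientation.  Complete cases only; no oblique rotations or
factor scores.

## Design calculations

Power to detect heritability from relatedness variation uses
`SE(ĥ²) = √(2/(n²·var_π))` and `power = Φ(h²/SE − z_{1−α/2})` — the
two-sided z is required to reproduce the reference value 0.8492 at
(n = 1152, var_π = 0.00015, h² = 0.3, α = 0.05); a one-sided convention
does not.  The prevalence-detection sample size is the one-sample normal
approximation with a ceiling convention, reproducing 1,323 at
(6.7% vs 8.7%, α = 0.05, power 0.80).

## Synthetic data

The generator emulates a family study of ~112 extended families (sizes
3–20, truncated-lognormal with mean ≈10, two to four generations, spouses
marrying in as founders), a 18-trait quantitative panel plus a
liability-threshold disease (default prevalence 0.35, liability h² 0.35),
and single-proband ascertainment.  Genetic effects are drawn per family as
`L Z M_G'` with L the Cholesky factor of the family's 2φ block —
distributionally equivalent to gene dropping for additive effects and
cheaper.  Default heritabilities range from 0.06 (C-peptide) to 0.73
(height); genetic and environmental correlation matrices are built from
explicit latent-factor loadings (body size, adiposity, disease liability),
which guarantees positive semidefiniteness while reproducing headline
values such as a biceps-skinfold × disease genetic correlation of 0.77 and
small negative environmental correlations for two skinfolds.  Covariates:
age decreasing ~27 years per generation (clipped to ≥20), sex Bernoulli
(59% female), smoking 4%, hemoglobin normal with sex-specific means chosen
so the derived anemia flag has ≈45% prevalence.  Traits are mapped to
natural units by sex-specific location/scale (cohort-realistic means/SDs)
and clipped to stay positive, and small age slopes are added on the
standardized scale; the disease liability has no covariate effects by
default so that "prevalence" is a single well-defined number.  The
family-size cap of 20 keeps every family inside the liability model's
rectangle-dimension cap; quantitative-only fixtures may raise it.

What the generator does **not** emulate: genotypes or markers, household or
dominance components, real measurement error and digit preference,
non-Gaussian trait shapes beyond the positivity clip, informative
within-family phenotyping patterns (everyone is phenotyped unless a
missingness probability is set), questionnaire-derived covariates, or
secular/cohort effects.  Passing tests therefore demonstrate correctness of
the estimators under the additive-polygenic generating model, not
robustness to those real-data features.

## Numerical conventions and degenerate inputs

- Optimizer tolerances: 1e-10 (scalar h² profile), ftol 1e-10 to 1e-12
  (L-BFGS-B); rectangle probabilities floored at 1e-300 before logs.
- Kinship blocks get a 1e-10 to 1e-12 jitter before Cholesky when needed.
- Constant traits cannot be inverse-normalized (error); an exact linear fit
  flags a σ²e boundary; one-class binary traits and rank-deficient designs
  raise errors naming the problem.
- Sample sizes round up; probabilities are clipped to [0, 1] after QMC.

## Known limitations

- Liability fits are practical to family dimension 25; the study-scale
  141-member family is only usable for quantitative traits.
- ML (not REML) variance components are slightly downward-biased in small
  samples with many covariates.
- Wald intervals for h² are poor near the boundaries; the truncation to
  [0, 1] mirrors common reporting but is not a profile-likelihood interval.
- The proband correction assumes the single-ascertainment sampling model;
  under complete ascertainment it over-corrects (see above).
- Bivariate mixed (quantitative × binary) fits are the slowest path and are
  validated at smoke level, not with full calibration sweeps.
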