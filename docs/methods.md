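# Methods

## Model and procedure

deltami handles one incomplete binary variable Y (the serological target)
in an otherwise fully observed rectangular survey table. R = 1 marks rows
where Y is observed. The imputation model is a maximum-likelihood logistic
regression of Y on the declared predictors, fitted to the R = 1 rows only —
optionally separately per stratum (the motivating application imputes men
and women separately because risk-factor profiles and refusal patterns
differ by sex). No interaction terms are added to the imputation model.

Imputation is *proper*: for imputation m the coefficient vector is drawn
from a multivariate normal centred at the MLE with the estimated
covariance (the standard large-sample approximation to the posterior), so
between-imputation variance reflects parameter uncertainty. The draw
mechanism is the package's choice — the analysis this mirrors delegated it
to a general MI package without stating the mechanism — and a
bootstrap-refit engine could be slotted in behind the same interface.
Draws are keyed by (base seed, stratum index, m) on independent RNG
substreams, so increasing M never perturbs earlier imputations.

MNAR imputation adds a log-odds offset to the linear predictor of missing
rows only, *after* the MAR fit (the deltas never enter the fit):
common mode adds one δ everywhere; by-group mode adds δ_z indexed by the
row's level of a fully observed auxiliary categorical variable Z, which
must then itself be an imputation predictor. δ = 0 reproduces the MAR
imputer bit for bit because both paths use identical RNG substreams.

### Common random numbers

Grid runs reuse one uniform per missing row per imputation across all
delta settings (stream keyed by seed and m only). Consequently the number
of imputed positives is exactly non-decreasing in every δ component, grid
surfaces are smooth, and the MAR grid point coincides bit-exactly with a
standalone MAR run under the same seed. An independent-draw mode (uniforms
additionally keyed by a hash of the delta values) exists for users who
prefer independent Monte Carlo error per grid point; the choice is recorded
in the run provenance.

### Pooling

Rubin's rules: Q̄ = mean of per-imputation estimates, T = W̄ + (1 + 1/M)B,
ν = (M − 1)(1 + W̄/((1 + 1/M)B))², intervals from the t quantile (normal
when B = 0). Prevalences are pooled on the proportion scale with binomial
within-imputation variance p(1 − p)/n — the reported SEs in the motivating
tables are consistent with this simple choice, and a logit-scale pooling
option exists for near-boundary prevalences. GLM coefficient vectors pool
element-wise with the between-imputation covariance taken as the sample
covariance of the coefficient vectors. Degrees of freedom use the
classical Rubin formula; a small-sample correction was deliberately left
out of the default because the intended n is in the tens of thousands.

### Mediation

Two logistic sub-models: outcome on exposure + mediator (+ optional
exposure–mediator interaction) + confounders; mediator on exposure +
confounders. Natural direct/indirect effects use the rare-outcome
odds-ratio expressions of the counterfactual (Valeri–VanderWeele-style)
framework; with η(a, a′) = θ_m + θ_am·a + β₀ + β_a·a′ + β_c′c,

    OR_NDE = exp(θ_a(a) − θ_a(a*)) · [1 + e^{η(a,a*)}] / [1 + e^{η(a*,a*)}]
    OR_NIE = [1 + e^{lpb(a*)}][1 + e^{η(a,a)}] / ([1 + e^{lpb(a)}][1 + e^{η(a,a*)}])

evaluated in the log domain (log1p-exp), so OR_TE = OR_NDE·OR_NIE holds to
machine precision by construction. This is an approximation when the
outcome is common; the default generator keeps the outcome prevalence near
3%, and users analysing common outcomes should treat the ORs as
risk-ratio-like only qualitatively. Standard errors use the multivariate
delta method with the (θ, β) covariance block-diagonal (the models are
fitted separately, so the cross-covariance is set to zero) and
central-difference gradients with relative step 1e-6; a symbolic
differentiation oracle in the tests confirms 6-significant-figure
agreement on the no-confounder case. "Average" effects over covariate
patterns are observed-frequency-weighted means on the log-OR scale (this
definition is recorded in output metadata since other weightings are
defensible), with SEs from the same delta method applied to the weighted
sum.

Within MI, the default order pools each sub-model's coefficients and
covariance by Rubin's rules first and computes effects once from the
pooled quantities — the order the motivating analysis states explicitly.
Computing per-imputation effects and pooling the log-ORs is available
behind a flag; on well-behaved data the two agree closely.

## Numerical choices

- **Separation.** Self-reported status nearly determines the serological
  result (observed ORs in the hundreds), so quasi-separation is a live
  risk. A fit is declared quasi-separated when it fails to converge or any
  |coefficient| exceeds 15; the fallback is a Newton ridge fit with
  penalty 1e-4·n on variance-standardised columns (intercept unpenalised),
  flagged as `engine="penalized"` in provenance.
- **Degenerate designs.** Predictors (or dummy levels) constant within a
  stratum — e.g. circumcision among women — are dropped with a logged
  warning, and the prediction design mirrors the fitted one.
- **Covariance repair.** Non-PSD covariance matrices are repaired by
  eigenvalue clipping before drawing; a zero matrix yields the MLE
  exactly.
- **Rounding.** Displayed percentages round half-up to one decimal,
  matching the survey tables' convention (the source tables do not state
  theirs; half-up reproduces all reconstructed entries).
- **Tipping points.** Crossings are located per delta axis, holding the
  other coordinates fixed; interpolation is linear in the estimand versus
  log δ, and results are reported as bracketing intervals plus the
  interpolated point, never a point alone.

## Synthetic-data generator

The generator draws sex, six age bands, four regions, five education
levels and the 4-level self-report variable Z from documented categorical
margins (Z conditional on sex), then missingness R from a logistic model
in (X, Z), then Y directly from the pattern-mixture law
logit P(Y=1|X,Z,R) = φ₀(sex) + φ_X′X + φ_Z Z + δ_z(1−R), then a binary TB
outcome from a logistic model in (Y, education, age, sex, region) with
mediator coupling θ_m = ln 3. Default margins echo the motivating survey:
~34/66 male/female split, ~32% missingness with refusal ordered
non-disclosers > self-reported positives > never tested > self-reported
negatives, >90% seropositivity among self-reported positives, ~19% overall
prevalence, and true group deltas exp(δ) = (2.5, 1.0, 2.5, 1.0) for
(negative, positive, refused, never). They are documented constants in one
place (`GeneratorParams`), chosen once; they echo but do not claim to
reproduce the original survey's joint distribution.

Because the generative law is pattern-mixture, imputing with the true δ_z
is *exactly* congenial, which is what makes recovery tests sharp: the
pooled prevalence must sit within Monte Carlo noise of the enumerated
truth, and imputing with δ = 0 instead must land below it. Ground truth is
computed by exact enumeration over the 960-cell covariate lattice:
subgroup prevalences and the missingness fraction are weighted sums; the
"true" mediator-model coefficients are the population projection of the
(marginally misspecified) analysis model, obtained by a weighted logistic
fit on the lattice; true natural effects are the closed-form expressions
evaluated at the generative θ and that projection.

What the generator does **not** emulate: household/cluster structure and
design weights, covariate dependence beyond the sex–Z coupling,
missingness in covariates, and any dependence of the departure from MAR on
TB status or education. Passing tests therefore demonstrate correctness of
the machinery under a faithful univariate-missingness pattern-mixture
world, not robustness to those real-data features.

## Problem sizes used in checks

The test suite and the acceptance script run the full pipeline at reduced
but statistically meaningful sizes chosen to keep the whole suite in the
tens of seconds: MAR-equivalence at n = 5,000 with M = 25; grid audits on
a 3×1×3×3 sub-grid at n = 5,000, M = 5; the closed-form delta oracle with
M = 200 over 1,000 missing rows; parameter recovery at n = 30,000 with
M = 25; delta-method vs 500-replicate bootstrap SEs at n = 2,000. All
stochastic assertions use three-standard-error (or stated relative)
tolerances with fixed seeds.

## Known limitations

- Only a single incomplete binary variable is supported; delta adjustment
  inside chained equations for multivariate missingness is deliberately
  out of scope (its theoretical footing is weak).
- The posterior-normal draw is an approximation; for tiny strata a
  bootstrap-refit engine would be preferable.
- Mediation effects assume the rare-outcome OR approximation and no
  unobserved confounding / no exposure-induced mediator-outcome
  confounding; neither is testable here.
- Delta values must come from elicitation; the package scans and locates
  tipping points but cannot say which deltas are plausible.
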