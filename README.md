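# deltami

Delta-adjusted multiple imputation for a single incomplete binary variable,
with Rubin's-rules pooling, missing-not-at-random (MNAR) sensitivity grids
and tipping-point scans, and MI-integrated parametric causal mediation
analysis.

## The problem

Population surveys that test for a stigmatised condition — the motivating
case is HIV serostatus in a large adult TB/HIV prevalence survey — routinely
lose a third of their outcome measurements to refusal, and refusal is
plausibly informative: people who know or suspect they are positive are more
likely to decline the test. Standard multiple imputation assumes the data
are missing at random (MAR), i.e. Pr(R | Y, X) = Pr(R | X) where R = 1 when
the serostatus Y is observed. That assumption cannot be checked from the
observed data, so the honest analysis is a *sensitivity analysis*: re-impute
under a spectrum of MNAR mechanisms and see how far the answer moves.

## The method

Fit a logistic imputation model to the observed rows under MAR,

    logit Pr[Y = 1 | X] = φ₀ + φ_X′ X,

then, before imputing each missing row, add a fixed log-odds offset δ to the
linear predictor:

    logit Pr[Y = 1 | X, R] = φ₀ + φ_X′ X + δ(1 − R).

exp(δ) is the assumed odds ratio of Y = 1 comparing non-responders to
responders with the same covariates — a simple pattern-mixture model, with
δ = 0 recovering MAR. When a fully observed auxiliary variable Z (here,
4-level self-reported HIV status) predicts both Y and its missingness, the
departure can differ by group:

    … + φ_Z Z + Σ_z δ_z 1{Z = z} (1 − R).

Per-imputation estimates are combined by Rubin's rules
(T = W̄ + (1 + 1/M)·B). For the mediation analysis (does HIV status mediate
the education → TB association?) two logistic sub-models give natural
direct and indirect effects on the odds-ratio scale with OR_TE = OR_NDE ×
OR_NIE, delta-method standard errors, and Rubin pooling of the coefficient
vectors before effect computation.

A synthetic-data generator emulates the survey's structure *in
pattern-mixture form*, so the true δ_z are generator parameters and every
population quantity (prevalences, the mediator-model projection, natural
effects) is computed by exact enumeration over the discrete covariate
lattice — making parameter-recovery tests sharp.

## Worked example

```python
import numpy as np
from deltami import (ImputationConfig, DeltaSpec, impute_mnar,
                     pooled_prevalence, synthgen, complete_case, Subgroup)

params = synthgen.default_params(n=20_000, seed=1)
table, truth = synthgen.generate(params)
roles = synthgen.default_roles()
print(f"rows: {table.n}, missing HIV results: {table.data['hiv'].isna().mean():.1%}")

cc = complete_case(table, roles, [Subgroup("overall")])
print(f"complete-case prevalence: {cc.iloc[0]['pct']:.1f}%")

cfg = ImputationConfig(predictors=("age", "region", "education", "selfreport"),
                       M=25, seed=7, strata="sex")
for exp_d in (1.0, 2.0, 5.0):
    comp = impute_mnar(table, roles.target, cfg,
                       DeltaSpec.common(exp_d, exp_scale=True))
    pct, se = pooled_prevalence(comp).as_percent()
    print(f"exp(delta) = {exp_d:>3}: pooled prevalence {pct:.1f}% (SE {se:.1f})")

spec = DeltaSpec.by_group(dict(zip(synthgen.AUX_LEVELS, (2.5, 1.0, 2.5, 1.0))),
                          "selfreport", exp_scale=True)
pct, se = pooled_prevalence(impute_mnar(table, roles.target, cfg, spec)).as_percent()
print(f"group-specific exp(delta) = (2.5, 1.0, 2.5, 1.0): {pct:.1f}% (SE {se:.1f})")
print(f"enumerated true prevalence: {100 * truth.prevalence['overall']:.1f}%")
```

prints

```
rows: 20000, missing HIV results: 31.8%
complete-case prevalence: 16.0%
exp(delta) = 1.0: pooled prevalence 17.2% (SE 0.3)
exp(delta) = 2.0: pooled prevalence 19.6% (SE 0.4)
exp(delta) = 5.0: pooled prevalence 24.2% (SE 0.4)
group-specific exp(delta) = (2.5, 1.0, 2.5, 1.0): 18.7% (SE 0.3)
enumerated true prevalence: 18.8%
```

Reading it: the complete-case estimate (16.0%) understates prevalence
because refusal is concentrated among higher-risk groups; MAR imputation
(exp(δ) = 1) lifts it to 17.2%; pushing the non-responders' odds of
positivity up by a factor of 2–5 moves the estimate to 19.6–24.2%. The data
were generated with group-specific true departures exp(δ) = 2.5 for
self-reported negatives and non-disclosers (MAR for the rest); imputing
with those values recovers the enumerated truth (18.7% vs 18.8%).

The same machinery drives grid scans (`run_sensitivity`, 500-point default
grid), tipping-point location (`tipping_point`), and MI-integrated
mediation (`mediation_mi`). A `deltami` CLI exposes `simulate`, `impute`,
`prevalence`, `sensitivity` and `mediate` subcommands over CSV + YAML
configs.

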