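"""Synthetic TB/HIV-survey-like data in pattern-mixture form with known truth.

The generator emulates the structure of a large adult TB/HIV prevalence
survey: sex-stratified covariates (6 age bands, 4 regions), a 5-level
educational-attainment exposure, a 4-category self-reported-HIV-status
auxiliary variable Z that strongly predicts both the serological target Y
and its missingness, roughly 32% missingness in Y, and a low-prevalence
binary TB outcome driven partly by Y.

The target is generated directly in pattern-mixture form:

    logit Pr[Y = 1 | X, Z, R] = phi_0 + phi_X' X + phi_Z Z + delta_z (1 - R)

so the true group-specific delta equals the generator parameter exactly
(not approximately, as it would under a selection model).  All covariates
are discrete, so every population quantity — prevalence overall and per
subgroup, the missingness fraction, and the population projection of the
mediator analysis model — is computed by exact enumeration over the
covariate lattice, never by nested simulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .dataio import Column, RoleMap, Schema, StudyTable

__all__ = [
    "GeneratorParams",
    "TruthRecord",
    "default_params",
    "default_roles",
    "build_schema",
    "generate",
    "SEX_LEVELS",
    "AGE_LEVELS",
    "REGION_LEVELS",
    "EDU_LEVELS",
    "AUX_LEVELS",
]

SEX_LEVELS = ("male", "female")
AGE_LEVELS = ("18-24", "25-29", "30-34", "35-39", "40-49", "50+")
REGION_LEVELS = ("rural_lowARTI", "urban_lowARTI", "urban_highARTI", "lusaka_highARTI")
EDU_LEVELS = ("none", "primary", "lower_secondary", "upper_secondary", "college")
#: Auxiliary self-report levels, in the order their sensitivity parameters
#: are conventionally indexed: delta_1 self-reported negative, delta_2
#: self-reported positive, delta_3 refused to disclose, delta_4 never tested.
AUX_LEVELS = ("negative", "positive", "refused", "never")


@dataclass(frozen=True)
class GeneratorParams:
    """All generative constants; every categorical distribution sums to 1.

    Coefficient mappings give one value per level with the reference level
    at zero; ``target_coefs`` is per sex (the survey's risk-factor profile
    differs by sex, and imputation is sex-stratified downstream).
    ``delta`` holds the true pattern-mixture log-odds offsets per auxiliary
    level.
    """

    n: int = 30_000
    seed: int = 0
    p_sex: tuple[float, ...] = (0.34, 0.66)
    p_age: tuple[float, ...] = (0.35, 0.17, 0.12, 0.09, 0.12, 0.15)
    p_region: tuple[float, ...] = (0.28, 0.21, 0.19, 0.32)
    p_education: tuple[float, ...] = (0.06, 0.32, 0.26, 0.31, 0.05)
    # Pr[Z | sex]: refusal-to-test patterns differ sharply by sex
    p_aux: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "male": (0.374, 0.049, 0.026, 0.551),
            "female": (0.522, 0.086, 0.032, 0.360),
        }
    )
    # logit Pr[Y = 1 | X, Z, R = 1], per sex; level dicts with reference 0
    target_coefs: Mapping[str, Mapping] = field(
        default_factory=lambda: {
            "male": {
                "Intercept": -3.45,
                "age": {"18-24": 0.0, "25-29": 1.2, "30-34": 1.6, "35-39": 1.7,
                        "40-49": 1.6, "50+": 0.6},
                "region": {"rural_lowARTI": 0.0, "urban_lowARTI": 0.45,
                           "urban_highARTI": 0.25, "lusaka_highARTI": 0.2},
                "education": {"none": 0.05, "primary": 0.0, "lower_secondary": -0.02,
                              "upper_secondary": -0.25, "college": -0.4},
                "selfreport": {"negative": -0.66, "positive": 5.6,
                               "refused": 0.85, "never": 0.0},
            },
            "female": {
                "Intercept": -2.55,
                "age": {"18-24": 0.0, "25-29": 0.9, "30-34": 1.25, "35-39": 1.4,
                        "40-49": 1.1, "50+": 0.05},
                "region": {"rural_lowARTI": 0.0, "urban_lowARTI": 0.5,
                           "urban_highARTI": 0.35, "lusaka_highARTI": 0.3},
                "education": {"none": -0.2, "primary": 0.0, "lower_secondary": 0.0,
                              "upper_secondary": -0.3, "college": -0.5},
                "selfreport": {"negative": -0.55, "positive": 5.25,
                               "refused": 1.35, "never": 0.0},
            },
        }
    )
    #: True pattern-mixture deltas (log-odds), per auxiliary level.
    delta: Mapping[str, float] = field(
        default_factory=lambda: {
            "negative": float(np.log(2.5)),
            "positive": 0.0,
            "refused": float(np.log(2.5)),
            "never": 0.0,
        }
    )
    # logit Pr[R = 0 | X, Z] (probability the target is MISSING)
    missing_coefs: Mapping[str, object] = field(
        default_factory=lambda: {
            "Intercept": -0.80,
            "sex": {"male": 0.0, "female": -0.05},
            "age": {"18-24": 0.0, "25-29": 0.05, "30-34": 0.1, "35-39": 0.15,
                    "40-49": 0.15, "50+": 0.1},
            "region": {"rural_lowARTI": 0.0, "urban_lowARTI": 0.25,
                       "urban_highARTI": 0.05, "lusaka_highARTI": -0.55},
            "education": {"none": 0.1, "primary": 0.0, "lower_secondary": 0.1,
                          "upper_secondary": 0.35, "college": 0.65},
            "selfreport": {"negative": -0.25, "positive": 0.35,
                           "refused": 0.55, "never": 0.0},
        }
    )
    # logit Pr[TB = 1 | Y, education, age, sex, region]; "mediator" is the
    # log-odds ratio for Y = 1 (the mediator coupling)
    outcome_coefs: Mapping[str, object] = field(
        default_factory=lambda: {
            "Intercept": -3.6,
            "education": {"none": 0.3, "primary": 0.0, "lower_secondary": -0.2,
                          "upper_secondary": -0.35, "college": -0.9},
            "mediator": float(np.log(3.0)),
            "age": {"18-24": 0.0, "25-29": 0.4, "30-34": 0.5, "35-39": 0.5,
                    "40-49": 0.4, "50+": 0.3},
            "sex": {"male": 0.0, "female": -0.4},
            "region": {"rural_lowARTI": 0.0, "urban_lowARTI": 0.2,
                       "urban_highARTI": 0.1, "lusaka_highARTI": 0.1},
        }
    )

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, dist, levels in (
            ("p_sex", self.p_sex, SEX_LEVELS),
            ("p_age", self.p_age, AGE_LEVELS),
            ("p_region", self.p_region, REGION_LEVELS),
            ("p_education", self.p_education, EDU_LEVELS),
        ):
            if len(dist) != len(levels):
                raise ValueError(f"{name} must have {len(levels)} entries")
            if not np.isclose(sum(dist), 1.0):
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in dist):
                raise ValueError(f"{name} has a negative probability")
        for sex in SEX_LEVELS:
            dist = self.p_aux[sex]
            if len(dist) != len(AUX_LEVELS) or not np.isclose(sum(dist), 1.0):
                raise ValueError(f"p_aux[{sex!r}] must be a distribution over Z")
        if set(self.delta) != set(AUX_LEVELS):
            raise ValueError("delta map must cover every auxiliary level")
        for z, d in self.delta.items():
            if not np.isfinite(d):
                raise ValueError(f"delta for {z!r} must be finite")


@dataclass
class TruthRecord:
    """Exact population quantities implied by the generator parameters.

    ``prevalence`` maps subgroup labels (overall, sex=*, selfreport=*) to
    the true marginal prevalence of the target.  ``beta_pop`` is the
    population projection of the mediator analysis model (the logistic fit
    of Y on exposure and confounders, marginal over Z and R, computed on
    the enumerated lattice) and ``theta`` the generative outcome-model
    coefficients; ``effects`` holds closed-form natural effects per
    exposure contrast (per-pattern plus the pattern-frequency-weighted
    average).
    """

    prevalence: dict[str, float]
    missing_fraction: float
    delta: dict[str, float]
    theta_labels: list[str]
    theta: np.ndarray
    beta_labels: list[str]
    beta_pop: np.ndarray
    effects: pd.DataFrame


def build_schema() -> Schema:
    return Schema(
        [
            Column("sex", "categorical", SEX_LEVELS),
            Column("age", "categorical", AGE_LEVELS),
            Column("region", "categorical", REGION_LEVELS),
            Column("education", "categorical", EDU_LEVELS),
            Column("selfreport", "categorical", AUX_LEVELS),
            Column("hiv", "binary"),
            Column("tb", "binary"),
        ]
    )


def default_roles() -> RoleMap:
    return RoleMap(
        target="hiv",
        outcome="tb",
        exposure="education",
        exposure_reference="primary",
        mediator="hiv",
        auxiliary="selfreport",
        confounders=("age", "sex", "region"),
        strata="sex",
    )


def default_params(**overrides) -> GeneratorParams:
    """The documented default generator constants (see class docstring)."""
    p = GeneratorParams(**overrides)
    p.validate()
    return p


# ---------------------------------------------------------------------------
# linear predictors (shared by sampling and enumeration)


def _lp_target(p: GeneratorParams, sex, age, region, edu, aux):
    c = p.target_coefs[sex]
    return (
        c["Intercept"] + c["age"][age] + c["region"][region]
        + c["education"][edu] + c["selfreport"][aux]
    )


def _lp_missing(p: GeneratorParams, sex, age, region, edu, aux):
    c = p.missing_coefs
    return (
        c["Intercept"] + c["sex"][sex] + c["age"][age] + c["region"][region]
        + c["education"][edu] + c["selfreport"][aux]
    )


def _lp_outcome(p: GeneratorParams, y, sex, age, region, edu):
    c = p.outcome_coefs
    return (
        c["Intercept"] + c["education"][edu] + c["mediator"] * y
        + c["age"][age] + c["sex"][sex] + c["region"][region]
    )


# ---------------------------------------------------------------------------
# truth by exact enumeration


def _lattice(p: GeneratorParams) -> pd.DataFrame:
    rows = []
    for (sex, ps), (age, pa), (region, pr), (edu, pe) in itertools.product(
        zip(SEX_LEVELS, p.p_sex), zip(AGE_LEVELS, p.p_age),
        zip(REGION_LEVELS, p.p_region), zip(EDU_LEVELS, p.p_education),
    ):
        for aux, pz in zip(AUX_LEVELS, p.p_aux[sex]):
            w = ps * pa * pr * pe * pz
            if w == 0.0:
                continue
            p_miss = expit(_lp_missing(p, sex, age, region, edu, aux))
            lp = _lp_target(p, sex, age, region, edu, aux)
            py_obs = expit(lp)
            py_miss = expit(lp + p.delta[aux])
            py = (1.0 - p_miss) * py_obs + p_miss * py_miss
            rows.append(
                {"sex": sex, "age": age, "region": region, "education": edu,
                 "selfreport": aux, "w": w, "p_miss": p_miss,
                 "py_obs": py_obs, "py_miss": py_miss, "py": py}
            )
    return pd.DataFrame(rows)


def _analysis_design(
    df: pd.DataFrame, roles: RoleMap, *, include_mediator: bool, mediator_col=None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix in the exact label order used by the mediation fits."""
    cols = [np.ones(len(df))]
    labels = ["Intercept"]
    ref = roles.exposure_reference or EDU_LEVELS[0]
    for lev in EDU_LEVELS:
        if lev == ref:
            continue
        cols.append((df[roles.exposure] == lev).to_numpy(dtype=float))
        labels.append(f"{roles.exposure}[{lev}]")
    if include_mediator:
        cols.append(np.asarray(mediator_col, dtype=float))
        labels.append(roles.mediator)
    conf_levels = {"age": AGE_LEVELS, "sex": SEX_LEVELS, "region": REGION_LEVELS}
    for c in roles.confounders:
        for lev in conf_levels[c][1:]:
            cols.append((df[c] == lev).to_numpy(dtype=float))
            labels.append(f"{c}[{lev}]")
    return np.column_stack(cols), labels


def _theta_vector(p: GeneratorParams, labels: list[str]) -> np.ndarray:
    c = p.outcome_coefs
    vec = []
    for lab in labels:
        if lab == "Intercept":
            vec.append(c["Intercept"])
        elif lab == "hiv":
            vec.append(c["mediator"])
        else:
            name, lev = lab[:-1].split("[")
            vec.append(c[name][lev])
    return np.asarray(vec, dtype=float)


def compute_truth(p: GeneratorParams, roles: RoleMap | None = None) -> TruthRecord:
    """Exact population quantities from the discrete covariate lattice."""
    if roles is None:
        roles = default_roles()
    lat = _lattice(p)
    w = lat["w"].to_numpy()
    prev = {"overall": float(np.sum(w * lat["py"]) / np.sum(w))}
    for sex in SEX_LEVELS:
        m = (lat["sex"] == sex).to_numpy()
        prev[f"sex={sex}"] = float(np.sum(w[m] * lat.loc[m, "py"]) / np.sum(w[m]))
    for aux in AUX_LEVELS:
        m = (lat["selfreport"] == aux).to_numpy()
        prev[f"selfreport={aux}"] = float(
            np.sum(w[m] * lat.loc[m, "py"]) / np.sum(w[m])
        )
    missing_fraction = float(np.sum(w * lat["p_miss"]))

    # population projection of the mediator analysis model (Y on exposure +
    # confounders, marginal over Z and R): weighted logistic fit on the lattice
    Xm, beta_labels = _analysis_design(lat, roles, include_mediator=False)
    res = sm.GLM(
        lat["py"].to_numpy(), Xm, family=sm.families.Binomial(), var_weights=w
    ).fit()
    beta_pop = np.asarray(res.params, dtype=float)

    # outcome-model truth is generative
    theta_labels = None
    Xo_labels_probe = _analysis_design(
        lat.iloc[:1], roles, include_mediator=True, mediator_col=[0.0]
    )[1]
    theta_labels = Xo_labels_probe
    theta = _theta_vector(p, theta_labels)

    effects = _true_effects(p, roles, lat, theta_labels, theta, beta_labels, beta_pop)
    return TruthRecord(
        prevalence=prev,
        missing_fraction=missing_fraction,
        delta=dict(p.delta),
        theta_labels=theta_labels,
        theta=theta,
        beta_labels=beta_labels,
        beta_pop=beta_pop,
        effects=effects,
    )


def _true_effects(
    p: GeneratorParams, roles: RoleMap, lat: pd.DataFrame,
    theta_labels, theta, beta_labels, beta_pop,
) -> pd.DataFrame:
    from .mediation import CovariatePattern, GlmFit, MediationModel

    conf_levels = {"age": AGE_LEVELS, "sex": SEX_LEVELS, "region": REGION_LEVELS}
    conf_spec = {
        c: ("categorical", tuple(conf_levels[c]), conf_levels[c][0])
        for c in roles.confounders
    }
    ref = roles.exposure_reference or EDU_LEVELS[0]
    out_fit = GlmFit(
        role="outcome", labels=list(theta_labels), coef=theta,
        vcov=np.zeros((len(theta), len(theta))), exposure=roles.exposure,
        exposure_levels=EDU_LEVELS, exposure_ref=ref,
        confounders=tuple(roles.confounders), conf_spec=conf_spec,
        mediator=roles.mediator,
    )
    med_fit = GlmFit(
        role="mediator", labels=list(beta_labels), coef=beta_pop,
        vcov=np.zeros((len(beta_pop), len(beta_pop))), exposure=roles.exposure,
        exposure_levels=EDU_LEVELS, exposure_ref=ref,
        confounders=tuple(roles.confounders), conf_spec=conf_spec,
    )
    model = MediationModel(out_fit, med_fit)
    # pattern weights: marginal joint law of the confounders
    pat_w = (
        lat.groupby(list(roles.confounders), sort=True)["w"].sum().reset_index()
    )
    pat_w["w"] = pat_w["w"] / pat_w["w"].sum()
    rows = []
    for a in EDU_LEVELS:
        if a == ref:
            continue
        logs = []
        weights = []
        for _, r in pat_w.iterrows():
            pat = {c: r[c] for c in roles.confounders}
            l_nde, l_nie = model.log_effects(theta, beta_pop, a, ref, pat)
            logs.append((l_nde, l_nie))
            weights.append(r["w"])
            rows.append(
                {"a": a, "a_star": ref,
                 "pattern": ",".join(f"{c}={pat[c]}" for c in roles.confounders),
                 "or_nde": float(np.exp(l_nde)), "or_nie": float(np.exp(l_nie)),
                 "or_te": float(np.exp(l_nde + l_nie))}
            )
        logs = np.asarray(logs)
        weights = np.asarray(weights)
        avg = weights @ logs
        rows.append(
            {"a": a, "a_star": ref, "pattern": "average",
             "or_nde": float(np.exp(avg[0])), "or_nie": float(np.exp(avg[1])),
             "or_te": float(np.exp(avg.sum()))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sampling


def generate(params: GeneratorParams) -> tuple[StudyTable, TruthRecord]:
    """Draw one synthetic survey table; return it with its exact truth.

    Deterministic given ``params`` (including the seed).  The emitted
    target column is blanked wherever R = 0; the pre-blanking values are
    retained in ``table.latent_target`` for oracle checks.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    def draw_cat(levels, probs, size):
        return np.asarray(levels)[rng.choice(len(levels), size=size, p=list(probs))]

    sex = draw_cat(SEX_LEVELS, params.p_sex, n)
    age = draw_cat(AGE_LEVELS, params.p_age, n)
    region = draw_cat(REGION_LEVELS, params.p_region, n)
    edu = draw_cat(EDU_LEVELS, params.p_education, n)
    aux = np.empty(n, dtype=object)
    for s in SEX_LEVELS:
        m = sex == s
        aux[m] = draw_cat(AUX_LEVELS, params.p_aux[s], int(m.sum()))

    lp_miss = np.array(
        [_lp_missing(params, sex[i], age[i], region[i], edu[i], aux[i]) for i in range(n)]
    )
    missing = rng.random(n) < expit(lp_miss)

    lp_y = np.array(
        [_lp_target(params, sex[i], age[i], region[i], edu[i], aux[i]) for i in range(n)]
    )
    delta_term = np.array([params.delta[z] for z in aux]) * missing
    y = (rng.random(n) < expit(lp_y + delta_term)).astype(float)

    lp_tb = np.array(
        [_lp_outcome(params, y[i], sex[i], age[i], region[i], edu[i]) for i in range(n)]
    )
    tb = (rng.random(n) < expit(lp_tb)).astype(float)

    y_emitted = y.copy()
    y_emitted[missing] = np.nan
    df = pd.DataFrame(
        {"sex": sex, "age": age, "region": region, "education": edu,
         "selfreport": aux, "hiv": y_emitted, "tb": tb}
    )
    table = StudyTable(df, build_schema())
    table.latent_target = y  # type: ignore[attr-defined]
    truth = compute_truth(params)
    return table, truth
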