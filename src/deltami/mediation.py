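"""Parametric causal mediation analysis with a binary outcome and mediator.

Two logistic sub-models are fitted: the outcome on exposure, mediator and
confounders (optionally with an exposure-mediator interaction), and the
mediator on exposure and confounders.  The total effect of moving a
categorical exposure from level a* to level a decomposes, on the
odds-ratio scale under a rare outcome, into natural direct and indirect
effects, evaluated at a covariate pattern c:

    eta(a1, a2) = theta_m + theta_am(a1) + beta_0 + beta_a(a2) + beta_c' c

    OR_NDE = exp(theta_a(a) - theta_a(a*))
             * [1 + exp(eta(a, a*))] / [1 + exp(eta(a*, a*))]
    OR_NIE = [1 + exp(lpb(a*))] [1 + exp(eta(a, a))]
             / ([1 + exp(lpb(a))] [1 + exp(eta(a, a*))])
    OR_TE  = OR_NDE * OR_NIE           (an identity, exact by construction)

where lpb(a) = beta_0 + beta_a(a) + beta_c' c is the mediator-model linear
predictor and theta_a, theta_am, beta_a are the exposure dummy blocks
(zero at the reference level).  All evaluation is in the log domain.

Standard errors use the multivariate delta method with the (theta, beta)
covariance block-diagonal across the two separately fitted models and
numerically differentiated gradients (central differences).  Within
multiple imputation, the default order pools the two models' coefficient
vectors and covariance matrices by Rubin's rules first and computes the
effects once from the pooled quantities; computing per-imputation effects
and pooling the log-ORs is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import RoleMap, StudyTable
from .delta_mnar import CompletedSet
from .impute_mar import _fit_logistic
from .pooling import PooledGlm, pool_glm, pool_scalar

__all__ = [
    "GlmFit",
    "MediationEffects",
    "CovariatePattern",
    "MediationModel",
    "fit_outcome_model",
    "fit_mediator_model",
    "natural_effects",
    "effect_standard_errors",
    "average_effects",
    "mediation_mi",
    "observed_patterns",
]

#: Relative step for central-difference gradients of the log-effect maps.
GRAD_REL_STEP = 1e-6


@dataclass
class GlmFit:
    """One fitted logistic sub-model with the metadata needed for effects."""

    role: str  # {"outcome", "mediator"}
    labels: list[str]
    coef: np.ndarray
    vcov: np.ndarray
    exposure: str
    exposure_levels: tuple[str, ...]
    exposure_ref: str
    confounders: tuple[str, ...]
    conf_spec: dict[str, tuple]  # name -> ("categorical", levels, ref) | ("numeric",)
    mediator: str | None = None
    interaction: bool = False
    engine: str = "mle"
    interaction_wald: tuple[float, float, float] | None = None  # (stat, df, p)

    def __post_init__(self) -> None:
        if self.role == "outcome" and self.mediator is None:
            raise ValueError("outcome fit must contain the mediator term")
        if self.role == "mediator" and self.mediator is not None:
            raise ValueError("mediator fit must not contain the outcome/mediator term")
        if len(self.coef) != len(self.labels):
            raise ValueError("coefficient/label length mismatch")

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class CovariatePattern:
    """One joint configuration of the confounders, with a frequency weight."""

    values: tuple[tuple[str, object], ...]
    weight: float = 1.0

    def as_dict(self) -> dict:
        return dict(self.values)

    def label(self) -> str:
        return ",".join(f"{k}={v}" for k, v in self.values)


@dataclass
class MediationEffects:
    """Natural-effect estimates for one exposure contrast.

    ``per_pattern`` has one row per covariate pattern plus an ``average``
    row (observed-frequency weights on the log-OR scale); columns carry the
    OR, the SE of the log OR, and the confidence interval for each of
    NDE, NIE and TE.
    """

    contrast: tuple[str, str]  # (a, a_star)
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# model fitting


def _dummy_block(
    data: pd.DataFrame, name: str, levels: Sequence[str], ref: str
) -> tuple[list[np.ndarray], list[str]]:
    cols, labels = [], []
    for lev in levels:
        if lev == ref:
            continue
        cols.append((data[name] == lev).to_numpy(dtype=float))
        labels.append(f"{name}[{lev}]")
    return cols, labels


def _confounder_block(
    data: pd.DataFrame, table: StudyTable, confounders: Sequence[str]
) -> tuple[list[np.ndarray], list[str], dict[str, tuple]]:
    cols, labels = [], []
    spec: dict[str, tuple] = {}
    for c in confounders:
        kind = table.schema[c].kind
        if kind == "categorical":
            levels = list(table.schema[c].levels)
            ref = levels[0]
            blk, lbl = _dummy_block(data, c, levels, ref)
            cols.extend(blk)
            labels.extend(lbl)
            spec[c] = ("categorical", tuple(levels), ref)
        else:
            cols.append(data[c].to_numpy(dtype=float))
            labels.append(c)
            spec[c] = ("numeric",)
    return cols, labels, spec


def _exposure_meta(table: StudyTable, roles: RoleMap) -> tuple[tuple[str, ...], str]:
    exp_col = table.schema[roles.exposure]
    if exp_col.kind == "categorical":
        levels = tuple(exp_col.levels)
    else:
        levels = ("0", "1")
    ref = roles.exposure_reference or levels[0]
    return levels, ref


def fit_outcome_model(
    table: StudyTable, roles: RoleMap, *, with_interaction: bool = False
) -> GlmFit:
    """Logistic regression of the outcome on exposure, mediator, confounders.

    With ``with_interaction`` the exposure-mediator product block is added
    and its joint Wald test is reported (to support dropping the block when
    there is no evidence of interaction).  Falls back to a ridge-penalised
    fit on separation.
    """
    data = table.data
    if data[roles.mediator].isna().any() or data[roles.outcome].isna().any():
        raise ValueError("outcome model requires complete outcome and mediator")
    levels, ref = _exposure_meta(table, roles)
    exp_is_cat = table.schema[roles.exposure].kind == "categorical"

    cols: list[np.ndarray] = [np.ones(len(data))]
    labels: list[str] = ["Intercept"]
    if exp_is_cat:
        blk, lbl = _dummy_block(data, roles.exposure, levels, ref)
    else:
        blk, lbl = [data[roles.exposure].to_numpy(dtype=float)], [roles.exposure]
    cols += blk
    labels += lbl
    med = data[roles.mediator].to_numpy(dtype=float)
    cols.append(med)
    labels.append(roles.mediator)
    inter_labels: list[str] = []
    if with_interaction:
        for b, l in zip(blk, lbl):
            cols.append(b * med)
            lab = f"{l}:{roles.mediator}"
            labels.append(lab)
            inter_labels.append(lab)
    cblk, clbl, cspec = _confounder_block(data, table, roles.confounders)
    cols += cblk
    labels += clbl
    X = np.column_stack(cols)
    y = data[roles.outcome].to_numpy(dtype=float)
    fit = _fit_logistic(X, y)
    wald = None
    if with_interaction and inter_labels:
        idx = [labels.index(l) for l in inter_labels]
        b = fit.coef[idx]
        v = fit.vcov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(v, b))
        dfw = len(idx)
        wald = (stat, float(dfw), float(stats.chi2.sf(stat, dfw)))
    return GlmFit(
        role="outcome", labels=labels, coef=fit.coef, vcov=fit.vcov,
        exposure=roles.exposure, exposure_levels=levels, exposure_ref=ref,
        confounders=tuple(roles.confounders), conf_spec=cspec,
        mediator=roles.mediator, interaction=with_interaction,
        engine=fit.engine, interaction_wald=wald,
    )


def fit_mediator_model(table: StudyTable, roles: RoleMap) -> GlmFit:
    """Logistic regression of the (binary) mediator on exposure and confounders."""
    data = table.data
    if data[roles.mediator].isna().any():
        raise ValueError("mediator model requires a complete mediator")
    levels, ref = _exposure_meta(table, roles)
    exp_is_cat = table.schema[roles.exposure].kind == "categorical"
    cols: list[np.ndarray] = [np.ones(len(data))]
    labels: list[str] = ["Intercept"]
    if exp_is_cat:
        blk, lbl = _dummy_block(data, roles.exposure, levels, ref)
    else:
        blk, lbl = [data[roles.exposure].to_numpy(dtype=float)], [roles.exposure]
    cols += blk
    labels += lbl
    cblk, clbl, cspec = _confounder_block(data, table, roles.confounders)
    cols += cblk
    labels += clbl
    X = np.column_stack(cols)
    y = data[roles.mediator].to_numpy(dtype=float)
    fit = _fit_logistic(X, y)
    return GlmFit(
        role="mediator", labels=labels, coef=fit.coef, vcov=fit.vcov,
        exposure=roles.exposure, exposure_levels=levels, exposure_ref=ref,
        confounders=tuple(roles.confounders), conf_spec=cspec,
        mediator=None, engine=fit.engine,
    )


# ---------------------------------------------------------------------------
# effect computation


def _log1pexp(x: float) -> float:
    return float(np.logaddexp(0.0, x))


class MediationModel:
    """Evaluates natural effects and their SEs from two fitted sub-models."""

    def __init__(self, outcome_fit: GlmFit, mediator_fit: GlmFit):
        if outcome_fit.role != "outcome" or mediator_fit.role != "mediator":
            raise ValueError("expected one outcome fit and one mediator fit")
        if outcome_fit.exposure_levels != mediator_fit.exposure_levels:
            raise ValueError("exposure dummy blocks must share level order")
        if outcome_fit.exposure_ref != mediator_fit.exposure_ref:
            raise ValueError("exposure reference level differs between fits")
        if outcome_fit.conf_spec != mediator_fit.conf_spec:
            raise ValueError("fits must share confounder coding")
        self.out = outcome_fit
        self.med = mediator_fit
        self.k_theta = len(outcome_fit.coef)
        self.k_beta = len(mediator_fit.coef)

    # -- coefficient lookups -------------------------------------------------

    def _exposure_term(self, fit: GlmFit, coef: np.ndarray, level: str) -> float:
        if level == fit.exposure_ref:
            return 0.0
        exp_is_cat = f"{fit.exposure}[{level}]" in fit.labels or any(
            l.startswith(f"{fit.exposure}[") for l in fit.labels
        )
        label = f"{fit.exposure}[{level}]" if exp_is_cat else fit.exposure
        if label not in fit.labels:
            raise KeyError(f"exposure level {level!r} not in fit {fit.role}")
        val = coef[fit.index(label)]
        if label == fit.exposure:  # numeric exposure: coef * value
            val = val * float(level)
        return float(val)

    def _interaction_term(self, coef: np.ndarray, level: str) -> float:
        if not self.out.interaction or level == self.out.exposure_ref:
            return 0.0
        label = f"{self.out.exposure}[{level}]:{self.out.mediator}"
        if label not in self.out.labels:
            label = f"{self.out.exposure}:{self.out.mediator}"
            if label not in self.out.labels:
                return 0.0
            return float(coef[self.out.index(label)]) * float(level)
        return float(coef[self.out.index(label)])

    def _confounder_term(
        self, fit: GlmFit, coef: np.ndarray, pattern: Mapping[str, object]
    ) -> float:
        total = 0.0
        for c, spec in fit.conf_spec.items():
            if c not in pattern:
                raise KeyError(f"covariate pattern missing confounder {c!r}")
            v = pattern[c]
            if spec[0] == "categorical":
                _, levels, ref = spec
                if v == ref:
                    continue
                if v not in levels:
                    raise KeyError(f"unknown level {v!r} for confounder {c!r}")
                total += float(coef[fit.index(f"{c}[{v}]")])
            else:
                total += float(coef[fit.index(c)]) * float(v)
        return total

    # -- log effects ---------------------------------------------------------

    def log_effects(
        self,
        theta: np.ndarray,
        beta: np.ndarray,
        a: str,
        a_star: str,
        pattern: Mapping[str, object],
    ) -> np.ndarray:
        """(log OR_NDE, log OR_NIE) at coefficient vectors (theta, beta)."""
        theta_m = float(theta[self.out.index(self.out.mediator)])
        conf_b = self._confounder_term(self.med, beta, pattern)

        def lpb(lev: str) -> float:
            return (
                float(beta[self.med.index("Intercept")])
                + self._exposure_term(self.med, beta, lev)
                + conf_b
            )

        def eta(a1: str, a2: str) -> float:
            return theta_m + self._interaction_term(theta, a1) + lpb(a2)

        d_theta_a = self._exposure_term(self.out, theta, a) - self._exposure_term(
            self.out, theta, a_star
        )
        l_nde = d_theta_a + _log1pexp(eta(a, a_star)) - _log1pexp(eta(a_star, a_star))
        l_nie = (
            _log1pexp(lpb(a_star))
            + _log1pexp(eta(a, a))
            - _log1pexp(lpb(a))
            - _log1pexp(eta(a, a_star))
        )
        return np.array([l_nde, l_nie])

    # -- gradients and SEs ---------------------------------------------------

    def _gradients(
        self, a: str, a_star: str, pattern: Mapping[str, object]
    ) -> np.ndarray:
        """Central-difference gradients of (log NDE, log NIE) wrt (theta, beta)."""
        psi0 = np.concatenate([self.out.coef, self.med.coef])
        k = len(psi0)
        grads = np.zeros((2, k))
        for i in range(k):
            h = GRAD_REL_STEP * max(1.0, abs(psi0[i]))
            up, dn = psi0.copy(), psi0.copy()
            up[i] += h
            dn[i] -= h
            f_up = self.log_effects(
                up[: self.k_theta], up[self.k_theta :], a, a_star, pattern
            )
            f_dn = self.log_effects(
                dn[: self.k_theta], dn[self.k_theta :], a, a_star, pattern
            )
            grads[:, i] = (f_up - f_dn) / (2.0 * h)
        return grads

    def _joint_vcov(self) -> np.ndarray:
        # theta-beta cross-covariance is zero: the two models are fitted
        # separately.
        k = self.k_theta + self.k_beta
        v = np.zeros((k, k))
        v[: self.k_theta, : self.k_theta] = self.out.vcov
        v[self.k_theta :, self.k_theta :] = self.med.vcov
        return v

    @staticmethod
    def _se_from_grad(grad: np.ndarray, v: np.ndarray) -> float:
        quad = float(grad @ v @ grad)
        if quad < 0:  # numerically singular vcov
            warnings.warn("singular joint vcov; using pseudo-inverse projection")
            quad = max(quad, 0.0)
        return float(np.sqrt(quad))

    # -- public API ----------------------------------------------------------

    def effects(
        self,
        a: str,
        a_star: str,
        pattern: Mapping[str, object] | CovariatePattern,
        *,
        alpha: float = 0.05,
        df: float = np.inf,
    ) -> dict:
        """Point estimates, SEs and CIs for NDE, NIE and TE at one pattern."""
        pat = pattern.as_dict() if isinstance(pattern, CovariatePattern) else dict(pattern)
        log_eff = self.log_effects(self.out.coef, self.med.coef, a, a_star, pat)
        grads = self._gradients(a, a_star, pat)
        v = self._joint_vcov()
        l_nde, l_nie = float(log_eff[0]), float(log_eff[1])
        l_te = l_nde + l_nie
        g_te = grads[0] + grads[1]
        se = {
            "nde": self._se_from_grad(grads[0], v),
            "nie": self._se_from_grad(grads[1], v),
            "te": self._se_from_grad(g_te, v),
        }
        q = (
            stats.norm.ppf(1 - alpha / 2)
            if np.isinf(df)
            else stats.t.ppf(1 - alpha / 2, df)
        )
        out = {"a": a, "a_star": a_star}
        for name, l, s in (("nde", l_nde, se["nde"]), ("nie", l_nie, se["nie"]),
                           ("te", l_te, se["te"])):
            out[f"or_{name}"] = float(np.exp(l))
            out[f"log_{name}"] = l
            out[f"se_log_{name}"] = s
            out[f"lo_{name}"] = float(np.exp(l - q * s))
            out[f"hi_{name}"] = float(np.exp(l + q * s))
        out["_grads"] = grads
        return out

    def average_effects(
        self,
        a: str,
        a_star: str,
        patterns: Sequence[CovariatePattern],
        *,
        alpha: float = 0.05,
        df: float = np.inf,
    ) -> dict:
        """Observed-frequency-weighted average of log-OR effects over patterns.

        The SE comes from the delta method applied to the weighted-sum
        functional (gradient = weighted sum of per-pattern gradients).
        """
        w = np.array([p.weight for p in patterns], dtype=float)
        if not np.isclose(w.sum(), 1.0):
            warnings.warn("pattern weights do not sum to 1; renormalising")
        w = w / w.sum()
        logs = np.zeros((len(patterns), 2))
        grads = np.zeros((2, self.k_theta + self.k_beta))
        for i, p in enumerate(patterns):
            logs[i] = self.log_effects(
                self.out.coef, self.med.coef, a, a_star, p.as_dict()
            )
            grads += w[i] * self._gradients(a, a_star, p.as_dict())
        l_nde, l_nie = (w @ logs[:, 0]), (w @ logs[:, 1])
        l_te = l_nde + l_nie
        v = self._joint_vcov()
        g_te = grads[0] + grads[1]
        se = {
            "nde": self._se_from_grad(grads[0], v),
            "nie": self._se_from_grad(grads[1], v),
            "te": self._se_from_grad(g_te, v),
        }
        q = (
            stats.norm.ppf(1 - alpha / 2)
            if np.isinf(df)
            else stats.t.ppf(1 - alpha / 2, df)
        )
        out = {"a": a, "a_star": a_star, "pattern": "average"}
        for name, l, s in (("nde", float(l_nde), se["nde"]),
                           ("nie", float(l_nie), se["nie"]),
                           ("te", float(l_te), se["te"])):
            out[f"or_{name}"] = float(np.exp(l))
            out[f"log_{name}"] = l
            out[f"se_log_{name}"] = s
            out[f"lo_{name}"] = float(np.exp(l - q * s))
            out[f"hi_{name}"] = float(np.exp(l + q * s))
        return out


# functional wrappers -------------------------------------------------------


def natural_effects(
    outcome_fit: GlmFit,
    mediator_fit: GlmFit,
    a: str,
    a_star: str,
    pattern: Mapping[str, object] | CovariatePattern,
) -> dict:
    """OR-scale NDE, NIE and TE at one covariate pattern (point estimates)."""
    model = MediationModel(outcome_fit, mediator_fit)
    pat = pattern.as_dict() if isinstance(pattern, CovariatePattern) else dict(pattern)
    l_nde, l_nie = model.log_effects(
        outcome_fit.coef, mediator_fit.coef, a, a_star, pat
    )
    return {
        "or_nde": float(np.exp(l_nde)),
        "or_nie": float(np.exp(l_nie)),
        "or_te": float(np.exp(l_nde + l_nie)),
    }


def effect_standard_errors(
    outcome_fit: GlmFit,
    mediator_fit: GlmFit,
    a: str,
    a_star: str,
    pattern: Mapping[str, object] | CovariatePattern,
) -> dict:
    """Delta-method SEs of log NDE, log NIE and log TE at one pattern."""
    model = MediationModel(outcome_fit, mediator_fit)
    res = model.effects(a, a_star, pattern)
    return {k: res[k] for k in ("se_log_nde", "se_log_nie", "se_log_te")}


def average_effects(
    outcome_fit: GlmFit,
    mediator_fit: GlmFit,
    a: str,
    a_star: str,
    patterns: Sequence[CovariatePattern],
    *,
    alpha: float = 0.05,
) -> dict:
    """Weighted-average natural effects over covariate patterns."""
    model = MediationModel(outcome_fit, mediator_fit)
    return model.average_effects(a, a_star, patterns, alpha=alpha)


def observed_patterns(
    table: StudyTable, confounders: Sequence[str]
) -> list[CovariatePattern]:
    """Unique observed confounder configurations with frequency weights."""
    if not confounders:
        return [CovariatePattern(values=(), weight=1.0)]
    counts = table.data.groupby(list(confounders), sort=True, observed=True).size()
    n = counts.sum()
    pats = []
    for key, cnt in counts.items():
        key = key if isinstance(key, tuple) else (key,)
        pats.append(
            CovariatePattern(
                values=tuple(zip(confounders, key)), weight=float(cnt) / float(n)
            )
        )
    return pats


# MI integration ------------------------------------------------------------


def _pooled_glmfit(template: GlmFit, pooled: PooledGlm) -> GlmFit:
    return GlmFit(
        role=template.role, labels=pooled.labels, coef=pooled.coef,
        vcov=pooled.vcov, exposure=template.exposure,
        exposure_levels=template.exposure_levels,
        exposure_ref=template.exposure_ref, confounders=template.confounders,
        conf_spec=template.conf_spec, mediator=template.mediator,
        interaction=template.interaction, engine=template.engine,
    )


def mediation_mi(
    completed: CompletedSet,
    roles: RoleMap,
    contrasts: Sequence[tuple[str, str]] | None = None,
    *,
    with_interaction: bool = False,
    order: str = "pool_then_compute",
    patterns: Sequence[CovariatePattern] | None = None,
    alpha: float = 0.05,
) -> dict[tuple[str, str], MediationEffects]:
    """Mediation analysis over M imputed data sets.

    Default order fits both sub-models in every completed table, pools the
    coefficient vectors and covariance matrices per model by Rubin's rules,
    then computes the natural effects and their delta-method SEs once from
    the pooled quantities.  ``order="compute_then_pool"`` instead computes
    per-imputation log-OR effects with their delta-method variances and
    Rubin-pools those.

    ``contrasts`` defaults to every non-reference exposure level versus the
    reference.
    """
    if completed.M == 0:
        raise ValueError("empty completed set")
    if order not in ("pool_then_compute", "compute_then_pool"):
        raise ValueError(f"unknown pooling order {order!r}")

    first = completed.tables[0]
    levels, ref = _exposure_meta(first, roles)
    if contrasts is None:
        contrasts = [(lev, ref) for lev in levels if lev != ref]
    if patterns is None:
        patterns = observed_patterns(first, roles.confounders)

    out_fits, med_fits = [], []
    for i, t in enumerate(completed.tables):
        try:
            out_fits.append(fit_outcome_model(t, roles, with_interaction=with_interaction))
            med_fits.append(fit_mediator_model(t, roles))
        except Exception as exc:  # pragma: no cover - propagated context
            raise RuntimeError(f"sub-model fit failed in imputation {i}") from exc

    results: dict[tuple[str, str], MediationEffects] = {}
    if order == "pool_then_compute":
        pooled_out = pool_glm(
            [(f.coef, f.vcov) for f in out_fits], [f.labels for f in out_fits]
        )
        pooled_med = pool_glm(
            [(f.coef, f.vcov) for f in med_fits], [f.labels for f in med_fits]
        )
        model = MediationModel(
            _pooled_glmfit(out_fits[0], pooled_out),
            _pooled_glmfit(med_fits[0], pooled_med),
        )
        for a, a_star in contrasts:
            rows = []
            for p in patterns:
                r = model.effects(a, a_star, p, alpha=alpha)
                r.pop("_grads")
                r["pattern"] = p.label() or "overall"
                r["weight"] = p.weight
                rows.append(r)
            rows.append(model.average_effects(a, a_star, patterns, alpha=alpha))
            results[(a, a_star)] = MediationEffects(
                contrast=(a, a_star), table=pd.DataFrame(rows)
            )
    else:
        for a, a_star in contrasts:
            rows = []
            per_pattern: dict[str, list[dict]] = {}
            for of, mf in zip(out_fits, med_fits):
                model = MediationModel(of, mf)
                for p in patterns:
                    per_pattern.setdefault(p.label(), []).append(
                        model.effects(a, a_star, p, alpha=alpha)
                    )
            for p in patterns:
                entries = per_pattern[p.label()]
                row = {"a": a, "a_star": a_star, "pattern": p.label() or "overall",
                       "weight": p.weight}
                for name in ("nde", "nie", "te"):
                    ps = pool_scalar(
                        [e[f"log_{name}"] for e in entries],
                        [e[f"se_log_{name}"] ** 2 for e in entries],
                        alpha=alpha,
                    )
                    row[f"or_{name}"] = float(np.exp(ps.estimate))
                    row[f"log_{name}"] = ps.estimate
                    row[f"se_log_{name}"] = ps.se
                    lo, hi = ps.ci
                    row[f"lo_{name}"], row[f"hi_{name}"] = float(np.exp(lo)), float(np.exp(hi))
                rows.append(row)
            results[(a, a_star)] = MediationEffects(
                contrast=(a, a_star), table=pd.DataFrame(rows)
            )
    return results
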