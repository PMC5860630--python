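"""Logistic imputation model for the incomplete binary target under MAR.

The imputation model is fitted by maximum likelihood to the rows where the
target is observed (R = 1), optionally separately per stratum (e.g. sex):

    logit Pr[Y = 1 | X] = phi_0 + phi_X' X.

Proper multiple imputation then draws the coefficient vector from its
approximate posterior — a multivariate normal centred at the MLE with the
estimated covariance — once per imputation m, on an RNG substream keyed by
(base seed, stratum, m) so that changing M never perturbs earlier draws.
Quasi-separation (the auxiliary self-report variable may almost determine
the serological result) triggers a weak ridge refit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import StudyTable

__all__ = [
    "ImputationConfig",
    "StratumFit",
    "FittedImputer",
    "CoefDraw",
    "build_design",
    "fit_imputation_model",
    "draw_parameters",
    "MODEL_PRESETS",
]

logger = logging.getLogger(__name__)

#: Absolute-coefficient threshold beyond which a fit is treated as
#: quasi-separated and refitted with a ridge penalty.
SEPARATION_COEF_LIMIT = 15.0

#: Ridge scale: penalty strength is RIDGE_SCALE * n on standardised columns.
RIDGE_SCALE = 1e-4

#: Named predictor bundles of increasing richness for the imputation model.
#: Keys are placeholders resolved against the table's column names; "A" is
#: demographics only, "D" adds the auxiliary self-report variable.
MODEL_PRESETS: dict[str, tuple[str, ...]] = {
    "A": ("age", "region"),
    "B": ("age", "region", "tb"),
    "C": ("age", "region", "tb", "education"),
    "D": ("age", "region", "tb", "education", "selfreport"),
}


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for fitting and drawing from the imputation model."""

    predictors: tuple[str, ...]
    M: int = 25
    seed: int = 0
    strata: str | None = None
    engine: str = "mle"  # {mle, penalized}

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.engine not in ("mle", "penalized"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class StratumFit:
    """One fitted logistic imputation model (for one stratum)."""

    labels: list[str]
    coef: np.ndarray
    vcov: np.ndarray
    engine: str  # "mle" or "penalized"
    converged: bool
    n_obs: int
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.labels):
            raise ValueError("coefficient length must equal design width")
        if self.vcov.shape != (len(self.coef), len(self.coef)):
            raise ValueError("vcov shape mismatch")


@dataclass
class FittedImputer:
    """Per-stratum imputation-model fits plus the design recipe."""

    strata: dict[object, StratumFit]  # key None = single unstratified fit
    config: ImputationConfig

    @property
    def stratum_keys(self) -> list[object]:
        return list(self.strata)


@dataclass(frozen=True)
class CoefDraw:
    """One posterior draw of the coefficient vector for one stratum."""

    coef: np.ndarray
    m: int
    stratum: object
    substream: tuple[int, ...]


# ---------------------------------------------------------------------------
# design construction


def build_design(
    table: StudyTable,
    predictors: Sequence[str],
    *,
    stratum: tuple[str, object] | None = None,
    reference_overrides: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the model matrix: intercept first, then dummy-coded predictors.

    Categorical predictors are dummy coded against their declared reference
    level (the first declared level unless overridden).  No interaction
    columns are added.  A predictor (or dummy) that is constant within the
    stratum is dropped with a warning — e.g. circumcision among women.

    Returns (X, labels, dropped_labels).  Rows follow the table (or the
    stratum subset) in order.
    """
    refs = dict(reference_overrides or {})
    data = table.data
    if stratum is not None:
        col, level = stratum
        data = data.loc[data[col] == level]
        if data.empty:
            raise ValueError(f"stratum {col}={level!r} is empty")
    cols: list[np.ndarray] = [np.ones(len(data))]
    labels: list[str] = ["Intercept"]
    dropped: list[str] = []
    for name in predictors:
        if name not in table.schema:
            raise KeyError(f"predictor {name!r} not in schema")
        spec = table.schema[name]
        if spec.kind == "categorical":
            levels = list(spec.levels)
            ref = refs.get(name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} is not a level of {name!r}")
            observed = set(data[name].dropna().unique())
            if len(observed) < 2:
                dropped.append(name)
                logger.warning(
                    "predictor %r is constant within stratum %s; dropped", name, stratum
                )
                continue
            for lev in levels:
                if lev == ref:
                    continue
                col_vals = (data[name] == lev).to_numpy(dtype=float)
                label = f"{name}[{lev}]"
                if lev not in observed:
                    dropped.append(label)
                    logger.warning("dummy %s has no observations; dropped", label)
                    continue
                cols.append(col_vals)
                labels.append(label)
        else:
            vals = data[name].to_numpy(dtype=float)
            if np.all(vals == vals[0]):
                dropped.append(name)
                logger.warning(
                    "predictor %r is constant within stratum %s; dropped", name, stratum
                )
                continue
            cols.append(vals)
            labels.append(name)
    X = np.column_stack(cols)
    return X, labels, dropped


# ---------------------------------------------------------------------------
# fitting


def _ridge_logit(
    X: np.ndarray, y: np.ndarray, alpha: np.ndarray, *, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton–Raphson logistic fit with a quadratic penalty alpha_j * b_j^2 / 2.

    Returns (coef, vcov, converged); vcov is the inverse penalised Hessian.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    A = np.diag(alpha)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - alpha * beta
        hess = (X.T * w) @ X + A
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (X.T * w) @ X + A
    vcov = np.linalg.inv(hess)
    return beta, vcov, converged


def _fit_logistic(X: np.ndarray, y: np.ndarray, engine: str = "mle") -> StratumFit:
    """ML logistic fit with automatic ridge fallback on quasi-separation."""
    n = len(y)
    labels = [f"x{j}" for j in range(X.shape[1])]  # placeholder; caller overwrites
    if engine == "mle":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            ok = (
                bool(res.converged)
                and np.all(np.isfinite(res.params))
                and np.max(np.abs(res.params)) <= SEPARATION_COEF_LIMIT
                and np.all(np.isfinite(np.diag(res.cov_params())))
            )
            if ok:
                return StratumFit(
                    labels=labels,
                    coef=np.asarray(res.params, dtype=float),
                    vcov=np.asarray(res.cov_params(), dtype=float),
                    engine="mle",
                    converged=True,
                    n_obs=n,
                )
        except (np.linalg.LinAlgError, ValueError):
            pass
    # ridge fallback, scaled to standardised columns; intercept unpenalised
    col_var = X.var(axis=0)
    alpha = RIDGE_SCALE * n * col_var
    alpha[0] = 0.0
    # guard degenerate zero-variance columns (should have been dropped upstream)
    alpha = np.where(col_var == 0, RIDGE_SCALE * n, alpha)
    alpha[0] = 0.0
    coef, vcov, converged = _ridge_logit(X, y, alpha)
    return StratumFit(
        labels=labels, coef=coef, vcov=vcov, engine="penalized",
        converged=converged, n_obs=n,
    )


def fit_imputation_model(
    table: StudyTable,
    target: str,
    config: ImputationConfig,
    *,
    reference_overrides: Mapping[str, str] | None = None,
) -> FittedImputer:
    """Fit the MAR imputation model to the observed rows (R = 1) only.

    Unobserved rows never influence the fit; permuting their covariates
    leaves the result unchanged.  With ``config.strata`` set, one model is
    fitted per stratum level.
    """
    data = table.data
    r = table.response_indicator(target)
    y_obs_all = data.loc[r == 1, target].to_numpy(dtype=float)
    if y_obs_all.size == 0 or len(np.unique(y_obs_all)) < 2:
        raise ValueError("degenerate target: need at least one observed 0 and one 1")

    if config.strata is None:
        keys: list[object] = [None]
    else:
        strat_col = table.schema[config.strata]
        keys = (
            list(strat_col.levels)
            if strat_col.kind == "categorical"
            else sorted(data[config.strata].dropna().unique())
        )
        keys = [k for k in keys if (data[config.strata] == k).any()]

    fits: dict[object, StratumFit] = {}
    for key in keys:
        stratum = None if key is None else (config.strata, key)
        obs_mask = r == 1
        if stratum is not None:
            obs_mask = obs_mask & (data[config.strata] == key).to_numpy()
        obs_table = StudyTable(
            data.loc[obs_mask].reset_index(drop=True), table.schema
        )
        X, labels, dropped = build_design(
            obs_table, config.predictors, reference_overrides=reference_overrides
        )
        y = obs_table.data[target].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate target within stratum {key!r}")
        fit = _fit_logistic(X, y, engine=config.engine if config.engine == "mle" else "mle")
        if config.engine == "penalized" and fit.engine == "mle":
            # user forced the penalised engine
            col_var = X.var(axis=0)
            alpha = RIDGE_SCALE * len(y) * col_var
            alpha[0] = 0.0
            coef, vcov, converged = _ridge_logit(X, y, alpha)
            fit = StratumFit(labels, coef, vcov, "penalized", converged, len(y))
        fit.labels = labels
        fit.dropped = dropped
        fits[key] = fit
    return FittedImputer(strata=fits, config=config)


# ---------------------------------------------------------------------------
# proper draws


def _nearest_psd(v: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Eigenvalue-clipped symmetric repair of a covariance matrix."""
    sym = (v + v.T) / 2.0
    w, q = np.linalg.eigh(sym)
    if np.all(w >= floor):
        return sym
    logger.warning("vcov not PSD; flooring eigenvalues at %.3g", floor)
    w = np.clip(w, floor, None)
    return (q * w) @ q.T


def _substream(seed: int, stratum_index: int, m: int) -> tuple[int, ...]:
    return (int(seed), int(stratum_index), int(m))


def draw_parameters(
    fitted: FittedImputer, stratum: object, m: int, seed: int | None = None
) -> CoefDraw:
    """Draw the coefficient vector for imputation m from its approximate posterior.

    Multivariate normal centred at the (possibly penalised) MLE with the
    estimated covariance.  Deterministic given (seed, stratum, m); a zero
    covariance returns the MLE exactly.
    """
    if seed is None:
        seed = fitted.config.seed
    keys = fitted.stratum_keys
    stratum_index = keys.index(stratum)
    fit = fitted.strata[stratum]
    key = _substream(seed, stratum_index, m)
    rng = np.random.default_rng(key)
    v = _nearest_psd(fit.vcov)
    w, q = np.linalg.eigh(v)
    scale = q * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal(len(fit.coef))
    coef = fit.coef + scale @ z
    return CoefDraw(coef=coef, m=m, stratum=stratum, substream=key)
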