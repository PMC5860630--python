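"""Rubin's-rules pooling of estimates across imputed data sets.

For M per-imputation estimates Q_m with variances U_m:

    Qbar = mean(Q_m)
    Wbar = mean(U_m)                     (within-imputation variance)
    B    = var(Q_m, ddof=1)              (between-imputation variance)
    T    = Wbar + (1 + 1/M) * B          (total variance)
    nu   = (M - 1) * (1 + Wbar / ((1 + 1/M) * B))**2   (df; inf when B = 0)

Intervals use the t quantile with nu degrees of freedom.  The same rules
apply element-wise to GLM coefficient vectors, with B replaced by the
between-imputation covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delta_mnar import CompletedSet

__all__ = [
    "PooledScalar",
    "PooledGlm",
    "pool_scalar",
    "pool_glm",
    "pooled_prevalence",
]


@dataclass(frozen=True)
class PooledScalar:
    """Rubin's-rules aggregate of one scalar estimand."""

    estimate: float
    within: float
    between: float
    total: float
    df: float
    M: int
    alpha: float = 0.05
    flag: str = ""

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    @property
    def ci(self) -> tuple[float, float]:
        if self.total == 0.0:
            return (self.estimate, self.estimate)
        q = (
            stats.norm.ppf(1 - self.alpha / 2)
            if np.isinf(self.df)
            else stats.t.ppf(1 - self.alpha / 2, self.df)
        )
        return (self.estimate - q * self.se, self.estimate + q * self.se)

    def as_percent(self) -> tuple[float, float]:
        """(estimate, SE) on the percent scale (for prevalence reporting)."""
        return 100.0 * self.estimate, 100.0 * self.se


@dataclass
class PooledGlm:
    """Rubin's-rules aggregate of a GLM coefficient vector."""

    labels: list[str]
    coef: np.ndarray
    vcov: np.ndarray  # Wbar + (1 + 1/M) B
    within: np.ndarray
    between: np.ndarray
    M: int

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.coef.shape != (k,) or self.vcov.shape != (k, k):
            raise ValueError("pooled GLM dimension mismatch")


def _rubin_df(M: int, wbar: float, b: float) -> float:
    if b <= 0.0 or M == 1:
        return np.inf
    return (M - 1) * (1.0 + wbar / ((1.0 + 1.0 / M) * b)) ** 2


def pool_scalar(
    estimates: Sequence[float],
    variances: Sequence[float],
    *,
    alpha: float = 0.05,
    flag: str = "",
) -> PooledScalar:
    """Pool M scalar estimates and their within-imputation variances."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    M = len(q)
    if M == 0:
        raise ValueError("cannot pool zero imputations")
    if len(u) != M:
        raise ValueError("estimates and variances length mismatch")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    wbar = float(u.mean())
    if M == 1:
        warnings.warn("pooling a single imputation: between-variance set to 0")
        b = 0.0
    else:
        b = float(q.var(ddof=1))
    total = wbar + (1.0 + 1.0 / M) * b
    return PooledScalar(
        estimate=qbar, within=wbar, between=b, total=total,
        df=_rubin_df(M, wbar, b), M=M, alpha=alpha, flag=flag,
    )


def pool_glm(
    fits: Sequence[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[Sequence[str]] | Sequence[str],
) -> PooledGlm:
    """Pool M (coefficients, vcov) pairs with identical labels and order.

    The between-imputation covariance is the sample covariance of the
    coefficient vectors (outer-product sum over beta_m - betabar, divided
    by M - 1).
    """
    M = len(fits)
    if M == 0:
        raise ValueError("cannot pool zero fits")
    if labels and isinstance(labels[0], str):
        label_sets = [list(labels)] * M
    else:
        label_sets = [list(l) for l in labels]
    ref = label_sets[0]
    for i, ls in enumerate(label_sets[1:], start=1):
        if ls != ref:
            diff = sorted(set(ls).symmetric_difference(ref))
            raise ValueError(f"coefficient labels differ at imputation {i}: {diff}")
    coefs = np.stack([np.asarray(c, dtype=float) for c, _ in fits])
    vcovs = np.stack([np.asarray(v, dtype=float) for _, v in fits])
    betabar = coefs.mean(axis=0)
    wbar = vcovs.mean(axis=0)
    if M == 1:
        warnings.warn("pooling a single fit: between-covariance set to 0")
        b = np.zeros_like(wbar)
    else:
        dev = coefs - betabar
        b = dev.T @ dev / (M - 1)
    pooled = wbar + (1.0 + 1.0 / M) * b
    return PooledGlm(
        labels=ref, coef=betabar, vcov=pooled, within=wbar, between=b, M=M
    )


def pooled_prevalence(
    completed: CompletedSet,
    subgroup: Callable[[pd.DataFrame], np.ndarray] | None = None,
    *,
    alpha: float = 0.05,
) -> PooledScalar:
    """Rubin-pooled prevalence of the target, optionally within a subgroup.

    Per imputation the estimate is the proportion of 1s and the within
    variance is binomial, p(1 - p)/n.  ``subgroup`` maps the completed
    data frame to a boolean row mask; rows are identical across
    imputations for fully observed grouping variables, so the subgroup is
    fixed across m.
    """
    ests, vars_ = [], []
    for t in completed.tables:
        df = t.data
        mask = np.ones(len(df), dtype=bool) if subgroup is None else np.asarray(
            subgroup(df), dtype=bool
        )
        n = int(mask.sum())
        if n == 0:
            return PooledScalar(
                estimate=np.nan, within=np.nan, between=np.nan, total=np.nan,
                df=np.nan, M=completed.M, alpha=alpha, flag="empty subgroup",
            )
        p = float(df.loc[mask, completed.target].mean())
        ests.append(p)
        vars_.append(p * (1.0 - p) / n)
    return pool_scalar(ests, vars_, alpha=alpha)
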