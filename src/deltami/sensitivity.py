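"""Sensitivity-analysis drivers: complete-case, best/worst case, MNAR grids.

The suite mirrors common practice for an incomplete binary prevalence
target: a complete-case analysis (observed rows only), deterministic
best-case (all missing imputed 0) and worst-case (all 1) bounds, multiple
imputation under MAR, and a grid of delta-adjusted MNAR imputations whose
pooled estimates are scanned for tipping points — delta values at which
the qualitative inference changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import RoleMap, StudyTable, round_half_up
from .delta_mnar import CompletedSet, DeltaSpec, impute_mnar
from .impute_mar import FittedImputer, ImputationConfig, fit_imputation_model
from .pooling import PooledScalar, pool_scalar, pooled_prevalence

__all__ = [
    "SensitivityGrid",
    "Subgroup",
    "default_subgroups",
    "complete_case",
    "extreme_case",
    "run_sensitivity",
    "tipping_point",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subgroup:
    """A labelled row filter: column == level, or overall when column is None."""

    label: str
    column: str | None = None
    level: object | None = None

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.column is None:
            return np.ones(len(df), dtype=bool)
        return (df[self.column] == self.level).to_numpy()


def default_subgroups(table: StudyTable, roles: RoleMap) -> list[Subgroup]:
    """Overall, one subgroup per stratum level, one per auxiliary level."""
    groups = [Subgroup("overall")]
    for col in (roles.strata, roles.auxiliary):
        if col is None:
            continue
        spec = table.schema[col]
        levels = spec.levels if spec.kind == "categorical" else (0.0, 1.0)
        for lev in levels:
            groups.append(Subgroup(f"{col}={lev}", col, lev))
    return groups


@dataclass
class SensitivityGrid:
    """Long-format grid results plus metadata.

    ``records`` columns: the exp-scale delta coordinates (one column per
    delta component), ``estimand``, ``subgroup``, ``estimate``, ``se`` and
    ``flag``.  One row per (delta spec x estimand x subgroup).
    """

    records: pd.DataFrame
    delta_columns: list[str]
    metadata: dict = field(default_factory=dict)

    def contour_matrix(
        self, row: str, col: str, *, estimand: str = "prevalence",
        subgroup: str = "overall", fixed: Mapping[str, float] | None = None,
    ) -> pd.DataFrame:
        """Pivot the grid into a matrix (rows exp delta_row, cols exp delta_col)."""
        df = self.records
        df = df[(df["estimand"] == estimand) & (df["subgroup"] == subgroup)]
        for k, v in (fixed or {}).items():
            df = df[np.isclose(df[k], v)]
        return df.pivot_table(index=row, columns=col, values="estimate")


def _binomial_prevalence(df: pd.DataFrame, target: str, mask: np.ndarray) -> tuple:
    n = int(mask.sum())
    if n == 0:
        return np.nan, np.nan, n, "empty subgroup"
    p = float(df.loc[mask, target].mean())
    se = float(np.sqrt(p * (1.0 - p) / n))
    return p, se, n, ""


def complete_case(
    table: StudyTable, roles: RoleMap, subgroups: Sequence[Subgroup] | None = None
) -> pd.DataFrame:
    """Prevalence of the target among observed rows (R = 1) per subgroup.

    Percent is also reported half-up to one decimal, matching survey-table
    display.
    """
    if subgroups is None:
        subgroups = default_subgroups(table, roles)
    r = table.response_indicator(roles.target)
    obs = table.data.loc[r == 1]
    rows = []
    for g in subgroups:
        p, se, n, flag = _binomial_prevalence(obs, roles.target, g.mask(obs))
        rows.append(
            {"analysis": "complete_case", "subgroup": g.label, "n": n,
             "prevalence": p, "se": se,
             "pct": round_half_up(100 * p) if n else np.nan, "flag": flag}
        )
    return pd.DataFrame(rows)


def extreme_case(
    table: StudyTable,
    roles: RoleMap,
    fill: int,
    subgroups: Sequence[Subgroup] | None = None,
) -> pd.DataFrame:
    """Deterministic single imputation: all missing targets set to `fill`.

    fill = 1 is the worst case (upper bound) for a prevalence, fill = 0 the
    best case (lower bound).
    """
    if fill not in (0, 1):
        raise ValueError("fill must be 0 or 1")
    if subgroups is None:
        subgroups = default_subgroups(table, roles)
    filled = table.data.copy()
    filled[roles.target] = filled[roles.target].fillna(float(fill))
    rows = []
    name = "worst_case" if fill == 1 else "best_case"
    for g in subgroups:
        p, se, n, flag = _binomial_prevalence(filled, roles.target, g.mask(filled))
        rows.append(
            {"analysis": name, "subgroup": g.label, "n": n, "prevalence": p,
             "se": se, "pct": round_half_up(100 * p) if n else np.nan,
             "flag": flag}
        )
    return pd.DataFrame(rows)


def _delta_coordinates(spec: DeltaSpec) -> dict[str, float]:
    """Grid coordinates on the exp (odds) scale for reporting."""
    if spec.mode == "common":
        return {"exp_delta": float(np.exp(spec.delta))}
    return {f"exp_delta[{z}]": float(np.exp(d)) for z, d in spec.group_map}


def run_sensitivity(
    table: StudyTable,
    roles: RoleMap,
    config: ImputationConfig,
    grid: Sequence[DeltaSpec],
    *,
    estimands: Sequence[str] = ("prevalence",),
    subgroups: Sequence[Subgroup] | None = None,
    contrasts: Sequence[tuple[str, str]] | None = None,
    rng_mode: str = "common",
    reference_overrides: Mapping[str, str] | None = None,
) -> SensitivityGrid:
    """Run the delta grid: one MNAR imputation + pooled analysis per spec.

    The imputation model is fitted once (the deltas never enter the fit)
    and shared across all grid points; with the default common-random-
    numbers mode the same per-row uniforms are reused at every point, so
    pooled prevalences are exactly monotone along each delta axis.

    A failed grid point is recorded with a flag rather than aborting the
    scan.
    """
    if len(grid) == 0:
        raise ValueError("empty delta grid")
    if subgroups is None:
        subgroups = default_subgroups(table, roles)
    imputer = fit_imputation_model(
        table, roles.target, config, reference_overrides=reference_overrides
    )
    records: list[dict] = []
    delta_cols: list[str] = []
    for spec in grid:
        coords = _delta_coordinates(spec)
        for c in coords:
            if c not in delta_cols:
                delta_cols.append(c)
        try:
            completed = impute_mnar(
                table, roles.target, config, spec, imputer=imputer,
                reference_overrides=reference_overrides, rng_mode=rng_mode,
            )
        except Exception as exc:
            logger.warning("grid point %s failed: %s", coords, exc)
            for g in subgroups:
                records.append(
                    {**coords, "estimand": "prevalence", "subgroup": g.label,
                     "estimate": np.nan, "se": np.nan, "flag": f"failed: {exc}"}
                )
            continue
        if "prevalence" in estimands:
            for g in subgroups:
                ps = pooled_prevalence(completed, g.mask)
                records.append(
                    {**coords, "estimand": "prevalence", "subgroup": g.label,
                     "estimate": ps.estimate, "se": ps.se, "flag": ps.flag}
                )
        if "mediation" in estimands:
            from .mediation import mediation_mi

            med = mediation_mi(completed, roles, contrasts)
            for (a, a_star), eff in med.items():
                avg = eff.table[eff.table["pattern"] == "average"].iloc[0]
                for name in ("nde", "nie", "te"):
                    records.append(
                        {**coords, "estimand": f"{name}:{a} vs {a_star}",
                         "subgroup": "average", "estimate": avg[f"or_{name}"],
                         "se": avg[f"se_log_{name}"], "flag": ""}
                    )
    meta = {
        "rng_mode": rng_mode, "M": config.M, "seed": config.seed,
        "n_grid_points": len(grid), "estimands": list(estimands),
    }
    return SensitivityGrid(
        records=pd.DataFrame(records), delta_columns=delta_cols, metadata=meta
    )


def tipping_point(
    grid: SensitivityGrid,
    threshold: float,
    *,
    estimand: str = "prevalence",
    subgroup: str = "overall",
) -> pd.DataFrame:
    """Locate where the estimand crosses `threshold` along each delta axis.

    For each axis, records are grouped by the values of the remaining axes
    and sorted along the axis; every adjacent pair straddling the threshold
    is reported as an interval, with a linearly interpolated crossing on
    the log-delta scale.  An empty result means no crossing in range.
    """
    df = grid.records
    df = df[(df["estimand"] == estimand) & (df["subgroup"] == subgroup)].copy()
    if df.empty:
        raise ValueError(f"no grid records for {estimand!r} / {subgroup!r}")
    crossings = []
    for axis in grid.delta_columns:
        others = [c for c in grid.delta_columns if c != axis]
        grouped = df.groupby(others, sort=True) if others else [((), df)]
        for key, sub in grouped:
            sub = sub.sort_values(axis)
            vals = sub[axis].to_numpy(dtype=float)
            est = sub["estimate"].to_numpy(dtype=float)
            for i in range(len(sub) - 1):
                lo, hi = est[i] - threshold, est[i + 1] - threshold
                if lo == 0.0 or np.isnan(lo) or np.isnan(hi):
                    continue
                if lo * hi <= 0.0 and lo != hi:
                    # interpolate on log(exp delta) = delta scale
                    x0, x1 = np.log(vals[i]), np.log(vals[i + 1])
                    frac = lo / (lo - hi)
                    cross = float(np.exp(x0 + frac * (x1 - x0)))
                    crossings.append(
                        {"axis": axis, "lower": vals[i], "upper": vals[i + 1],
                         "interpolated": cross,
                         **dict(zip(others, key if isinstance(key, tuple) else (key,)))}
                    )
    return pd.DataFrame(crossings)
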