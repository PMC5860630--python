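"""Study-table I/O, variable roles, and missingness summaries.

A study table is a rectangular survey data set with one incomplete binary
target variable (e.g. an HIV serological test result), fully observed
covariates, and optionally a fully observed categorical auxiliary variable
(e.g. 4-level self-reported HIV status) that predicts both the target and
its missingness.  Missingness must be univariate: only the target column
may contain missing entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Column",
    "Schema",
    "StudyTable",
    "RoleMap",
    "MissingnessSummary",
    "SchemaError",
    "UnivariateMissingnessError",
    "load_table",
    "write_table",
    "load_config",
    "missingness_summary",
    "crude_and_adjusted_or",
    "round_half_up",
]

#: Accepted encodings of a missing entry in CSV input.
MISSING_MARKERS = ("", "NA")


class SchemaError(ValueError):
    """A value or column does not conform to the declared schema."""


class UnivariateMissingnessError(ValueError):
    """More than one column contains missing entries."""


@dataclass(frozen=True)
class Column:
    """Declared kind of one variable.

    kind is one of ``binary`` (0/1), ``categorical`` (with an ordered level
    list whose first entry is the default reference) or ``count``.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "count"):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(f"categorical column {self.name!r} needs >=2 levels")
        elif self.levels is not None:
            raise SchemaError(f"{self.kind} column {self.name!r} must not declare levels")


class Schema:
    """Ordered collection of :class:`Column` declarations."""

    def __init__(self, columns: Iterable[Column]):
        self.columns = {c.name: c for c in columns}
        if not self.columns:
            raise SchemaError("schema is empty")

    def __getitem__(self, name: str) -> Column:
        return self.columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def __iter__(self):
        return iter(self.columns.values())

    @property
    def names(self) -> list[str]:
        return list(self.columns)


@dataclass
class StudyTable:
    """A validated rectangular survey table with at most one incomplete column.

    ``data`` holds one row per respondent; the incomplete column (if any) uses
    ``NaN`` for missing entries and floats elsewhere; categorical columns hold
    strings drawn from their declared level list.
    """

    data: pd.DataFrame
    schema: Schema

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("study table must have n >= 1 rows")
        missing_cols = [c for c in self.schema.names if self.data[c].isna().any()]
        if len(missing_cols) > 1:
            raise UnivariateMissingnessError(
                f"univariate missingness violated: columns {missing_cols} all contain "
                "missing entries"
            )
        self._missing_column = missing_cols[0] if missing_cols else None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_column(self) -> str | None:
        """Name of the unique column with missing entries, or None."""
        return self._missing_column

    def response_indicator(self, target: str) -> np.ndarray:
        """R = 1 where the target is observed, 0 where missing."""
        return (~self.data[target].isna()).to_numpy(dtype=int)

    def copy(self) -> "StudyTable":
        return StudyTable(self.data.copy(), self.schema)


@dataclass(frozen=True)
class RoleMap:
    """Assignment of analysis roles to table columns.

    The reference level of the exposure defaults to the first declared level
    of its column; override with ``exposure_reference``.
    """

    target: str
    outcome: str | None = None
    exposure: str | None = None
    exposure_reference: str | None = None
    mediator: str | None = None
    auxiliary: str | None = None
    confounders: tuple[str, ...] = ()
    strata: str | None = None

    def validate(self, schema: Schema) -> None:
        named = {
            "target": self.target,
            "outcome": self.outcome,
            "exposure": self.exposure,
            "mediator": self.mediator,
            "auxiliary": self.auxiliary,
            "strata": self.strata,
        }
        for role, col in named.items():
            if col is not None and col not in schema:
                raise SchemaError(f"{role} column {col!r} not in schema")
        for col in self.confounders:
            if col not in schema:
                raise SchemaError(f"confounder column {col!r} not in schema")
        if schema[self.target].kind != "binary":
            raise SchemaError(f"target {self.target!r} must be binary")
        if self.auxiliary is not None and schema[self.auxiliary].kind != "categorical":
            raise SchemaError(f"auxiliary {self.auxiliary!r} must be categorical")
        # conflicting roles: target may not double as any other analysis role
        # except the mediator (the incomplete variable IS the mediator in the
        # mediation analysis).
        others = [self.outcome, self.exposure, self.auxiliary, self.strata]
        if self.target in [c for c in others if c is not None]:
            raise SchemaError(f"target {self.target!r} holds a conflicting second role")
        if self.exposure is not None and self.exposure_reference is not None:
            levels = schema[self.exposure].levels or ()
            if self.exposure_reference not in levels:
                raise SchemaError(
                    f"exposure reference {self.exposure_reference!r} not a level of "
                    f"{self.exposure!r}"
                )


@dataclass
class MissingnessSummary:
    """Per-subgroup missingness counts, mirroring survey report layout.

    ``records`` has columns: the grouping variables, ``n_missing``,
    ``n_at_risk``, ``pct_missing`` (one decimal, half-up) and ``flag``
    (set to ``"empty subgroup"`` where n_at_risk is zero, with pct left NA).
    """

    records: pd.DataFrame
    by: tuple[str, ...]

    @property
    def total_missing(self) -> int:
        return int(self.records["n_missing"].sum())


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at `decimals`, matching printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# loading / writing


def _parse_column(raw: pd.Series, col: Column) -> pd.Series:
    vals = raw.astype("string").str.strip()
    is_missing = vals.isin(MISSING_MARKERS) | vals.isna()
    if col.kind == "categorical":
        bad = set(vals[~is_missing]) - set(col.levels)
        if bad:
            raise SchemaError(
                f"unknown category level(s) {sorted(bad)} in column {col.name!r}; "
                f"declared levels are {list(col.levels)}"
            )
        out = vals.where(~is_missing, other=pd.NA)
        return out.astype(object).where(out.notna(), np.nan)
    numeric = pd.to_numeric(vals.where(~is_missing), errors="raise")
    arr = numeric.astype(float)
    obs = arr[~is_missing]
    if col.kind == "binary" and not obs.isin([0.0, 1.0]).all():
        bad = sorted(set(obs[~obs.isin([0.0, 1.0])]))
        raise SchemaError(f"binary column {col.name!r} has non-0/1 value(s) {bad}")
    if col.kind == "count" and ((obs < 0) | (obs != obs.round())).any():
        raise SchemaError(f"count column {col.name!r} has negative or non-integer values")
    return arr


def load_table(
    path: str | Path,
    schema: Schema,
    *,
    target: str | None = None,
    drop_incomplete_covariates: bool = False,
) -> StudyTable:
    """Read a CSV with header into a validated :class:`StudyTable`.

    Missing entries may be encoded as the empty string or ``NA``.  If
    ``drop_incomplete_covariates`` is set, rows with missing entries in any
    column other than ``target`` are deleted (and counted in
    ``table.dropped_rows``) so the result has univariate missingness;
    otherwise such rows raise :class:`UnivariateMissingnessError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    extra = [c for c in schema.names if c not in raw.columns]
    if extra:
        raise SchemaError(f"file {path} is missing declared column(s) {extra}")
    parsed = pd.DataFrame({c.name: _parse_column(raw[c.name], c) for c in schema})
    dropped = 0
    if drop_incomplete_covariates and target is not None:
        others = [c for c in schema.names if c != target]
        keep = ~parsed[others].isna().any(axis=1)
        dropped = int((~keep).sum())
        parsed = parsed.loc[keep].reset_index(drop=True)
    table = StudyTable(parsed, schema)
    table.dropped_rows = dropped  # type: ignore[attr-defined]
    return table


def write_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table to CSV, encoding missing entries as ``NA``."""
    out = table.data.copy()
    for col in table.schema:
        if col.kind in ("binary", "count"):
            s = out[col.name]
            out[col.name] = s.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        else:
            out[col.name] = out[col.name].fillna("NA")
    out.to_csv(path, index=False)


def load_config(path: str | Path) -> tuple[Schema, RoleMap, dict]:
    """Read a YAML config declaring the schema, roles and run options.

    Expected layout::

        columns:
          - {name: hiv, kind: binary}
          - {name: region, kind: categorical, levels: [rural, urban]}
        roles:
          target: hiv
          ...
        options: {M: 25, seed: 1}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cols = [
        Column(
            name=c["name"],
            kind=c["kind"],
            levels=tuple(c["levels"]) if "levels" in c else None,
        )
        for c in cfg["columns"]
    ]
    schema = Schema(cols)
    roles_raw = dict(cfg.get("roles", {}))
    if "confounders" in roles_raw:
        roles_raw["confounders"] = tuple(roles_raw["confounders"])
    roles = RoleMap(**roles_raw)
    roles.validate(schema)
    return schema, roles, cfg.get("options", {})


def write_run_metadata(path: str | Path, **meta) -> None:
    """Persist run provenance (seeds, M, deltas, model spec) as JSON."""
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# summaries


def missingness_summary(
    table: StudyTable, roles: RoleMap, by: Sequence[str] = ()
) -> MissingnessSummary:
    """Tabulate refusal/missingness of the target per cross-category of `by`.

    Percent missing = 100 * n_missing / n_at_risk, half-up to one decimal.
    Empty subgroups are flagged rather than propagating NaN.
    """
    by = tuple(by)
    for c in by:
        if c not in table.schema:
            raise SchemaError(f"grouping column {c!r} not in schema")
        if table.data[c].isna().any():
            raise SchemaError(f"grouping column {c!r} is not fully observed")
    miss = table.data[roles.target].isna()
    if not by:
        df = pd.DataFrame(
            {"n_missing": [int(miss.sum())], "n_at_risk": [table.n]}
        )
    else:
        grouped = pd.DataFrame({"_miss": miss.to_numpy()}, index=table.data.index)
        for c in by:
            grouped[c] = table.data[c].to_numpy()
        agg = grouped.groupby(list(by), sort=True, dropna=False)["_miss"].agg(
            n_missing="sum", n_at_risk="size"
        )
        # include declared-but-unobserved cross categories as empty subgroups
        levels = [
            list(table.schema[c].levels)
            if table.schema[c].kind == "categorical"
            else sorted(grouped[c].unique())
            for c in by
        ]
        if len(by) == 1:
            full_index = pd.Index(levels[0], name=by[0])
        else:
            full_index = pd.MultiIndex.from_product(levels, names=list(by))
        agg = agg.reindex(full_index)
        agg["n_missing"] = agg["n_missing"].fillna(0).astype(int)
        agg["n_at_risk"] = agg["n_at_risk"].fillna(0).astype(int)
        df = agg.reset_index()
    pct = [
        round_half_up(100.0 * m / r) if r > 0 else np.nan
        for m, r in zip(df["n_missing"], df["n_at_risk"])
    ]
    df["pct_missing"] = pct
    df["flag"] = np.where(df["n_at_risk"] == 0, "empty subgroup", "")
    return MissingnessSummary(records=df, by=by)


def crude_and_adjusted_or(
    table: StudyTable,
    event: str,
    factor: str,
    adjusters: Sequence[str] = (),
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Odds ratios (Wald 95% CI) for `event` per non-reference level of `factor`.

    One logistic regression of the binary event on the factor plus the
    adjusters (e.g. age and region), restricted to rows where the event is
    observed.  Non-convergence or separation falls back to a weak ridge
    penalty and is flagged in the ``engine`` column.
    """
    from .impute_mar import build_design, _fit_logistic  # local import: avoids cycle

    data = table.data.loc[~table.data[event].isna()]
    if data.empty:
        raise ValueError("no rows with the event observed")
    sub = StudyTable(data.reset_index(drop=True), table.schema)
    predictors = [factor, *adjusters]
    X, labels, dropped = build_design(sub, predictors)
    y = sub.data[event].to_numpy(dtype=float)
    fit = _fit_logistic(X, y)
    z = float(_normal_quantile(1 - alpha / 2))
    rows = []
    fac = table.schema[factor]
    fac_levels = fac.levels if fac.kind == "categorical" else ("0", "1")
    for i, lev in enumerate(fac_levels):
        label = f"{factor}[{lev}]" if fac.kind == "categorical" else factor
        if i == 0:
            rows.append(
                {"factor": factor, "level": lev, "or": 1.0, "lo": np.nan,
                 "hi": np.nan, "reference": True, "engine": fit.engine}
            )
            continue
        if label not in labels:
            continue
        j = labels.index(label)
        b, se = fit.coef[j], np.sqrt(fit.vcov[j, j])
        rows.append(
            {"factor": factor, "level": lev, "or": float(np.exp(b)),
             "lo": float(np.exp(b - z * se)), "hi": float(np.exp(b + z * se)),
             "reference": False, "engine": fit.engine}
        )
    return pd.DataFrame(rows)


def _normal_quantile(p: float) -> float:
    from scipy.stats import norm

    return norm.ppf(p)
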