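"""Delta-adjusted imputation of a binary variable under MNAR.

After fitting the imputation model under MAR, a fixed log-odds offset delta
is added to the linear predictor of every missing row before imputing:

    logit Pr[Y = 1 | X, R] = phi_0 + phi_X' X + delta * (1 - R).

delta is the assumed difference in the log-odds of Y = 1 between rows with
missing and observed Y — a simple pattern-mixture model.  delta = 0
recovers MAR.  The offset may instead vary with a fully observed auxiliary
categorical variable Z (e.g. self-reported HIV status), giving one delta_z
per auxiliary level:

    ... + sum_z delta_z 1{Z = z} (1 - R).

The deltas enter only at imputation time; the model fit itself is always
the MAR fit to the observed rows.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import StudyTable
from .impute_mar import (
    CoefDraw,
    FittedImputer,
    ImputationConfig,
    build_design,
    draw_parameters,
    fit_imputation_model,
)

__all__ = [
    "DeltaSpec",
    "CompletedSet",
    "adjusted_probability",
    "impute_mnar",
    "impute_mar_set",
    "delta_grid_spec",
    "default_grid",
    "TABLE_GRID_RANGES",
]

#: Default sensitivity grid on the odds (exp delta) scale, one range per
#: assumed refusal type of the 4-level self-report auxiliary: strongly MNAR
#: for self-reported negatives and non-disclosers, MAR for self-reported
#: positives, weakly MNAR for the never tested.
TABLE_GRID_RANGES: tuple[tuple[float, ...], ...] = (
    (1.00, 1.25, 1.33, 1.50, 1.67, 2.00, 2.50, 3.00, 4.00, 5.00),
    (1.00,),
    (1.00, 1.25, 1.33, 1.50, 1.67, 2.00, 2.50, 3.00, 4.00, 5.00),
    (0.75, 0.80, 1.00, 1.25, 1.33),
)


@dataclass(frozen=True)
class DeltaSpec:
    """A log-odds offset: one common delta, or one delta per auxiliary level.

    Internally always on the log-odds scale.  Use :meth:`common` /
    :meth:`by_group` with ``exp_scale=True`` to pass odds-ratio-scale values.
    """

    mode: str  # {"common", "by_group"}
    delta: float = 0.0
    group_map: tuple[tuple[str, float], ...] = ()
    auxiliary: str | None = None
    default_delta: float | None = None  # fallback for unmapped levels, if set

    def __post_init__(self) -> None:
        if self.mode not in ("common", "by_group"):
            raise ValueError(f"unknown delta mode {self.mode!r}")
        if self.mode == "common":
            if not math.isfinite(self.delta):
                raise ValueError("delta must be finite")
        else:
            if self.auxiliary is None:
                raise ValueError("by_group mode requires the auxiliary column name")
            if not self.group_map:
                raise ValueError("by_group mode requires a non-empty group map")
            seen = [z for z, _ in self.group_map]
            if len(seen) != len(set(seen)):
                raise ValueError("duplicate auxiliary level in delta map")
            for z, d in self.group_map:
                if not math.isfinite(d):
                    raise ValueError(f"delta for level {z!r} must be finite")

    @classmethod
    def common(cls, delta: float, *, exp_scale: bool = False) -> "DeltaSpec":
        return cls(mode="common", delta=math.log(delta) if exp_scale else float(delta))

    @classmethod
    def by_group(
        cls,
        mapping: Mapping[str, float],
        auxiliary: str,
        *,
        exp_scale: bool = False,
        default_delta: float | None = None,
    ) -> "DeltaSpec":
        items = tuple(
            (str(z), math.log(d) if exp_scale else float(d)) for z, d in mapping.items()
        )
        return cls(
            mode="by_group",
            group_map=items,
            auxiliary=auxiliary,
            default_delta=default_delta,
        )

    def as_dict(self) -> dict[str, float]:
        if self.mode == "common":
            return {"delta": self.delta}
        return dict(self.group_map)

    def is_mar(self) -> bool:
        """True when the spec is the MAR special case (all deltas zero)."""
        if self.mode == "common":
            return self.delta == 0.0
        return all(d == 0.0 for _, d in self.group_map)

    def row_offsets(self, table: StudyTable, rows: np.ndarray) -> np.ndarray:
        """Per-row delta for the given (missing-)row positions."""
        if self.mode == "common":
            return np.full(len(rows), self.delta)
        zvals = table.data[self.auxiliary].to_numpy()[rows]
        lookup = dict(self.group_map)
        out = np.empty(len(rows))
        for i, z in enumerate(zvals):
            if z in lookup:
                out[i] = lookup[z]
            elif self.default_delta is not None:
                out[i] = self.default_delta
            else:
                raise ValueError(
                    f"auxiliary level {z!r} has no delta in the group map and no "
                    "default_delta was set"
                )
        return out

    def _stable_hash(self) -> int:
        text = repr((self.mode, self.delta, self.group_map, self.auxiliary))
        return zlib.crc32(text.encode())


@dataclass
class CompletedSet:
    """M completed copies of a study table plus provenance.

    Completed tables contain no missing entries; rows observed in the input
    are identical to the input in every copy.
    """

    tables: list[StudyTable]
    target: str
    delta: DeltaSpec
    config: ImputationConfig
    rng_mode: str
    imputer: FittedImputer | None = None

    @property
    def M(self) -> int:
        return len(self.tables)

    def provenance(self) -> dict:
        return {
            "M": self.M,
            "target": self.target,
            "delta_mode": self.delta.mode,
            "delta": self.delta.as_dict(),
            "seed": self.config.seed,
            "predictors": list(self.config.predictors),
            "strata": self.config.strata,
            "rng_mode": self.rng_mode,
            "engines": {
                str(k): f.engine for k, f in (self.imputer.strata.items() if self.imputer else {})
            },
        }


def adjusted_probability(linpred: float | np.ndarray, delta: float) -> float | np.ndarray:
    """Inverse-logit of (linear predictor + delta).

    Adding delta multiplies the odds of Y = 1 by exp(delta); the result is
    strictly increasing in delta and saturates smoothly at 0 and 1.
    """
    return expit(np.asarray(linpred, dtype=float) + delta)


#: RNG stream tag separating imputation uniforms from coefficient draws.
_UNIFORM_STREAM = 910109


def impute_mnar(
    table: StudyTable,
    target: str,
    config: ImputationConfig,
    delta: DeltaSpec,
    *,
    imputer: FittedImputer | None = None,
    reference_overrides: Mapping[str, str] | None = None,
    rng_mode: str = "common",
) -> CompletedSet:
    """Generate M completed tables under the delta-adjusted (MNAR) model.

    For each imputation m: draw imputation-model coefficients from their
    approximate posterior, compute the linear predictor of every missing
    row, add the row's applicable delta, and impute Bernoulli.

    With ``rng_mode="common"`` (the default) the per-row uniforms depend
    only on (seed, m), not on delta, so re-running with a different
    DeltaSpec reuses the same uniforms: imputed totals are then exactly
    monotone in each delta component, and delta = 0 reproduces the MAR
    imputer bit for bit.  ``rng_mode="independent"`` keys the uniforms by
    the delta values as well.

    A prefitted ``imputer`` may be passed to share one MAR fit across a
    whole sensitivity grid (the deltas never enter the fit).
    """
    if delta.mode == "by_group":
        if delta.auxiliary not in config.predictors:
            raise ValueError(
                "group-specific deltas require the auxiliary variable among the "
                "imputation predictors"
            )
        aux_levels = set(table.data[delta.auxiliary].dropna().unique())
        mapped = {z for z, _ in delta.group_map}
        unmapped = aux_levels - mapped
        if unmapped and delta.default_delta is None:
            raise ValueError(
                f"auxiliary level(s) {sorted(unmapped)} absent from the delta map; "
                "set default_delta explicitly to permit a fallback"
            )
    if rng_mode not in ("common", "independent"):
        raise ValueError(f"unknown rng_mode {rng_mode!r}")

    if imputer is None:
        imputer = fit_imputation_model(
            table, target, config, reference_overrides=reference_overrides
        )

    data = table.data
    r = table.response_indicator(target)
    missing_rows = np.flatnonzero(r == 0)

    # per-stratum missing-row designs, built once
    stratum_designs: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    for key, fit in imputer.strata.items():
        if key is None:
            rows = missing_rows
        else:
            in_stratum = (data[config.strata] == key).to_numpy()
            rows = missing_rows[in_stratum[missing_rows]]
        if len(rows) == 0:
            stratum_designs[key] = (rows, np.empty((0, len(fit.coef))))
            continue
        sub = StudyTable(data.iloc[rows].reset_index(drop=True), table.schema)
        X, labels, _ = build_design(
            sub, config.predictors, reference_overrides=reference_overrides
        )
        # align to the fitted design: keep only fitted columns, in fit order
        idx = []
        for lab in fit.labels:
            if lab in labels:
                idx.append(labels.index(lab))
            else:
                idx.append(-1)  # fitted column absent here (cannot happen w/ dummies)
        Xa = np.zeros((len(rows), len(fit.labels)))
        for j, src in enumerate(idx):
            if src >= 0:
                Xa[:, j] = X[:, src]
        stratum_designs[key] = (rows, Xa)

    pos_in_missing = {row: i for i, row in enumerate(missing_rows)}

    completed: list[StudyTable] = []
    for m in range(config.M):
        if rng_mode == "common":
            u_key = (config.seed, _UNIFORM_STREAM, m)
        else:
            u_key = (config.seed, _UNIFORM_STREAM, m, delta._stable_hash())
        u = np.random.default_rng(u_key).random(len(missing_rows))
        filled = data[target].to_numpy(dtype=float).copy()
        for key, fit in imputer.strata.items():
            rows, Xa = stratum_designs[key]
            if len(rows) == 0:
                continue
            draw = draw_parameters(imputer, key, m, config.seed)
            linpred = Xa @ draw.coef
            offsets = delta.row_offsets(table, rows)
            p = expit(linpred + offsets)
            u_rows = u[[pos_in_missing[rr] for rr in rows]]
            filled[rows] = (u_rows < p).astype(float)
        new = data.copy()
        new[target] = filled
        completed.append(StudyTable(new, table.schema))
    return CompletedSet(
        tables=completed,
        target=target,
        delta=delta,
        config=config,
        rng_mode=rng_mode,
        imputer=imputer,
    )


def impute_mar_set(
    table: StudyTable,
    target: str,
    config: ImputationConfig,
    *,
    imputer: FittedImputer | None = None,
    reference_overrides: Mapping[str, str] | None = None,
) -> CompletedSet:
    """Generate M completed tables under MAR (no delta adjustment).

    Uses the same coefficient-draw and uniform RNG substreams as
    :func:`impute_mnar`, so a delta of zero there reproduces this output
    exactly.
    """
    if imputer is None:
        imputer = fit_imputation_model(
            table, target, config, reference_overrides=reference_overrides
        )
    data = table.data
    r = table.response_indicator(target)
    missing_rows = np.flatnonzero(r == 0)
    pos_in_missing = {row: i for i, row in enumerate(missing_rows)}

    completed: list[StudyTable] = []
    for m in range(config.M):
        u = np.random.default_rng((config.seed, _UNIFORM_STREAM, m)).random(
            len(missing_rows)
        )
        filled = data[target].to_numpy(dtype=float).copy()
        for key, fit in imputer.strata.items():
            if key is None:
                rows = missing_rows
            else:
                in_stratum = (data[config.strata] == key).to_numpy()
                rows = missing_rows[in_stratum[missing_rows]]
            if len(rows) == 0:
                continue
            sub = StudyTable(data.iloc[rows].reset_index(drop=True), table.schema)
            X, labels, _ = build_design(
                sub, config.predictors, reference_overrides=reference_overrides
            )
            Xa = np.zeros((len(rows), len(fit.labels)))
            for j, lab in enumerate(fit.labels):
                if lab in labels:
                    Xa[:, j] = X[:, labels.index(lab)]
            draw = draw_parameters(imputer, key, m, config.seed)
            p = expit(Xa @ draw.coef)
            u_rows = u[[pos_in_missing[rr] for rr in rows]]
            filled[rows] = (u_rows < p).astype(float)
        new = data.copy()
        new[target] = filled
        completed.append(StudyTable(new, table.schema))
    return CompletedSet(
        tables=completed,
        target=target,
        delta=DeltaSpec.common(0.0),
        config=config,
        rng_mode="common",
        imputer=imputer,
    )


def delta_grid_spec(
    ranges: Mapping[str, Sequence[float]] | Sequence[float],
    *,
    auxiliary: str | None = None,
    exp_scale: bool = True,
) -> list[DeltaSpec]:
    """Cartesian product of per-group delta ranges, in lexicographic order.

    ``ranges`` is either a mapping auxiliary-level -> sequence of values
    (group-specific grid) or a flat sequence (common-delta grid).  Values
    are on the odds (exp delta) scale by default.
    """
    if isinstance(ranges, Mapping):
        if auxiliary is None:
            raise ValueError("auxiliary column name required for a group-specific grid")
        levels = list(ranges)
        for z, rng in ranges.items():
            if len(rng) == 0:
                raise ValueError(f"empty delta range for group {z!r}")
        combos = itertools.product(*(ranges[z] for z in levels))
        return [
            DeltaSpec.by_group(dict(zip(levels, combo)), auxiliary, exp_scale=exp_scale)
            for combo in combos
        ]
    vals = list(ranges)
    if not vals:
        raise ValueError("empty delta range")
    return [DeltaSpec.common(v, exp_scale=exp_scale) for v in vals]


def default_grid(aux_levels: Sequence[str], auxiliary: str) -> list[DeltaSpec]:
    """The default 500-point sensitivity grid for a 4-level auxiliary.

    Level order: self-reported negative, self-reported positive,
    refused to disclose, never tested.
    """
    if len(aux_levels) != 4:
        raise ValueError("default grid is defined for a 4-level auxiliary")
    ranges = {z: list(r) for z, r in zip(aux_levels, TABLE_GRID_RANGES)}
    return delta_grid_spec(ranges, auxiliary=auxiliary, exp_scale=True)
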