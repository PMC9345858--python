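"""Survival association of spatial immune scores.

Kaplan–Meier curves with log-rank comparisons, proportional-hazards
regression (univariable and covariate-adjusted) with trend tests over
ordinal score categories, follow-up truncation, and subgroup/interaction
analyses.  Partial-likelihood numerics are delegated to lifelines
(Efron tie handling, Wald confidence intervals on the log-HR scale).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .exceptions import FitError, ValidationError

DAYS_PER_YEAR = 365.25

#: endpoint -> event column; the analysis time column is always time_days.
ENDPOINTS = {"CSS": "event_css", "OS": "event_os"}

#: Adjustment covariates with ordered levels, reference level first.
DEFAULT_COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "age_group": ("<65", "65-75", ">75"),
    "year_of_operation": ("2000-2005", "2006-2010", "2011-2015"),
    "tumour_location": ("proximal colon", "distal colon", "rectum"),
    "stage": ("I-II", "III", "IV"),
    "grade": ("low", "high"),
    "lymphovascular_invasion": ("no", "yes"),
    "mmr": ("proficient", "deficient"),
    "braf": ("wild-type", "mutant"),
}

ALPHA = 0.005  # stringent significance threshold used when flagging results


@dataclass
class SurvivalResult:
    """Hazard-ratio table for one model plus trend p-values.

    ``table`` has one row per exposure level (variable, level, n, events,
    hr, ci_low, ci_high); ``p_trend`` maps each exposure to the Wald p-value
    of its ordinal-as-continuous coding; ``n_imputed`` counts
    majority-category assignments per covariate.
    """

    table: pd.DataFrame
    p_trend: dict[str, float]
    trend_coef: dict[str, float]
    trend_se: dict[str, float]
    endpoint: str
    covariates: tuple[str, ...]
    n_imputed: dict[str, int] = field(default_factory=dict)
    alpha: float = ALPHA


@dataclass
class KMResult:
    """Per-group product-limit curves plus the log-rank comparison."""

    curves: pd.DataFrame  # columns group, time, survival
    statistic: float
    p_value: float
    groups: tuple[str, ...]


def truncate_followup(records: pd.DataFrame, horizon_years: float = 10.0) -> pd.DataFrame:
    """Administratively censor all follow-up beyond ``horizon_years``.

    Times past the horizon are set to the horizon with every event flag
    cleared; times at or below it are untouched.
    """
    if horizon_years <= 0:
        raise ValidationError(f"horizon must be positive, got {horizon_years}")
    out = records.copy()
    if not np.isfinite(horizon_years):
        return out
    horizon_days = horizon_years * DAYS_PER_YEAR
    over = out["time_days"] > horizon_days
    for col in ENDPOINTS.values():
        if col in out.columns:
            out.loc[over, col] = 0
    out.loc[over, "time_days"] = horizon_days
    return out


def _event_column(records: pd.DataFrame, endpoint: str) -> str:
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; expected one of {list(ENDPOINTS)}")
    col = ENDPOINTS[endpoint]
    if col not in records.columns:
        raise ValidationError(f"records lack event column '{col}'")
    return col


def km_logrank(records: pd.DataFrame, group_col: str, endpoint: str = "CSS") -> KMResult:
    """Kaplan–Meier curves per group and the log-rank test across groups."""
    event_col = _event_column(records, endpoint)
    groups = [g for g, sub in records.groupby(group_col, observed=True) if len(sub)]
    if len(groups) < 2:
        raise ValidationError(f"log-rank needs >= 2 non-empty groups, got {len(groups)}")
    if int(records[event_col].sum()) == 0:
        raise ValidationError("no events in any group; log-rank test undefined")
    curves = []
    for g, sub in records.groupby(group_col, observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub[event_col], label=str(g))
        sf = kmf.survival_function_
        curves.append(
            pd.DataFrame(
                {"group": str(g), "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    res = multivariate_logrank_test(
        records["time_days"], records[group_col], records[event_col]
    )
    return KMResult(
        curves=pd.concat(curves, ignore_index=True),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        groups=tuple(str(g) for g in groups),
    )


def _levels_of(records: pd.DataFrame, col: str,
               level_map: Mapping[str, Sequence[str]]) -> list:
    if col in level_map:
        return [lv for lv in level_map[col] if lv in set(records[col].dropna())]
    series = records[col].dropna()
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [lv for lv in series.cat.categories if lv in set(series)]
    return sorted(series.unique())


def _impute_majority(records: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Assign missing categorical values to the majority category, with counts."""
    out = records.copy()
    counts: dict[str, int] = {}
    for col in cols:
        missing = out[col].isna()
        n_missing = int(missing.sum())
        if n_missing:
            majority = out[col].mode(dropna=True)
            if majority.empty:
                raise ValidationError(f"covariate '{col}' is entirely missing")
            out.loc[missing, col] = majority.iloc[0]
            counts[col] = n_missing
    return out, counts


def _design(records: pd.DataFrame, cols: Sequence[str],
            level_map: Mapping[str, Sequence[str]],
            ordinal: Sequence[str] = ()) -> tuple[pd.DataFrame, dict]:
    """Build the regression design: indicators vs reference, or 0..k codes.

    Returns the design frame and, per categorical column, the mapping
    level -> indicator column name (reference level maps to None).
    """
    parts = []
    meta: dict[str, dict] = {}
    for col in cols:
        series = records[col]
        if pd.api.types.is_numeric_dtype(series) and col not in level_map:
            parts.append(series.astype(float).rename(col))
            continue
        levels = _levels_of(records, col, level_map)
        if len(levels) < 2:
            raise FitError(f"column '{col}' is constant ({levels}); cannot enter the model")
        codes = series.map({lv: i for i, lv in enumerate(levels)})
        if codes.isna().any():
            raise ValidationError(f"column '{col}' has values outside its declared levels")
        if col in ordinal:
            parts.append(codes.astype(float).rename(f"{col}__trend"))
            meta[col] = {"levels": levels, "ordinal": True}
            continue
        colmap = {levels[0]: None}
        for i, lv in enumerate(levels[1:], start=1):
            name = f"{col}__{lv}"
            parts.append((codes == i).astype(float).rename(name))
            colmap[lv] = name
        meta[col] = {"levels": levels, "columns": colmap, "ordinal": False}
    return pd.concat(parts, axis=1), meta


def _fit_cox(design: pd.DataFrame, records: pd.DataFrame, event_col: str) -> CoxPHFitter:
    df = design.copy()
    df["time_days"] = records["time_days"].to_numpy(dtype=float)
    df["__event"] = records[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time_days", event_col="__event")
    except ConvergenceError as exc:  # pragma: no cover - surfaced, not synthesised
        raise FitError(f"proportional-hazards fit failed to converge: {exc}") from exc
    return cph


def ph_fit(
    records: pd.DataFrame,
    exposure: str | Sequence[str],
    *,
    adjust: Sequence[str] = (),
    endpoint: str = "CSS",
    level_map: Mapping[str, Sequence[str]] | None = None,
) -> SurvivalResult:
    """Proportional-hazards fit of one or more score exposures.

    Each categorical exposure enters as indicator variables against its
    first (reference) level; a second fit with the exposure's ordinal
    categories coded 0, 1, 2, … yields the trend test.  Several exposures
    may be passed together for reciprocal adjustment (both enter the same
    model).  Missing covariate values are assigned to the majority category
    and the number of such assignments is reported.
    """
    exposures = [exposure] if isinstance(exposure, str) else list(exposure)
    level_map = dict(DEFAULT_COVARIATE_LEVELS, **(level_map or {}))
    event_col = _event_column(records, endpoint)
    cols = exposures + [c for c in adjust if c not in exposures]
    work = records[["time_days", event_col] + cols].copy()
    for exp in exposures:
        if work[exp].isna().any():
            raise ValidationError(f"exposure '{exp}' has missing values")
        if work[exp].nunique(dropna=True) < 2:
            raise FitError(f"exposure '{exp}' is constant; nothing to estimate")
    work, n_imputed = _impute_majority(work, list(adjust))

    design, meta = _design(work, cols, level_map)
    cph = _fit_cox(design, work, event_col)
    summary = cph.summary

    def _hr(log_hr: float) -> float:
        # unstable fits can put a CI bound past the float range; report inf
        with np.errstate(over="ignore"):
            return float(np.exp(log_hr))

    rows = []
    for exp in exposures:
        info = meta.get(exp)
        if info is None:  # numeric exposure: report per-unit HR
            coef = summary.loc[exp]
            rows.append(
                {"variable": exp, "level": "per unit", "n": len(work),
                 "events": int(work[event_col].sum()),
                 "hr": _hr(coef["coef"]),
                 "ci_low": _hr(coef["coef lower 95%"]),
                 "ci_high": _hr(coef["coef upper 95%"])}
            )
            continue
        for lv in info["levels"]:
            sub = work[work[exp] == lv]
            name = info["columns"][lv]
            if name is None:
                hr = ci_low = ci_high = 1.0
            else:
                coef = summary.loc[name]
                hr = _hr(coef["coef"])
                ci_low = _hr(coef["coef lower 95%"])
                ci_high = _hr(coef["coef upper 95%"])
            rows.append(
                {"variable": exp, "level": lv, "n": len(sub),
                 "events": int(sub[event_col].sum()),
                 "hr": hr, "ci_low": ci_low, "ci_high": ci_high}
            )
    table = pd.DataFrame(rows)

    # trend model: all categorical exposures as 0..k continuous codes
    trend_design, _ = _design(work, cols, level_map, ordinal=tuple(
        e for e in exposures if e in meta
    ))
    trend_fit = _fit_cox(trend_design, work, event_col)
    p_trend, trend_coef, trend_se = {}, {}, {}
    for exp in exposures:
        name = f"{exp}__trend" if exp in meta else exp
        row = trend_fit.summary.loc[name]
        p_trend[exp] = float(row["p"])
        trend_coef[exp] = float(row["coef"])
        trend_se[exp] = float(row["se(coef)"])

    return SurvivalResult(
        table=table, p_trend=p_trend, trend_coef=trend_coef, trend_se=trend_se,
        endpoint=endpoint.upper(), covariates=tuple(adjust), n_imputed=n_imputed,
    )


def subgroup_and_interaction(
    records: pd.DataFrame,
    exposure: str,
    stratifier: str,
    *,
    adjust: Sequence[str] = (),
    endpoint: str = "CSS",
    level_map: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, SurvivalResult], float]:
    """Exposure effect per stratum plus an interaction p-value.

    Fits the exposure model separately within each stratifier level (strata
    without events are skipped with a warning), then a joint model with
    ordinal codes for both variables and their product term; the Wald
    p-value of the product term is the interaction test.
    """
    full_map = dict(DEFAULT_COVARIATE_LEVELS, **(level_map or {}))
    event_col = _event_column(records, endpoint)
    strata = _levels_of(records, stratifier, full_map)
    if len(strata) < 2:
        raise ValidationError(f"stratifier '{stratifier}' has fewer than 2 levels")
    per_stratum: dict[str, SurvivalResult] = {}
    adj = [c for c in adjust if c != stratifier]
    for lv in strata:
        sub = records[records[stratifier] == lv]
        if sub.empty or int(sub[event_col].sum()) == 0:
            warnings.warn(f"stratum {stratifier}={lv!r} has no events; skipped")
            continue
        per_stratum[str(lv)] = ph_fit(
            sub, exposure, adjust=adj, endpoint=endpoint, level_map=level_map
        )

    work = records[["time_days", event_col, exposure, stratifier] + list(adj)].copy()
    work, _ = _impute_majority(work, list(adj) + [stratifier])
    design, meta = _design(
        work, [exposure, stratifier] + list(adj), full_map,
        ordinal=(exposure, stratifier),
    )
    design[f"{exposure}x{stratifier}"] = (
        design[f"{exposure}__trend"] * design[f"{stratifier}__trend"]
    )
    fit = _fit_cox(design, work, event_col)
    p_interaction = float(fit.summary.loc[f"{exposure}x{stratifier}", "p"])
    return per_stratum, p_interaction


def result_to_frame(result: SurvivalResult) -> pd.DataFrame:
    """Tidy export of a fitted model (one row per exposure level)."""
    out = result.table.copy()
    out["endpoint"] = result.endpoint
    out["p_trend"] = out["variable"].map(result.p_trend)
    out["adjusted_for"] = ",".join(result.covariates)
    return out
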