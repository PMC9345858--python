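"""Percentile-based T cell proximity and density scores.

Each patient contributes four component values — one per marker/region
combination (CD3/CD8 × tumour centre/invasive margin) — either a cell
density (cells/mm²) or the G-cross value at a chosen radius (default
20 µm).  Component values are converted to cohort percentiles, the four
percentiles are averaged into a 0–100 score, and the score is categorised
low (0–25], intermediate (25–70] or high (70–100].  Scoring an external
cohort against a stored reference distribution reproduces the
validation-cohort workflow.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_io import CellClass, CoreSample, Marker, Region, REQUIRED_COMPONENTS
from .exceptions import ConfigError, ConsistencyError, ParameterError, ValidationError
from .spatial_stats import Correction, evaluate_g_at, gcross, gcross_from_distances, \
    compute_density, nn_cross_distances


class Measure(str, Enum):
    DENSITY = "DENSITY"  # cells/mm²
    G_AT_R = "G_AT_R"    # G-cross value at a fixed radius, dimensionless


class Category(str, Enum):
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


def component_key(marker: Marker, region: Region) -> str:
    return f"{Marker(marker).value}_{Region(region).value}"


COMPONENT_KEYS = [component_key(m, r) for m, r in REQUIRED_COMPONENTS]


@dataclass(frozen=True)
class ScoreConfig:
    """Radius and category thresholds of the scoring scheme."""

    radius: float = 20.0            # µm, G evaluation radius
    low_max: float = 25.0           # score in [0, low_max] -> LOW
    intermediate_max: float = 70.0  # (low_max, intermediate_max] -> INTERMEDIATE
    percentile_method: str = "le_fraction"  # 100 * #{ref <= value} / N

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.intermediate_max < 100):
            raise ConfigError(
                f"thresholds must satisfy 0 < low < intermediate < 100, "
                f"got ({self.low_max}, {self.intermediate_max})"
            )


SENSITIVITY_RADII: tuple[float, ...] = (10.0, 30.0, 40.0, 50.0, 100.0, 500.0)


@dataclass
class ComponentMatrix:
    """Per-patient values of the four scoring components.

    ``values`` is indexed by patient_id with columns CD3_CT, CD3_IM,
    CD8_CT, CD8_IM.
    """

    values: pd.DataFrame
    measure: Measure
    radius: float | None = None  # µm, set for G_AT_R

    def __post_init__(self) -> None:
        self.measure = Measure(self.measure)
        missing = [k for k in COMPONENT_KEYS if k not in self.values.columns]
        if missing:
            raise ConsistencyError(f"component matrix lacks columns {missing}")
        vals = self.values[COMPONENT_KEYS]
        if vals.isna().any().any():
            bad = sorted(vals.index[vals.isna().any(axis=1)].astype(str))
            raise ConsistencyError(f"missing component values for patients {bad}")
        if self.measure is Measure.G_AT_R:
            arr = vals.to_numpy(dtype=float)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValidationError("G values must lie in [0, 1]")
        elif (vals.to_numpy(dtype=float) < 0).any():
            raise ValidationError("densities must be non-negative")


def core_measures(
    cores: Iterable[CoreSample],
    measure: Measure | str,
    *,
    radius: float = 20.0,
    correction: Correction | str = Correction.KM,
    pool_cores: bool = False,
) -> pd.DataFrame:
    """Per-core (or per-pooled-group) measurement table.

    Returns a tidy frame with columns ``patient_id, marker, region, core_id,
    value`` (and ``beyond_range`` for G evaluations past the reliable radius).
    With ``pool_cores=True`` the censored nearest-neighbour distances of all
    same-(patient, marker, region) cores are pooled into one product-limit
    estimate instead of estimating G per core.
    """
    measure = Measure(measure)
    rows: list[dict] = []
    if measure is Measure.DENSITY or not pool_cores:
        for core in cores:
            if measure is Measure.DENSITY:
                value, beyond = compute_density(core, CellClass.T_CELL), False
            else:
                curve = gcross(core, correction)
                value, beyond = evaluate_g_at(curve, radius, return_flag=True)
            rows.append(
                {
                    "patient_id": core.patient_id,
                    "marker": core.marker.value,
                    "region": core.region.value,
                    "core_id": core.core_id,
                    "value": value,
                    "beyond_range": beyond,
                }
            )
        return pd.DataFrame(rows)
    groups: dict[tuple, list[CoreSample]] = {}
    for core in cores:
        groups.setdefault((core.patient_id, core.marker.value, core.region.value), []).append(core)
    for (pid, marker, region), members in sorted(groups.items()):
        nnd = None
        n_tcell = 0
        for core in members:
            part = nn_cross_distances(core)
            nnd = part if nnd is None else nnd.concat(part)
            n_tcell += core.count(CellClass.T_CELL)
        curve = gcross_from_distances(
            nnd, correction, core_id=f"{pid}:{marker}:{region}:pooled", n_tcell=n_tcell
        )
        value, beyond = evaluate_g_at(curve, radius, return_flag=True)
        rows.append(
            {
                "patient_id": pid,
                "marker": marker,
                "region": region,
                "core_id": curve.core_id,
                "value": value,
                "beyond_range": beyond,
            }
        )
    return pd.DataFrame(rows)


def aggregate_components(
    core_values: pd.DataFrame,
    measure: Measure | str,
    radius: float | None = None,
) -> ComponentMatrix:
    """Average per-core values into the per-patient component matrix.

    A patient with several analysable cores of the same marker and region
    contributes the arithmetic mean of the per-core values (the same rule is
    applied to G values as to densities).
    """
    measure = Measure(measure)
    if core_values.empty:
        raise ConsistencyError("no core measurements to aggregate")
    df = core_values.copy()
    df["component"] = df["marker"].astype(str) + "_" + df["region"].astype(str)
    wide = df.pivot_table(index="patient_id", columns="component", values="value", aggfunc="mean")
    missing = [k for k in COMPONENT_KEYS if k not in wide.columns]
    if missing or wide[COMPONENT_KEYS].isna().any().any():
        raise ConsistencyError(
            "component(s) missing after QC; run qc_filter_cohort before aggregation"
        )
    wide = wide[COMPONENT_KEYS].sort_index()
    wide.index = wide.index.astype(str)
    return ComponentMatrix(values=wide, measure=measure, radius=radius)


@dataclass
class PercentileReference:
    """Reference distributions (one sorted array per component) for scoring.

    Built from the study cohort; an external cohort scored against this
    reference receives percentiles on the study-cohort scale.
    """

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for key in COMPONENT_KEYS:
            if key not in self.values:
                raise ConsistencyError(f"reference lacks component {key}")
            arr = np.sort(np.asarray(self.values[key], dtype=float))
            if arr.size < 2:
                raise ValidationError(f"reference for {key} needs at least 2 values")
            if not np.isfinite(arr).all():
                raise ValidationError(f"reference for {key} contains non-finite values")
            self.values[key] = arr

    @classmethod
    def from_components(cls, components: ComponentMatrix) -> "PercentileReference":
        return cls({k: components.values[k].to_numpy(dtype=float) for k in COMPONENT_KEYS})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.values[k] for k in COMPONENT_KEYS})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PercentileReference":
        df = pd.read_csv(path)
        return cls({k: df[k].to_numpy(dtype=float) for k in COMPONENT_KEYS})


def percentile_transform(value: float, reference: np.ndarray) -> float:
    """Percentile (0–100) of ``value`` within a sorted reference distribution.

    Defined as ``100 * #{u in reference : u <= value} / N``; values below
    the reference minimum map to 0 and above the maximum to 100.
    """
    if not np.isfinite(value):
        raise ValidationError(f"cannot take the percentile of non-finite value {value}")
    ref = np.asarray(reference, dtype=float)
    return 100.0 * float(np.searchsorted(ref, value, side="right")) / ref.size


def composite_score(percentiles: Sequence[float]) -> float:
    """Mean of the four component percentiles."""
    arr = np.asarray(percentiles, dtype=float)
    if arr.shape != (4,):
        raise ValidationError(f"expected exactly 4 percentiles, got shape {arr.shape}")
    if not np.isfinite(arr).all() or arr.min() < 0 or arr.max() > 100:
        raise ValidationError("percentiles must be finite and within [0, 100]")
    return float(arr.mean())


def categorize_score(score: float, config: ScoreConfig = ScoreConfig()) -> Category:
    """Category bands: [0, 25] low, (25, 70] intermediate, (70, 100] high."""
    if not np.isfinite(score) or score < 0 or score > 100:
        raise ValidationError(f"score must lie in [0, 100], got {score}")
    if score <= config.low_max:
        return Category.LOW
    if score <= config.intermediate_max:
        return Category.INTERMEDIATE
    return Category.HIGH


def quartile_categories(values: Sequence[float]) -> list[str]:
    """Ordinal quartile labels Q1 (lowest) … Q4 (highest) across a cohort.

    Cuts sit at the 25th/50th/75th empirical ranks with ties assigned to the
    lower quartile; quartile sizes follow a largest-remainder rule that gives
    any extra cases to the lower quartiles (983 values split 246/246/246/245).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValidationError(f"quartiles need at least 4 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValidationError("quartile input contains non-finite values")
    srt = np.sort(arr)
    n = arr.size
    cuts = [srt[int(np.ceil(n * k / 4)) - 1] for k in (1, 2, 3)]
    if cuts[0] == cuts[2] and srt[0] == srt[-1]:
        warnings.warn("degenerate component distribution: all values tied, assigning Q1")
    labels = np.full(n, 1, dtype=int)
    for c in cuts:
        labels += (arr > c).astype(int)
    return [f"Q{k}" for k in labels]


DEFAULT_SUBGROUP_SCHEME = "dichotomised"


def cross_classify(
    proximity_category: Category,
    density_category: Category,
    scheme: str = DEFAULT_SUBGROUP_SCHEME,
) -> str:
    """Combined proximity × density subgroup label.

    The default scheme dichotomises each score at LOW vs {INTERMEDIATE,
    HIGH}, yielding four subgroups 'prox±/dens±'.  The 'full' scheme keeps
    all nine category pairs.
    """
    p = Category(proximity_category)
    d = Category(density_category)
    if scheme == "dichotomised":
        ptag = "prox+" if p is not Category.LOW else "prox-"
        dtag = "dens+" if d is not Category.LOW else "dens-"
        return f"{ptag}/{dtag}"
    if scheme == "full":
        return f"prox:{p.value}/dens:{d.value}"
    raise ConfigError(f"unknown subgroup scheme {scheme!r}")


def score_patients(
    g_components: ComponentMatrix,
    density_components: ComponentMatrix,
    *,
    g_reference: PercentileReference | None = None,
    density_reference: PercentileReference | None = None,
    config: ScoreConfig = ScoreConfig(),
    subgroup_scheme: str = DEFAULT_SUBGROUP_SCHEME,
) -> pd.DataFrame:
    """Full per-patient score table.

    Percentiles are taken against the cohort itself unless an external
    reference is supplied (validation-cohort mode).  Returns a frame indexed
    by patient_id with component values and percentiles, the proximity and
    density scores, categories, per-component quartiles and the combined
    subgroup label.
    """
    if not g_components.values.index.equals(density_components.values.index):
        raise ConsistencyError("proximity and density matrices cover different patients")
    g_ref = g_reference or PercentileReference.from_components(g_components)
    d_ref = density_reference or PercentileReference.from_components(density_components)

    out = pd.DataFrame(index=g_components.values.index.copy())
    for prefix, comp, ref in (
        ("gcross", g_components, g_ref),
        ("density", density_components, d_ref),
    ):
        pct_cols = []
        for key in COMPONENT_KEYS:
            vals = comp.values[key].to_numpy(dtype=float)
            out[f"{prefix}_{key}"] = vals
            pct = np.array([percentile_transform(v, ref.values[key]) for v in vals])
            out[f"{prefix}_{key}_pct"] = pct
            pct_cols.append(f"{prefix}_{key}_pct")
            out[f"{prefix}_{key}_quartile"] = quartile_categories(vals) if len(vals) >= 4 else "Q1"
        score_name = "proximity_score" if prefix == "gcross" else "density_score"
        out[score_name] = out[pct_cols].mean(axis=1)
    out["proximity_category"] = [
        categorize_score(s, config).value for s in out["proximity_score"]
    ]
    out["density_category"] = [
        categorize_score(s, config).value for s in out["density_score"]
    ]
    out["combined_subgroup"] = [
        cross_classify(Category(p), Category(d), subgroup_scheme)
        for p, d in zip(out["proximity_category"], out["density_category"])
    ]
    return out
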