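"""End-to-end orchestration: read → QC → measure → score → survival → report.

The pipeline consumes a fixture-bundle directory (cores + manifest +
clinical table, as written by :mod:`tcellprox.synthetic_data` or assembled
from real exports), runs every stage with a fully serialised configuration,
and writes CSV artefacts plus a structured log into the output directory.
Identical config and inputs yield byte-identical score tables.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cell_io, scoring, spatial_stats, survival
from .exceptions import ConfigError, TCellProxError
from .synthetic_data import read_fixture_bundle

log = logging.getLogger("tcellprox")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML-serialisable)."""

    input_dir: str = "."
    output_dir: str = "tcellprox_run"
    dialect: str = "GENERIC_CSV"
    window_method: str = "FIXED_DISC"       # used when the manifest has no window
    window_diameter_um: float = 1000.0
    min_tumour_cells: int = 20
    correction: str = "KM"
    radius_um: float = 20.0
    sensitivity_radii_um: tuple[float, ...] = ()
    pool_cores: bool = False
    percentile_reference: str | None = None  # CSV path for external-reference scoring
    low_max: float = 25.0
    intermediate_max: float = 70.0
    subgroup_scheme: str = "dichotomised"
    endpoints: tuple[str, ...] = ("CSS", "OS")
    covariates: tuple[str, ...] = tuple(survival.DEFAULT_COVARIATE_LEVELS)
    horizon_years: float = 10.0
    write_gcurves: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("sensitivity_radii_um", "endpoints", "covariates"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        for key in ("sensitivity_radii_um", "endpoints", "covariates"):
            data[key] = list(data[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def load_and_qc(config: PipelineConfig) -> tuple[cell_io.CohortData, pd.DataFrame]:
    """Stage 1: read the bundle, attach windows, QC-filter the cohort."""
    cohort = read_fixture_bundle(config.input_dir)
    log.info("read %d cores, %d clinical records from %s",
             len(cohort.cores), len(cohort.clinical), config.input_dir)
    for core in cohort.cores:
        if core.window is None:
            core.window = cell_io.build_window(
                core, config.window_method, diameter=config.window_diameter_um
            )
    orphans = cohort.orphan_cores()
    if orphans:
        log.warning("%d cores lack a clinical record: %s", len(orphans), orphans[:5])
    filtered, report = cell_io.qc_filter_cohort(cohort, config.min_tumour_cells)
    log.info("QC: retained %d cores (%d patients), excluded %d cores",
             len(filtered.cores), len(filtered.patients()), len(report))
    return filtered, report


def compute_scores(
    config: PipelineConfig, cohort: cell_io.CohortData
) -> tuple[pd.DataFrame, dict]:
    """Stage 2: measure, aggregate and score; returns (score table, extras)."""
    g_ref = d_ref = None
    if config.percentile_reference:
        ref_dir = Path(config.percentile_reference)
        g_ref = scoring.PercentileReference.load(ref_dir / "reference_gcross.csv")
        d_ref = scoring.PercentileReference.load(ref_dir / "reference_density.csv")
        log.info("external percentile reference loaded from %s", ref_dir)

    g_values = scoring.core_measures(
        cohort.cores, scoring.Measure.G_AT_R, radius=config.radius_um,
        correction=config.correction, pool_cores=config.pool_cores,
    )
    n_beyond = int(g_values["beyond_range"].sum())
    if n_beyond:
        log.warning("%d G evaluations beyond the reliable radius range", n_beyond)
    d_values = scoring.core_measures(cohort.cores, scoring.Measure.DENSITY)
    g_comp = scoring.aggregate_components(g_values, scoring.Measure.G_AT_R, config.radius_um)
    d_comp = scoring.aggregate_components(d_values, scoring.Measure.DENSITY)
    cfg = scoring.ScoreConfig(
        radius=config.radius_um, low_max=config.low_max,
        intermediate_max=config.intermediate_max,
    )
    scores = scoring.score_patients(
        g_comp, d_comp, g_reference=g_ref, density_reference=d_ref,
        config=cfg, subgroup_scheme=config.subgroup_scheme,
    )
    # sensitivity analysis: one proximity-score column per extra radius
    for r in config.sensitivity_radii_um:
        gv = scoring.core_measures(
            cohort.cores, scoring.Measure.G_AT_R, radius=r,
            correction=config.correction, pool_cores=config.pool_cores,
        )
        gc = scoring.aggregate_components(gv, scoring.Measure.G_AT_R, r)
        ref = g_ref if g_ref is not None else scoring.PercentileReference.from_components(gc)
        pct = pd.DataFrame(
            {
                key: [scoring.percentile_transform(v, ref.values[key]) for v in gc.values[key]]
                for key in scoring.COMPONENT_KEYS
            },
            index=gc.values.index,
        )
        scores[f"proximity_score_r{r:g}"] = pct.mean(axis=1)
        log.info("sensitivity radius %g µm scored", r)
    extras = {
        "g_components": g_comp, "density_components": d_comp,
        "g_reference": g_ref or scoring.PercentileReference.from_components(g_comp),
        "density_reference": d_ref or scoring.PercentileReference.from_components(d_comp),
        "n_beyond_range": n_beyond,
    }
    log.info("scored %d patients", len(scores))
    return scores.sort_index(), extras


def run_survival(
    config: PipelineConfig, scores: pd.DataFrame, clinical: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Stage 3: KM/log-rank and adjusted hazard models per endpoint."""
    merged = clinical.merge(
        scores[["proximity_category", "density_category", "proximity_score", "density_score"]],
        left_on="patient_id", right_index=True, how="inner",
    )
    merged = survival.truncate_followup(merged, config.horizon_years)
    cat_levels = {
        "proximity_category": ("LOW", "INTERMEDIATE", "HIGH"),
        "density_category": ("LOW", "INTERMEDIATE", "HIGH"),
    }
    covariates = [c for c in config.covariates if c in merged.columns]
    results: dict[str, pd.DataFrame] = {}
    km_frames = []
    for endpoint in config.endpoints:
        frames = []
        for exposure in ("proximity_category", "density_category"):
            if merged[exposure].nunique() < 2:
                log.warning("%s has a single level; survival models skipped", exposure)
                continue
            try:
                uni = survival.ph_fit(
                    merged, exposure, endpoint=endpoint, level_map=cat_levels
                )
                adj = survival.ph_fit(
                    merged, exposure, adjust=covariates, endpoint=endpoint,
                    level_map=cat_levels,
                )
            except (survival.FitError, ValueError) as exc:
                # degenerate small cohorts (empty levels, separation) stay non-fatal
                log.warning("%s/%s model skipped: %s", endpoint, exposure, exc)
                continue
            if adj.n_imputed:
                log.info("majority-category imputations for %s/%s: %s",
                         endpoint, exposure, adj.n_imputed)
            for model, res in (("univariable", uni), ("multivariable", adj)):
                frame = survival.result_to_frame(res)
                frame.insert(0, "model", model)
                frames.append(frame)
            km = survival.km_logrank(merged, exposure, endpoint=endpoint)
            kmc = km.curves.copy()
            kmc.insert(0, "exposure", exposure)
            kmc.insert(0, "endpoint", endpoint)
            kmc["logrank_stat"] = km.statistic
            kmc["logrank_p"] = km.p_value
            km_frames.append(kmc)
        if frames:
            results[endpoint] = pd.concat(frames, ignore_index=True)
            log.info("survival models fitted for %s", endpoint)
    if km_frames:
        results["km_curves"] = pd.concat(km_frames, ignore_index=True)
    return results


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages and write the artefact set; returns artefact paths."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    artefacts: dict[str, Path] = {}
    try:
        config.to_yaml(out_dir / "resolved_config.yaml")
        artefacts["config"] = out_dir / "resolved_config.yaml"

        cohort, exclusions = load_and_qc(config)
        exclusions.to_csv(out_dir / "exclusions.csv", index=False)
        artefacts["exclusions"] = out_dir / "exclusions.csv"

        scores, extras = compute_scores(config, cohort)
        scores.round(10).to_csv(out_dir / "patient_scores.csv", index_label="patient_id")
        artefacts["patient_scores"] = out_dir / "patient_scores.csv"
        extras["g_reference"].save(out_dir / "reference_gcross.csv")
        extras["density_reference"].save(out_dir / "reference_density.csv")
        artefacts["reference_gcross"] = out_dir / "reference_gcross.csv"
        artefacts["reference_density"] = out_dir / "reference_density.csv"

        if config.write_gcurves:
            curves = [
                spatial_stats.gcross(core, config.correction) for core in cohort.cores
            ]
            spatial_stats.gcurves_to_frame(curves).to_csv(
                out_dir / "gcurves.csv", index=False
            )
            artefacts["gcurves"] = out_dir / "gcurves.csv"

        if not cohort.clinical.empty:
            surv = run_survival(config, scores, cohort.clinical)
            for name, frame in surv.items():
                path = out_dir / (
                    "km_curves.csv" if name == "km_curves" else f"survival_{name.lower()}.csv"
                )
                frame.to_csv(path, index=False)
                artefacts[f"survival_{name}"] = path
        else:
            log.warning("no clinical table; survival stage skipped")
        log.info("pipeline complete: %d artefacts in %s", len(artefacts), out_dir)
        return artefacts
    except TCellProxError:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def report_summary(scores: pd.DataFrame) -> str:
    """Human-readable summary: category counts and proximity × density cross-tab."""
    lines = [f"Patients scored: {len(scores)}", ""]
    for col in ("proximity_category", "density_category"):
        counts = scores[col].value_counts().reindex(
            ["LOW", "INTERMEDIATE", "HIGH"], fill_value=0
        )
        frac = 100 * counts / max(len(scores), 1)
        lines.append(col.replace("_", " ") + ":")
        for level in counts.index:
            lines.append(f"  {level:<12} {counts[level]:>6} ({frac[level]:5.1f}%)")
        lines.append("")
    tab = pd.crosstab(
        scores["proximity_category"], scores["density_category"], margins=True
    ).reindex(index=["LOW", "INTERMEDIATE", "HIGH", "All"],
              columns=["LOW", "INTERMEDIATE", "HIGH", "All"], fill_value=0)
    lines.append("proximity (rows) x density (columns):")
    lines.append(tab.to_string())
    lines.append("")
    lines.append("combined subgroups:")
    for label, n in scores["combined_subgroup"].value_counts().sort_index().items():
        lines.append(f"  {label:<14} {n:>6}")
    return "\n".join(lines)
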