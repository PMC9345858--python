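"""Synthetic TMA cohorts with known co-localisation ground truth.

Real single-cell cohorts of this kind are rarely shareable, so every
pipeline stage is exercised against generated data whose answer is known.
A core is a disc (default 1 mm diameter) containing

* tumour cells from a Thomas cluster process (Poisson parents with
  isotropic Gaussian offspring), emulating tumour-cell nests, and
* T cells of which a fraction ``rho`` is attached to randomly chosen
  tumour cells at a half-normal radial offset (co-localised component)
  while the remainder is uniform background.

``rho = 0`` makes the T cells a homogeneous Poisson process independent of
the tumour cells, for which the nearest-neighbour distance function has the
closed form G(r) = 1 − exp(−λπr²) — the analytic oracle used throughout the
tests.  A cohort draws one ``rho`` per patient, builds cores for all four
scoring components (CD3/CD8 × CT/IM), and links survival to the true
co-localisation level through an exponential hazard.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_io import (
    CellClass,
    CohortData,
    CoreSample,
    Dialect,
    Marker,
    Region,
    Window,
    read_cell_table,
    read_clinical_table,
    write_cell_table,
)
from .exceptions import ConfigError, ParameterError

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class SyntheticCoreParams:
    """Generative parameters of one synthetic core.

    Intensities are per mm²; lengths are µm.  ``n_tumour`` overrides the
    Thomas process with a fixed number of uniformly placed tumour cells
    (convenient for analytic null checks).
    """

    radius: float = 500.0        # disc radius, µm (1-mm TMA core)
    kappa: float = 50.0          # tumour parent intensity, per mm²
    sigma: float = 30.0          # cluster spread (Gaussian sd), µm
    mu: float = 12.0             # mean offspring per parent
    lambda_t: float = 500.0      # total T cell intensity, per mm²
    rho: float = 0.0             # fraction of T cells attached to tumour cells
    sigma_a: float = 10.0        # half-normal attachment offset, µm
    lambda_other: float = 0.0    # uniform "other cell" noise, per mm²
    n_tumour: int | None = None  # fixed uniform tumour count (overrides Thomas)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho}")
        if min(self.kappa, self.lambda_t, self.lambda_other) < 0:
            raise ParameterError("intensities must be non-negative")
        if self.sigma <= 0 or self.sigma_a <= 0:
            raise ParameterError("sigma and sigma_a must be positive")
        if self.radius <= 0:
            raise ParameterError("window radius must be positive")


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Cohort-level design: patients, cores, markers and linked survival.

    ``rho_groups``/``rho_weights`` define a mixture of co-localisation
    levels across patients (the default three groups mirror the low /
    intermediate / high category prevalences implied by the 25/70 score
    thresholds).  The log hazard increases by ``beta`` per unit of the true
    exposure — the group index when ``beta_scale='category'``, or ``rho``
    itself when ``beta_scale='rho'``.
    """

    n_patients: int = 50
    rho_groups: tuple[float, ...] = (0.1, 0.5, 0.9)
    rho_weights: tuple[float, ...] = (0.25, 0.45, 0.30)
    rho_uniform: tuple[float, float] | None = None  # overrides the mixture
    balanced_groups: bool = False     # deterministic equal-size group assignment
    cores_per_component: int = 2      # two 1 mm cores per region per marker
    core: SyntheticCoreParams = SyntheticCoreParams()
    cd8_lambda_ratio: float = 0.5     # CD8 T cell intensity relative to CD3
    im_lambda_ratio: float = 1.5      # invasive margin densities run higher
    beta: float = 0.0                 # log-HR per unit of true exposure
    beta_scale: str = "category"      # 'category' (group index) or 'rho'
    h0: float = 0.05                  # baseline cancer-death hazard, per year
    other_cause_rate: float = 0.04    # non-cancer death hazard, per year
    censoring_rate: float = 0.03      # random loss to follow-up, per year
    follow_up_years: float = 15.0     # administrative end of follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.rho_uniform is None:
            if len(self.rho_groups) != len(self.rho_weights):
                raise ConfigError("rho_groups and rho_weights must align")
            if abs(sum(self.rho_weights) - 1.0) > 1e-9:
                raise ConfigError("rho_weights must sum to 1")
        if self.beta_scale not in ("category", "rho"):
            raise ConfigError(f"unknown beta_scale {self.beta_scale!r}")
        if min(self.h0, self.other_cause_rate, self.censoring_rate) < 0:
            raise ConfigError("hazard rates must be non-negative")


def theoretical_g_poisson(lam: float, r: float) -> float:
    """Closed-form G(r) = 1 − exp(−λπr²) for Poisson T cells (λ per µm²)."""
    if lam < 0 or r < 0:
        raise ParameterError("intensity and radius must be non-negative")
    return 1.0 - math.exp(-lam * math.pi * r * r)


def _uniform_in_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_core(
    params: SyntheticCoreParams,
    *,
    core_id: str = "synthetic",
    patient_id: str = "P0",
    region: Region = Region.CT,
    marker: Marker = Marker.CD3,
) -> CoreSample:
    """Generate one synthetic core; bit-identical for identical params+seed."""
    rng = np.random.default_rng(params.seed)
    R = params.radius
    area_mm2 = math.pi * R * R / UM2_PER_MM2
    window = Window.disc(0.0, 0.0, R)

    # --- tumour cells ---------------------------------------------------
    if params.n_tumour is not None:
        tumour = _uniform_in_disc(rng, int(params.n_tumour), R)
    else:
        # parents on a dilated disc so clusters near the edge are not lost
        R_ext = R + 4.0 * params.sigma
        area_ext_mm2 = math.pi * R_ext * R_ext / UM2_PER_MM2
        n_parents = rng.poisson(params.kappa * area_ext_mm2)
        parents = _uniform_in_disc(rng, n_parents, R_ext)
        counts = rng.poisson(params.mu, size=n_parents)
        centres = np.repeat(parents, counts, axis=0)
        offspring = centres + rng.normal(0.0, params.sigma, size=centres.shape)
        inside = np.hypot(offspring[:, 0], offspring[:, 1]) <= R
        tumour = offspring[inside]
        if tumour.shape[0] == 0:
            warnings.warn(f"core {core_id}: empty tumour pattern (window too small?)")

    # --- T cells ---------------------------------------------------------
    n_t = rng.poisson(params.lambda_t * area_mm2)
    attached_mask = rng.random(n_t) < params.rho if tumour.shape[0] else np.zeros(n_t, bool)
    n_att = int(attached_mask.sum())
    tcells = np.empty((n_t, 2), dtype=float)
    tcells[~attached_mask] = _uniform_in_disc(rng, n_t - n_att, R)
    if n_att:
        pts = np.empty((n_att, 2), dtype=float)
        todo = np.arange(n_att)
        while todo.size:
            anchors = tumour[rng.integers(0, tumour.shape[0], size=todo.size)]
            offset_r = np.abs(rng.normal(0.0, params.sigma_a, size=todo.size))
            angle = 2.0 * np.pi * rng.random(todo.size)
            cand = anchors + np.column_stack(
                [offset_r * np.cos(angle), offset_r * np.sin(angle)]
            )
            ok = np.hypot(cand[:, 0], cand[:, 1]) <= R
            pts[todo[ok]] = cand[ok]
            todo = todo[~ok]  # resample attached cells that fell outside
        tcells[attached_mask] = pts

    # --- other cells ------------------------------------------------------
    n_other = rng.poisson(params.lambda_other * area_mm2)
    other = _uniform_in_disc(rng, n_other, R)

    cells = pd.DataFrame(
        {
            "x": np.concatenate([tumour[:, 0], tcells[:, 0], other[:, 0]]),
            "y": np.concatenate([tumour[:, 1], tcells[:, 1], other[:, 1]]),
            "cell_class": (
                [CellClass.TUMOUR] * tumour.shape[0]
                + [CellClass.T_CELL] * n_t
                + [CellClass.OTHER] * n_other
            ),
        }
    )
    return CoreSample(
        core_id=core_id, patient_id=patient_id, region=region, marker=marker,
        cells=cells, window=window,
    )


def _core_seed(master: int, counter: int) -> int:
    """Deterministic per-core seed stream derived from the master seed."""
    return int(np.random.SeedSequence([int(master), int(counter)]).generate_state(1)[0] % 2**31)


def _draw_rho(rng: np.random.Generator, params: SyntheticCohortParams) -> tuple[float, int]:
    if params.rho_uniform is not None:
        lo, hi = params.rho_uniform
        rho = float(rng.uniform(lo, hi))
        return rho, int(np.digitize(rho, [lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3]))
    g = int(rng.choice(len(params.rho_groups), p=params.rho_weights))
    return float(params.rho_groups[g]), g


_COVARIATE_FREQS = {
    "sex": (("male", "female"), (0.51, 0.49)),
    "age_group": (("<65", "65-75", ">75"), (0.27, 0.35, 0.38)),
    "year_of_operation": (("2000-2005", "2006-2010", "2011-2015"), (0.30, 0.32, 0.38)),
    "tumour_location": (("proximal colon", "distal colon", "rectum"), (0.49, 0.36, 0.15)),
    "stage": (("I-II", "III", "IV"), (0.54, 0.33, 0.13)),
    "grade": (("low", "high"), (0.83, 0.17)),
    "lymphovascular_invasion": (("no", "yes"), (0.79, 0.21)),
    "mmr": (("proficient", "deficient"), (0.85, 0.15)),
    "braf": (("wild-type", "mutant"), (0.84, 0.16)),
}


def simulate_cohort(params: SyntheticCohortParams) -> CohortData:
    """Generate a full cohort: cores for all four components plus outcomes.

    The true per-patient co-localisation level (and its mixture-group index)
    is recorded in ``provenance['truth']`` for recovery tests.  Survival
    times are exponential with hazard ``h0 * exp(beta * x)``; cancer death
    competes with an independent other-cause death process, and independent
    censoring plus an administrative horizon close follow-up.
    """
    rng = np.random.default_rng(params.seed)
    cores: list[CoreSample] = []
    clinical_rows: list[dict] = []
    truth_rows: list[dict] = []
    counter = 0
    for i in range(params.n_patients):
        pid = f"P{i:04d}"
        if params.balanced_groups and params.rho_uniform is None:
            group = i % len(params.rho_groups)
            rho = float(params.rho_groups[group])
        else:
            rho, group = _draw_rho(rng, params)
        for marker in (Marker.CD3, Marker.CD8):
            lam_marker = params.core.lambda_t * (
                params.cd8_lambda_ratio if marker is Marker.CD8 else 1.0
            )
            for region in (Region.CT, Region.IM):
                lam = lam_marker * (params.im_lambda_ratio if region is Region.IM else 1.0)
                for j in range(params.cores_per_component):
                    counter += 1
                    cp = replace(
                        params.core, lambda_t=lam, rho=rho,
                        seed=_core_seed(params.seed, counter),
                    )
                    cores.append(
                        simulate_core(
                            cp,
                            core_id=f"{pid}_{marker.value}_{region.value}_{j + 1}",
                            patient_id=pid, region=region, marker=marker,
                        )
                    )
        x = float(group) if params.beta_scale == "category" else rho
        rate_cancer = params.h0 * math.exp(params.beta * x)
        t_cancer = rng.exponential(1.0 / rate_cancer) if rate_cancer > 0 else math.inf
        t_other = (
            rng.exponential(1.0 / params.other_cause_rate)
            if params.other_cause_rate > 0 else math.inf
        )
        t_cens = (
            rng.exponential(1.0 / params.censoring_rate)
            if params.censoring_rate > 0 else math.inf
        )
        t_end = min(t_cens, params.follow_up_years)
        t_death = min(t_cancer, t_other)
        time_y = min(t_death, t_end)
        event_os = int(t_death <= t_end)
        event_css = int(event_os and t_cancer <= t_other)
        row = {
            "patient_id": pid,
            "time_days": time_y * 365.25,
            "event_css": event_css,
            "event_os": event_os,
        }
        for col, (levels, freqs) in _COVARIATE_FREQS.items():
            row[col] = levels[int(rng.choice(len(levels), p=freqs))]
        clinical_rows.append(row)
        truth_rows.append({"patient_id": pid, "rho": rho, "group": group})

    clinical = pd.DataFrame(clinical_rows)
    truth = pd.DataFrame(truth_rows)
    return CohortData(
        cores=cores,
        clinical=clinical,
        provenance={"truth": truth, "params": asdict(params), "generator": "tcellprox.synthetic_data"},
    )


def write_fixture_bundle(cohort: CohortData, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as a self-contained plain-text bundle.

    Layout: ``cores/<core_id>.csv`` (GENERIC_CSV), ``cores.csv`` manifest
    (core metadata + disc window geometry), ``clinical.csv``, ``truth.csv``
    (when ground truth is known) and ``config.json`` (generator snapshot).
    """
    directory = Path(directory)
    (directory / "cores").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for core in cohort.cores:
        rel = Path("cores") / f"{core.core_id}.csv"
        write_cell_table(core, directory / rel)
        win = core.window
        manifest_rows.append(
            {
                "core_id": core.core_id,
                "patient_id": core.patient_id,
                "region": core.region.value,
                "marker": core.marker.value,
                "file": rel.as_posix(),
                "window_cx_um": win.centre[0] if win and win.centre else "",
                "window_cy_um": win.centre[1] if win and win.centre else "",
                "window_radius_um": win.radius if win and win.radius else "",
            }
        )
    paths = {"manifest": directory / "cores.csv", "clinical": directory / "clinical.csv"}
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    cohort.clinical.to_csv(paths["clinical"], index=False)
    truth = cohort.provenance.get("truth")
    if truth is not None:
        paths["truth"] = directory / "truth.csv"
        truth.to_csv(paths["truth"], index=False)
    config = {k: v for k, v in cohort.provenance.items() if k != "truth"}
    paths["config"] = directory / "config.json"
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=2, default=str)
    return paths


def read_fixture_bundle(directory: str | Path) -> CohortData:
    """Re-read a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "cores.csv")
    cores = []
    for row in manifest.itertuples(index=False):
        window = None
        if row.window_radius_um and not pd.isna(row.window_radius_um):
            window = Window.disc(
                float(row.window_cx_um), float(row.window_cy_um), float(row.window_radius_um)
            )
        cores.append(
            read_cell_table(
                directory / row.file,
                Dialect.GENERIC_CSV,
                core_id=str(row.core_id),
                patient_id=str(row.patient_id),
                region=Region(row.region),
                marker=Marker(row.marker),
                window=window,
            )
        )
    clinical_path = directory / "clinical.csv"
    clinical = read_clinical_table(clinical_path) if clinical_path.exists() else pd.DataFrame()
    provenance: dict = {"source": str(directory)}
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        provenance["truth"] = pd.read_csv(truth_path).assign(
            patient_id=lambda d: d["patient_id"].astype(str)
        )
    return CohortData(cores=cores, clinical=clinical, provenance=provenance)
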