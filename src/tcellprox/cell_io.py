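"""Reading, validation and quality filtering of per-core single-cell tables.

The pipeline consumes tables exported by cell-classification software
(one row per detected cell, centroid coordinates in micrometres, a class
label) together with the tissue-microarray core metadata needed downstream:
which patient the core belongs to, whether it samples the tumour centre (CT)
or the invasive margin (IM), and which T cell marker (CD3 or CD8) the section
was stained for.  Three input dialects are supported: a minimal generic CSV,
QuPath-style detection-measurement TSV exports, and GeoJSON point features.

All coordinates are micrometres internally; areas are reported in mm².
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .exceptions import (
    EmptyCohortError,
    EmptyInputError,
    FormatError,
    GeometryError,
    ParameterError,
    ValidationError,
)

UM2_PER_MM2 = 1e6


class CellClass(str, Enum):
    TUMOUR = "TUMOUR"
    T_CELL = "T_CELL"
    OTHER = "OTHER"


class Region(str, Enum):
    CT = "CT"  # tumour centre
    IM = "IM"  # invasive margin


class Marker(str, Enum):
    CD3 = "CD3"
    CD8 = "CD8"


class WindowShape(str, Enum):
    DISC = "DISC"
    POLYGON = "POLYGON"


class Dialect(str, Enum):
    GENERIC_CSV = "GENERIC_CSV"
    QUPATH_TSV = "QUPATH_TSV"
    GEOJSON = "GEOJSON"


class WindowMethod(str, Enum):
    FIXED_DISC = "FIXED_DISC"
    CONVEX_HULL = "CONVEX_HULL"
    BUFFERED_HULL = "BUFFERED_HULL"


#: Built-in class-label map covering common QuPath classifier outputs.
#: Keys are matched case-insensitively after stripping whitespace.
DEFAULT_LABEL_MAP: dict[str, CellClass] = {
    "tumour": CellClass.TUMOUR,
    "tumor": CellClass.TUMOUR,
    "tumour cell": CellClass.TUMOUR,
    "tumor cell": CellClass.TUMOUR,
    "tumour cells": CellClass.TUMOUR,
    "tumor cells": CellClass.TUMOUR,
    "t cell": CellClass.T_CELL,
    "t_cell": CellClass.T_CELL,
    "t cells": CellClass.T_CELL,
    "t-cell": CellClass.T_CELL,
    "tcell": CellClass.T_CELL,
    "t lymphocyte": CellClass.T_CELL,
    "cd3": CellClass.T_CELL,
    "cd3+": CellClass.T_CELL,
    "cd8": CellClass.T_CELL,
    "cd8+": CellClass.T_CELL,
    "other": CellClass.OTHER,
    "other cell": CellClass.OTHER,
    "other cells": CellClass.OTHER,
}

#: Default QuPath detection-measurement column names.
DEFAULT_QUPATH_COLUMNS = {"x": "Centroid X µm", "y": "Centroid Y µm", "class": "Class"}

CELL_COLUMNS = ["x", "y", "cell_class"]


@dataclass(frozen=True)
class Cell:
    """A single classified cell: centroid position (µm) and class."""

    x: float
    y: float
    cell_class: CellClass

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"cell coordinates must be finite, got ({self.x}, {self.y})")
        if not isinstance(self.cell_class, CellClass):
            raise ValidationError(f"invalid cell class {self.cell_class!r}")


@dataclass(frozen=True)
class Window:
    """Observation window of one core: a disc or a simple polygon.

    The window is required by the edge-corrected G estimator, which censors
    each nearest-neighbour distance at the distance from the cell to the
    window boundary.
    """

    shape: WindowShape
    centre: tuple[float, float] | None = None
    radius: float | None = None
    polygon: Polygon | None = None

    @classmethod
    def disc(cls, cx: float, cy: float, radius: float) -> "Window":
        if radius <= 0:
            raise ParameterError(f"disc radius must be positive, got {radius}")
        return cls(shape=WindowShape.DISC, centre=(float(cx), float(cy)), radius=float(radius))

    @classmethod
    def from_polygon(cls, polygon: Polygon) -> "Window":
        if not polygon.is_valid or polygon.is_empty:
            raise GeometryError("polygon window must be a valid, non-empty simple polygon")
        if polygon.area <= 0:
            raise GeometryError("polygon window must have positive area")
        return cls(shape=WindowShape.POLYGON, polygon=polygon)

    @property
    def area_um2(self) -> float:
        if self.shape is WindowShape.DISC:
            return math.pi * self.radius**2
        return self.polygon.area

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / UM2_PER_MM2

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside or on the boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.shape is WindowShape.DISC:
            d = np.hypot(pts[:, 0] - self.centre[0], pts[:, 1] - self.centre[1])
            return d <= self.radius + tol
        geoms = shapely.points(pts)
        return shapely.dwithin(self.polygon, geoms, tol)

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the window boundary, clipped at 0."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.shape is WindowShape.DISC:
            d = np.hypot(pts[:, 0] - self.centre[0], pts[:, 1] - self.centre[1])
            return np.clip(self.radius - d, 0.0, None)
        boundary = self.polygon.exterior
        geoms = shapely.points(pts)
        dist = shapely.distance(boundary, geoms)
        inside = shapely.covers(self.polygon, geoms)
        dist[~inside] = 0.0
        return dist


@dataclass
class CoreSample:
    """One TMA core: classified cells plus window and metadata."""

    core_id: str
    patient_id: str
    region: Region
    marker: Marker
    cells: pd.DataFrame  # columns x (µm), y (µm), cell_class (CellClass values)
    window: Window | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValidationError(f"cell table lacks columns {missing}")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValidationError("cell coordinates must be finite")
        bad = set(self.cells["cell_class"]) - {c for c in CellClass}
        if bad:
            raise ValidationError(f"invalid cell classes: {sorted(map(str, bad))}")
        self.region = Region(self.region)
        self.marker = Marker(self.marker)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords(self, cell_class: CellClass | None = None) -> np.ndarray:
        """(n, 2) array of centroids, optionally restricted to one class."""
        df = self.cells
        if cell_class is not None:
            df = df[df["cell_class"] == cell_class]
        return df[["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)

    def count(self, cell_class: CellClass) -> int:
        return int((self.cells["cell_class"] == cell_class).sum())


@dataclass
class CohortData:
    """All cores of a cohort plus the per-patient clinical table."""

    cores: list[CoreSample]
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    def orphan_cores(self) -> list[str]:
        """Core ids whose patient has no clinical record."""
        if self.clinical.empty or "patient_id" not in self.clinical.columns:
            return [c.core_id for c in self.cores]
        known = set(self.clinical["patient_id"].astype(str))
        return [c.core_id for c in self.cores if c.patient_id not in known]

    def patients(self) -> list[str]:
        return sorted({c.patient_id for c in self.cores})


def _map_labels(labels: pd.Series, label_map: Mapping[str, CellClass] | None) -> pd.Series:
    table = {k.strip().lower(): CellClass(v) for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    norm = labels.astype(str).str.strip().str.lower()
    mapped = norm.map(table)
    if mapped.isna().any():
        offenders = sorted(labels[mapped.isna()].astype(str).unique())
        raise ValidationError(f"unmappable cell class labels: {offenders}")
    return mapped


def read_cell_table(
    path: str | Path,
    dialect: Dialect | str = Dialect.GENERIC_CSV,
    *,
    core_id: str,
    patient_id: str,
    region: Region | str,
    marker: Marker | str,
    label_map: Mapping[str, CellClass] | None = None,
    window: Window | None = None,
    unit_scale: float = 1.0,
    qupath_columns: Mapping[str, str] | None = None,
    geojson_class_key: str = "classification",
) -> CoreSample:
    """Parse one per-core cell table into a :class:`CoreSample`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``GENERIC_CSV`` (columns ``x_um,y_um,class``), ``QUPATH_TSV``
        (tab-separated detection export; column names configurable via
        ``qupath_columns``) or ``GEOJSON`` (FeatureCollection of Point
        features; class label read from property ``geojson_class_key``,
        accepting either a plain string or QuPath's ``{"name": ...}`` dict).
    unit_scale
        Multiplier applied to raw coordinates to convert them to µm
        (e.g. 1000 for tables exported in mm).
    """
    dialect = Dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect is Dialect.GENERIC_CSV:
        df = pd.read_csv(path, float_precision="round_trip")
        required = ["x_um", "y_um", "class"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"{path.name}: missing mandatory column '{col}'")
        x, y, labels = df["x_um"], df["y_um"], df["class"]
    elif dialect is Dialect.QUPATH_TSV:
        cols = dict(DEFAULT_QUPATH_COLUMNS)
        cols.update(qupath_columns or {})
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        for key in ("x", "y", "class"):
            if cols[key] not in df.columns:
                raise FormatError(f"{path.name}: missing mandatory column '{cols[key]}'")
        x, y, labels = df[cols["x"]], df[cols["y"]], df[cols["class"]]
    else:  # GEOJSON
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        feats = doc.get("features")
        if feats is None:
            raise FormatError(f"{path.name}: not a GeoJSON FeatureCollection (no 'features')")
        xs, ys, labs = [], [], []
        for feat in feats:
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                continue
            cx, cy = geom["coordinates"][:2]
            cls = (feat.get("properties") or {}).get(geojson_class_key)
            if isinstance(cls, dict):
                cls = cls.get("name")
            if cls is None:
                raise FormatError(
                    f"{path.name}: point feature lacks classification property "
                    f"'{geojson_class_key}'"
                )
            xs.append(cx)
            ys.append(cy)
            labs.append(cls)
        x, y, labels = pd.Series(xs, dtype=float), pd.Series(ys, dtype=float), pd.Series(labs)

    if len(x) == 0:
        raise EmptyInputError(f"{path.name}: no cells in table")

    cells = pd.DataFrame(
        {
            "x": np.asarray(x, dtype=float) * unit_scale,
            "y": np.asarray(y, dtype=float) * unit_scale,
            "cell_class": _map_labels(labels, label_map),
        }
    )
    return CoreSample(
        core_id=core_id,
        patient_id=patient_id,
        region=Region(region),
        marker=Marker(marker),
        cells=cells,
        window=window,
    )


def write_cell_table(core: CoreSample, path: str | Path) -> Path:
    """Write a core in the GENERIC_CSV dialect (lossless round trip)."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "x_um": core.cells["x"].to_numpy(dtype=float),
            "y_um": core.cells["y"].to_numpy(dtype=float),
            "class": [CellClass(c).value for c in core.cells["cell_class"]],
        }
    )
    # repr-based float formatting so coordinates survive the round trip exactly
    out.to_csv(path, index=False, float_format=None)
    return path


def build_window(
    core: CoreSample,
    method: WindowMethod | str = WindowMethod.FIXED_DISC,
    *,
    diameter: float | None = None,
    margin: float = 10.0,
) -> Window:
    """Construct the observation window for a core.

    ``FIXED_DISC`` places a disc of the nominal core diameter on the cell
    centroid (the TMA punch geometry); ``CONVEX_HULL`` / ``BUFFERED_HULL``
    follow the tissue outline for irregular cores, the latter dilated by
    ``margin`` µm so boundary cells get a positive boundary distance.
    """
    method = WindowMethod(method)
    pts = core.coords()
    if method is WindowMethod.FIXED_DISC:
        if diameter is None or diameter <= 0:
            raise ParameterError(f"FIXED_DISC requires a positive diameter, got {diameter}")
        if pts.shape[0] == 0:
            raise GeometryError("cannot centre a disc on a core with no cells")
        cx, cy = pts.mean(axis=0)
        win = Window.disc(cx, cy, diameter / 2.0)
        outside = ~win.contains(pts)
        if outside.any():
            raise GeometryError(
                f"{int(outside.sum())} cells fall outside the {diameter} µm disc; "
                "use a larger diameter or a hull-based window"
            )
        return win
    # hull-based methods
    if pts.shape[0] < 3:
        raise GeometryError("hull window requires at least 3 cells")
    hull = shapely.multipoints(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise GeometryError("hull window requires at least 3 non-collinear cells")
    if method is WindowMethod.BUFFERED_HULL:
        if margin < 0:
            raise ParameterError(f"hull margin must be non-negative, got {margin}")
        hull = hull.buffer(margin, quad_segs=16)
    return Window.from_polygon(hull)


#: Required (marker, region) components of the scoring system.
REQUIRED_COMPONENTS: tuple[tuple[Marker, Region], ...] = (
    (Marker.CD3, Region.CT),
    (Marker.CD3, Region.IM),
    (Marker.CD8, Region.CT),
    (Marker.CD8, Region.IM),
)


def qc_filter_cohort(
    cohort: CohortData,
    min_tumour_cells: int = 20,
    min_tcells_allowed_zero: bool = True,
) -> tuple[CohortData, pd.DataFrame]:
    """Quality-filter a cohort, mirroring the TMA review step.

    Cores with fewer than ``min_tumour_cells`` tumour cells are dropped
    (a core with no or minimal tumour cannot support the tumour-anchored
    G estimate).  A patient is then retained only if at least one core
    survives for every (marker, region) combination of CD3/CD8 × CT/IM.
    With ``min_tcells_allowed_zero=False``, cores without any T cell are
    additionally dropped; by default they are kept, yielding a G curve
    that is identically zero.

    Returns the filtered cohort and an exclusion report with one row per
    excluded core (columns ``core_id, patient_id, level, reason``), so that
    ``len(report) + retained cores == input cores``.
    """
    if not cohort.cores:
        raise EmptyCohortError("cohort contains no cores")
    exclusions: list[dict] = []
    survivors: list[CoreSample] = []
    for core in cohort.cores:
        n_tum = core.count(CellClass.TUMOUR)
        n_tc = core.count(CellClass.T_CELL)
        if n_tum == 0:
            exclusions.append(
                {"core_id": core.core_id, "patient_id": core.patient_id,
                 "level": "core", "reason": "no tumour cells"}
            )
        elif n_tum < min_tumour_cells:
            exclusions.append(
                {"core_id": core.core_id, "patient_id": core.patient_id,
                 "level": "core",
                 "reason": f"tumour cells below threshold ({n_tum} < {min_tumour_cells})"}
            )
        elif not min_tcells_allowed_zero and n_tc == 0:
            exclusions.append(
                {"core_id": core.core_id, "patient_id": core.patient_id,
                 "level": "core", "reason": "no T cells"}
            )
        else:
            survivors.append(core)

    # patient completeness: every (marker, region) must keep >= 1 core
    by_patient: dict[str, set[tuple[Marker, Region]]] = {}
    for core in survivors:
        by_patient.setdefault(core.patient_id, set()).add((core.marker, core.region))
    complete = {
        pid for pid, combos in by_patient.items()
        if all(c in combos for c in REQUIRED_COMPONENTS)
    }
    retained: list[CoreSample] = []
    for core in survivors:
        if core.patient_id in complete:
            retained.append(core)
        else:
            missing = [
                f"{m.value}/{r.value}"
                for (m, r) in REQUIRED_COMPONENTS
                if (m, r) not in by_patient.get(core.patient_id, set())
            ]
            exclusions.append(
                {"core_id": core.core_id, "patient_id": core.patient_id,
                 "level": "patient", "reason": "missing " + ", ".join(missing)}
            )
    if not retained:
        raise EmptyCohortError("quality filtering excluded every patient")

    clinical = cohort.clinical
    report = pd.DataFrame(exclusions, columns=["core_id", "patient_id", "level", "reason"])
    filtered = CohortData(cores=retained, clinical=clinical, provenance=dict(cohort.provenance))
    return filtered, report


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical CSV (patient_id, time_days, events, covariates)."""
    df = pd.read_csv(path)
    for col in ("patient_id", "time_days"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing mandatory column '{col}'")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
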