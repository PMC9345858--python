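"""Cell densities and the cross-type nearest-neighbour distance function.

The central quantity is the empirical G-cross function
``G_tumour:T cell(r)``: the fraction of tumour cells whose nearest T cell
lies within radius ``r``.  Because a tumour cell close to the core boundary
may have its true nearest T cell outside the observation window, the
distance is treated as right-censored at the cell's distance to the window
boundary, and the Kaplan–Meier product-limit estimator is applied to the
censored distances (the standard edge correction for nearest-neighbour
distance distributions).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_io import CellClass, CoreSample
from .exceptions import GeometryError, ParameterError, ValidationError


class Correction(str, Enum):
    RAW = "RAW"  # uncorrected empirical CDF of nearest-neighbour distances
    KM = "KM"    # Kaplan-Meier product-limit on boundary-censored distances


@dataclass(frozen=True)
class NNDistanceData:
    """Per tumour cell: nearest cross-type distance and censoring structure.

    ``d`` is the distance to the nearest T cell centroid (``inf`` when the
    core has no T cells), ``b`` the distance to the window boundary.  The
    observed time is ``t = min(d, b)`` with event indicator ``d <= b``.
    """

    d: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if self.d.shape != self.b.shape:
            raise ValidationError("d and b must have identical shape")
        if np.any(self.b < 0):
            raise ValidationError("boundary distances must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return np.minimum(self.d, self.b)

    @property
    def event(self) -> np.ndarray:
        return self.d <= self.b

    def concat(self, other: "NNDistanceData") -> "NNDistanceData":
        return NNDistanceData(
            d=np.concatenate([self.d, other.d]), b=np.concatenate([self.b, other.b])
        )


@dataclass
class GCurve:
    """Right-continuous step estimate of G_tumour:T cell(r) for one core.

    ``jump_r``/``jump_g`` hold the jump locations (µm) and post-jump values;
    the implicit value at r = 0 is 0.  ``r_max`` is the largest boundary
    distance observed, beyond which the estimate is no longer reliable.
    """

    core_id: str
    n_tumour: int
    n_tcell: int
    correction: Correction
    jump_r: np.ndarray
    jump_g: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        self.correction = Correction(self.correction)
        if len(self.jump_r) != len(self.jump_g):
            raise ValidationError("jump radii and values must align")
        if len(self.jump_g):
            g = np.asarray(self.jump_g, dtype=float)
            if np.any(np.diff(g) < -1e-12) or g.min() < -1e-12 or g.max() > 1 + 1e-12:
                raise ValidationError("G estimate must be non-decreasing within [0, 1]")

    def __call__(self, r: float) -> float:
        return evaluate_g_at(self, r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_id": self.core_id,
                "correction": self.correction.value,
                "r_um": self.jump_r,
                "g_value": self.jump_g,
            }
        )


def compute_density(core: CoreSample, cell_class: CellClass) -> float:
    """Cell count of ``cell_class`` divided by the window area in mm²."""
    if core.window is None:
        raise GeometryError(f"core {core.core_id} has no observation window")
    area = core.window.area_mm2
    if area <= 0:
        raise GeometryError(f"core {core.core_id} window has zero area")
    return core.count(CellClass(cell_class)) / area


def nn_cross_distances(
    core: CoreSample,
    *,
    from_class: CellClass = CellClass.TUMOUR,
    to_class: CellClass = CellClass.T_CELL,
) -> NNDistanceData:
    """Nearest-neighbour distances from each ``from_class`` cell to ``to_class``.

    Uses a k-d tree; equals an exhaustive pairwise search exactly.
    """
    if core.window is None:
        raise GeometryError(f"core {core.core_id} has no observation window")
    src = core.coords(from_class)
    if src.shape[0] == 0:
        raise ValidationError(f"core {core.core_id} has no {from_class} cells")
    dst = core.coords(to_class)
    if dst.shape[0] == 0:
        d = np.full(src.shape[0], np.inf)
    else:
        d, _ = cKDTree(dst).query(src, k=1)
        d = np.asarray(d, dtype=float)
    b = core.window.boundary_distance(src)
    return NNDistanceData(d=d, b=b)


def _km_curve(t: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit CDF on (t, event): 1 - prod_{t(j)<=r}(1 - e_j/n_j).

    Ties between events and censorings at the same time are resolved
    events-first: a censored observation at time u is still at risk for
    events at u.
    """
    order = np.argsort(t, kind="stable")
    t = t[order]
    event = event[order]
    times = np.unique(t[event])
    surv = 1.0
    jump_r, jump_g = [], []
    n = len(t)
    for u in times:
        n_risk = n - np.searchsorted(t, u, side="left")
        e = int(np.sum((t == u) & event))
        if n_risk <= 0:
            break
        surv *= 1.0 - e / n_risk
        jump_r.append(u)
        jump_g.append(1.0 - surv)
    return np.asarray(jump_r, dtype=float), np.asarray(jump_g, dtype=float)


def gcross_from_distances(
    nnd: NNDistanceData,
    correction: Correction | str = Correction.KM,
    *,
    core_id: str = "",
    n_tcell: int = 0,
) -> GCurve:
    """Build a :class:`GCurve` from precomputed censored NN distances."""
    correction = Correction(correction)
    n = len(nnd.d)
    r_max = float(np.max(nnd.b)) if n else 0.0
    if n_tcell == 0 and not np.isfinite(nnd.d).any():
        # no T cells anywhere: co-localisation likelihood is identically 0
        return GCurve(core_id, n, n_tcell, correction, np.empty(0), np.empty(0), r_max)
    if correction is Correction.RAW:
        finite = nnd.d[np.isfinite(nnd.d)]
        r = np.unique(finite)
        g = np.searchsorted(np.sort(finite), r, side="right") / n
        return GCurve(core_id, n, n_tcell, correction, r, g, r_max)
    jump_r, jump_g = _km_curve(nnd.t, nnd.event)
    return GCurve(core_id, n, n_tcell, correction, jump_r, jump_g, r_max)


def gcross(core: CoreSample, correction: Correction | str = Correction.KM) -> GCurve:
    """Empirical G-cross function of one core (RAW ECDF or KM edge-corrected)."""
    nnd = nn_cross_distances(core)
    return gcross_from_distances(
        nnd, correction, core_id=core.core_id, n_tcell=core.count(CellClass.T_CELL)
    )


def evaluate_g_at(curve: GCurve, r: float, *, return_flag: bool = False):
    """Right-continuous evaluation of a G curve at radius ``r``.

    Beyond ``r_max`` (the largest observed boundary distance) the last value
    is returned; with ``return_flag=True`` the second element of the result
    flags such beyond-reliable-range evaluations.
    """
    if r < 0:
        raise ParameterError(f"radius must be non-negative, got {r}")
    idx = int(np.searchsorted(curve.jump_r, r, side="right"))
    value = float(curve.jump_g[idx - 1]) if idx > 0 else 0.0
    if return_flag:
        return value, bool(r > curve.r_max)
    return value


def gcurves_to_frame(curves: Iterable[GCurve]) -> pd.DataFrame:
    """Long-format export: one row per jump point (core_id, correction, r_um, g_value)."""
    frames = [c.to_frame() for c in curves]
    if not frames:
        return pd.DataFrame(columns=["core_id", "correction", "r_um", "g_value"])
    return pd.concat(frames, ignore_index=True)
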