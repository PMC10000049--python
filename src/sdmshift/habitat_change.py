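"""Suitability classification, range-change accounting, and centroid shifts.

A continuous suitability surface p ∈ [0,1] is cut into four classes —
highly (p ≥ 0.6), moderately (0.4 ≤ p < 0.6), poorly (0.2 ≤ p < 0.4)
suitable, and unsuitable (p < 0.2).  "Suitable" for change and centroid
purposes means p ≥ 0.2 (the union of the three suitable classes).  Current
vs. future classified maps are compared cell-wise into gain / loss / stable
/ consistently-unsuitable categories, with areas from the exact spherical
cell-area formula, and the displacement of the suitable-area centroid is
reported as a great-circle distance and initial bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import Grid, GridAlignmentError, area_grid_km2, cell_center
from .occurrence_prep import haversine_km

CLASS_LABELS = {0: "unsuitable", 1: "poor", 2: "moderate", 3: "high"}
CHANGE_LABELS = {0: "consistently_unsuitable", 1: "loss", 2: "stable", 3: "gain"}
DEFAULT_THRESHOLDS = (0.2, 0.4, 0.6)


class SuitabilityError(ValueError):
    pass


def classify(suitability: Grid, thresholds=DEFAULT_THRESHOLDS) -> Grid:
    """Label each valid cell 0..3 per the threshold rules; nodata propagated.

    Boundary semantics: high ⇔ p ≥ t3; moderate ⇔ t2 ≤ p < t3;
    poor ⇔ t1 ≤ p < t2; unsuitable ⇔ p < t1.
    """
    t1, t2, t3 = thresholds
    mask = suitability.mask
    p = suitability.values
    if np.any((p[~mask] < 0) | (p[~mask] > 1)):
        raise SuitabilityError("suitability values outside [0, 1]")
    labels = np.zeros_like(p)
    labels[p >= t1] = 1
    labels[p >= t2] = 2
    labels[p >= t3] = 3
    labels[mask] = suitability.nodata_value
    return suitability.copy_with(labels)


def class_areas(classified: Grid) -> pd.DataFrame:
    """Per-class area (km²) and share of the suitable area.

    Suitable area = high + moderate + poor.  ``share_pct`` is the raw
    percentage; ``share_pct_rounded`` is the nearest-integer report style.
    """
    areas = area_grid_km2(classified)
    mask = classified.mask
    rows = []
    per_class = {}
    for code, label in CLASS_LABELS.items():
        sel = (classified.values == code) & ~mask
        per_class[label] = float(areas[sel].sum())
    suitable = per_class["high"] + per_class["moderate"] + per_class["poor"]
    for label in ("high", "moderate", "poor", "unsuitable"):
        a = per_class[label]
        share = 100.0 * a / suitable if label != "unsuitable" and suitable > 0 else np.nan
        rows.append({"class": label, "area_km2": a, "share_pct": share,
                     "share_pct_rounded": int(round(share)) if np.isfinite(share) else np.nan})
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["suitable_km2"] = suitable
    return out


def suitable_area_km2(classified: Grid) -> float:
    df = class_areas(classified)
    return float(df.attrs["suitable_km2"])


def change_map(current: Grid, future: Grid) -> Grid:
    """Cell-wise change categories between two classified maps.

    suitable ⇔ class ≥ poor (p ≥ 0.2); loss = suitable→unsuitable,
    gain = unsuitable→suitable, stable = suitable→suitable, else
    consistently unsuitable.  Cells nodata in either map are nodata.
    """
    if not current.same_header(future):
        raise GridAlignmentError("current/future grids not aligned")
    mask = current.mask | future.mask
    cur = (current.values >= 1) & (current.values <= 3) & ~mask
    fut = (future.values >= 1) & (future.values <= 3) & ~mask
    out = np.zeros(current.values.shape)
    out[cur & ~fut] = 1   # loss
    out[cur & fut] = 2    # stable
    out[~cur & fut] = 3   # gain
    out[mask] = current.nodata_value
    return current.copy_with(out)


@dataclass
class ChangeAccount:
    """Gain/loss/stable areas and percentages vs the current suitable area."""

    gain_km2: float
    loss_km2: float
    stable_km2: float
    current_suitable_km2: float

    @property
    def net_change_km2(self) -> float:
        return self.gain_km2 - self.loss_km2

    def _pct(self, area: float) -> float:
        return 100.0 * area / self.current_suitable_km2

    @property
    def gain_pct(self) -> float:
        return self._pct(self.gain_km2)

    @property
    def loss_pct(self) -> float:
        return self._pct(self.loss_km2)

    @property
    def stable_pct(self) -> float:
        return self._pct(self.stable_km2)

    @property
    def net_pct(self) -> float:
        return self._pct(self.net_change_km2)

    def to_row(self) -> dict:
        """Report-style row: areas as-is, percentages to 2 decimals."""
        return {
            "gain_km2": self.gain_km2, "loss_km2": self.loss_km2,
            "stable_km2": self.stable_km2, "net_change_km2": self.net_change_km2,
            "gain_pct": round(self.gain_pct, 2), "loss_pct": round(self.loss_pct, 2),
            "stable_pct": round(self.stable_pct, 2), "net_pct": round(self.net_pct, 2),
        }


def change_accounting(change: Grid, current_suitable_km2: float) -> ChangeAccount:
    if current_suitable_km2 <= 0:
        raise ZeroDivisionError("current suitable area must be positive")
    areas = area_grid_km2(change)
    mask = change.mask
    def area_of(code: int) -> float:
        return float(areas[(change.values == code) & ~mask].sum())
    return ChangeAccount(area_of(3), area_of(1), area_of(2), current_suitable_km2)


@dataclass
class Centroid:
    lon: float
    lat: float
    threshold: float = 0.2
    weighting: str = "binary"


def centroid(suitability: Grid, threshold: float = 0.2,
             weighting: str = "binary") -> Centroid:
    """Area-weighted mean cell-center of cells with p ≥ threshold.

    ``weighting="suitability"`` multiplies each cell's area weight by its p.
    Longitudes are averaged arithmetically (domains far from the
    antimeridian).
    """
    if weighting not in ("binary", "suitability"):
        raise ValueError("weighting must be 'binary' or 'suitability'")
    mask = suitability.mask
    sel = (suitability.values >= threshold) & ~mask
    if not sel.any():
        raise SuitabilityError("no cells at or above the threshold")
    rows, cols = np.nonzero(sel)
    lon, lat = cell_center(suitability, rows, cols)
    w = area_grid_km2(suitability)[rows, cols]
    if weighting == "suitability":
        w = w * suitability.values[rows, cols]
    w = w / w.sum()
    return Centroid(float(w @ lon), float(w @ lat), threshold, weighting)


def centroid_shift(a: Centroid, b: Centroid) -> tuple[float, float]:
    """Great-circle distance (km) and initial bearing (° clockwise from
    north) from centroid a to centroid b; bearing is NaN for identical
    centroids."""
    d = haversine_km((a.lon, a.lat), (b.lon, b.lat))
    if d == 0.0:
        return 0.0, float("nan")
    lam1, phi1 = np.radians([a.lon, a.lat])
    lam2, phi2 = np.radians([b.lon, b.lat])
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    bearing = (np.degrees(np.arctan2(y, x)) + 360.0) % 360.0
    return float(d), float(bearing)
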