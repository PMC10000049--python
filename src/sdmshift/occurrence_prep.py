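"""Occurrence loading and spatial thinning.

Survey records of a species are often clustered (many observations around
one wetland), which inflates spatial autocorrelation in presence-background
models.  The standard remedy is to thin records so that every retained pair
is at least a minimum great-circle distance apart — here 2 km by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_io import EARTH_RADIUS_KM


class CoordinateError(ValueError):
    pass


def haversine_km(a, b) -> np.ndarray | float:
    """Great-circle distance in km between lon/lat points (broadcasting).

    ``a`` and ``b`` are (lon, lat) pairs or (n, 2) arrays in decimal degrees.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scalar = a.ndim == 1 and b.ndim == 1
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    for arr in (a, b):
        if np.any(np.abs(arr[..., 0]) > 180) or np.any(np.abs(arr[..., 1]) > 90):
            raise CoordinateError("coordinates outside [-180,180] x [-90,90]")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d[0]) if scalar else d


@dataclass
class OccurrenceSet:
    """Ordered lon/lat occurrence points; duplicates collapsed on creation."""

    points: np.ndarray
    thinning_radius_km: float = 0.0
    ids: list | None = field(default=None)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise CoordinateError("points must be (n, 2) lon/lat")
        # collapse exact duplicates, keeping first occurrence order
        _, idx = np.unique(pts, axis=0, return_index=True)
        keep = np.sort(idx)
        self.points = pts[keep]
        if self.ids is not None:
            self.ids = [self.ids[i] for i in keep]

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["lon", "lat"])


def load_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV with at least ``lon`` and ``lat`` header columns."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise CoordinateError(f"{path}: need 'lon' and 'lat' columns")
    return OccurrenceSet(df[[cols["lon"], cols["lat"]]].to_numpy())


def save_occurrences(occ: OccurrenceSet, path: str | Path,
                     retained: np.ndarray | None = None) -> None:
    df = occ.to_frame()
    if retained is not None:
        df["retained"] = np.asarray(retained, dtype=int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def thin_occurrences(occ: OccurrenceSet, min_km: float = 2.0,
                     seed: int | None = None) -> OccurrenceSet:
    """Greedy spatial thinning: keep a point iff it is at least ``min_km``
    from every already-kept point.

    The threshold is inclusive ("at least"): a pair exactly ``min_km`` apart
    is kept.  With ``seed=None`` the scan runs in input order; an integer
    seed shuffles the scan order first (result is still maximal: no dropped
    point could be added back).  Empty input returns an empty set.
    """
    if min_km < 0:
        raise ValueError("min_km must be non-negative")
    n = len(occ)
    if n == 0 or min_km == 0:
        return OccurrenceSet(occ.points.copy(), thinning_radius_km=min_km)

    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)

    kept: list[int] = []
    for i in order:
        p = occ.points[i]
        # 1e-9 km slack keeps the inclusive boundary robust to roundoff
        if not kept or np.all(haversine_km(p, occ.points[kept]) >= min_km - 1e-9):
            kept.append(int(i))
    kept.sort()
    return OccurrenceSet(occ.points[kept], thinning_radius_km=min_km)
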