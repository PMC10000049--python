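"""Synthetic landscapes with known truth for end-to-end pipeline testing.

Real wintering-survey coordinates and climate rasters are not distributable,
so every pipeline stage is exercised against generated stand-ins: smooth
spatially autocorrelated environmental fields on a common geographic grid, a
categorical land-use layer, a distance-to-water field derived from a random
water mask, presences sampled from a known logistic suitability surface, and
"future" layer sets in which the climate layers are perturbed by a known
amount while static layers pass through unchanged.

Default ranges echo field-realistic optima for a wintering waterbird:
a temperature layer (°C, mean of the driest quarter analog) with a
north-south gradient and a suitable band centred at 7 °C (4–10 °C wide), a
precipitation layer (mm) with a 110–190 mm band centred at 150 mm, altitude
preferred below 100 m, suitability decaying with distance to water, plus a
pure-noise layer and an uninformative categorical layer as negative
controls.  The default 200×200 grid at 30″ keeps a full run fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .grid_io import Grid, GridStack, cell_center, harmonize_stack
from .occurrence_prep import OccurrenceSet

NODATA = -9999.0


class SpecError(ValueError):
    pass


def _default_variables() -> dict[str, dict[str, Any]]:
    return {
        # north-south gradient: warmer to the south; gradient in °C per
        # degree latitude (steep so the suitable band fits a small domain)
        "temp": {"kind": "gradient_lat", "base": 7.0, "gradient": 4.0,
                 "noise_amp": 0.4, "noise_scale": 8.0, "dynamic": True},
        # east-west precipitation gradient, mm
        "precip": {"kind": "gradient_lon", "base": 150.0, "gradient": 40.0,
                   "noise_amp": 10.0, "noise_scale": 10.0, "dynamic": True},
        # smooth noise field rescaled to 0..300 m
        "alt": {"kind": "noise_field", "lo": 0.0, "hi": 300.0,
                "noise_scale": 12.0, "dynamic": False},
        # derived from the water mask; km
        "water_dist": {"kind": "water_distance", "density": 0.01,
                       "dynamic": False},
        # pure-noise continuous layer, negative control
        "noise": {"kind": "noise_field", "lo": 0.0, "hi": 1.0,
                  "noise_scale": 6.0, "dynamic": False},
        # categorical layer with no true effect
        "landuse": {"kind": "categorical", "levels": 4, "noise_scale": 10.0,
                    "dynamic": False},
    }


def _default_true_model() -> dict[str, Any]:
    return {
        "intercept": 4.0,
        "terms": {
            "temp": {"kind": "band", "opt": 7.0, "scale": 1.2, "weight": 5.0},
            "precip": {"kind": "band", "opt": 150.0, "scale": 25.0, "weight": 2.5},
            "alt": {"kind": "linear", "slope": -0.012},
            "water_dist": {"kind": "linear", "slope": -1.5},
        },
    }


@dataclass
class LandscapeSpec:
    """Stated world of the synthetic study area (reproducible from seed)."""

    nrows: int = 200
    ncols: int = 200
    xllcorner: float = 112.0
    yllcorner: float = 28.0
    cellsize: float = 1.0 / 120.0  # 30 arc-seconds
    nodata_fraction: float = 0.02
    variables: dict[str, dict[str, Any]] = field(default_factory=_default_variables)
    true_model: dict[str, Any] = field(default_factory=_default_true_model)
    # default future scenario: +1.2 °C warming, +5% dry-quarter precipitation
    future_deltas: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"temp": ("add", 1.2), "precip": ("mul", 1.05)})

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise SpecError("grid must have positive shape")
        if self.cellsize <= 0:
            raise SpecError("cellsize must be positive")

    def dynamic_names(self) -> list[str]:
        return [n for n, v in self.variables.items() if v.get("dynamic")]

    def categorical_names(self) -> list[str]:
        return [n for n, v in self.variables.items() if v["kind"] == "categorical"]


@dataclass
class SyntheticLandscape:
    stack: GridStack
    truth: Grid                 # true suitability s(x) in [0,1]
    spec: LandscapeSpec
    metadata: dict[str, Any] = field(default_factory=dict)


# -- field builders ----------------------------------------------------------

def _smooth_noise(shape: tuple[int, int], scale: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-ish variance spatially autocorrelated field
    (low-pass filtered white noise)."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _latlon_fields(spec: LandscapeSpec) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(spec.nrows)
    cols = np.arange(spec.ncols)
    ref = Grid(spec.ncols, spec.nrows, spec.xllcorner, spec.yllcorner,
               spec.cellsize, NODATA, np.zeros((spec.nrows, spec.ncols)))
    lon_c, _ = cell_center(ref, np.zeros_like(cols), cols)
    _, lat_c = cell_center(ref, rows, np.zeros_like(rows))
    lon = np.broadcast_to(lon_c[None, :], (spec.nrows, spec.ncols)).copy()
    lat = np.broadcast_to(lat_c[:, None], (spec.nrows, spec.ncols)).copy()
    return lon, lat


def _ground_sampling_km(spec: LandscapeSpec) -> tuple[float, float]:
    """(row step, col step) in km at the domain's central latitude."""
    lat_mid = spec.yllcorner + spec.nrows * spec.cellsize / 2
    from .grid_io import EARTH_RADIUS_KM
    step = np.radians(spec.cellsize) * EARTH_RADIUS_KM
    return step, step * float(np.cos(np.radians(lat_mid)))


def _make_variable(name: str, vspec: dict[str, Any], spec: LandscapeSpec,
                   lon: np.ndarray, lat: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    kind = vspec["kind"]
    shape = (spec.nrows, spec.ncols)
    if kind == "gradient_lat":
        lat_mid = spec.yllcorner + spec.nrows * spec.cellsize / 2
        base = vspec["base"] + vspec["gradient"] * (lat_mid - lat)
        return base + vspec["noise_amp"] * _smooth_noise(shape, vspec["noise_scale"], rng)
    if kind == "gradient_lon":
        lon_mid = spec.xllcorner + spec.ncols * spec.cellsize / 2
        base = vspec["base"] + vspec["gradient"] * (lon - lon_mid)
        return base + vspec["noise_amp"] * _smooth_noise(shape, vspec["noise_scale"], rng)
    if kind == "noise_field":
        f = _smooth_noise(shape, vspec["noise_scale"], rng)
        f = (f - f.min()) / (f.max() - f.min())
        return vspec["lo"] + f * (vspec["hi"] - vspec["lo"])
    if kind == "water_distance":
        water = rng.random(shape) < vspec["density"]
        if not water.any():
            water[shape[0] // 2, shape[1] // 2] = True
        sampling = _ground_sampling_km(spec)
        return ndimage.distance_transform_edt(~water, sampling=sampling)
    if kind == "categorical":
        f = _smooth_noise(shape, vspec["noise_scale"], rng)
        edges = np.quantile(f, np.linspace(0, 1, vspec["levels"] + 1)[1:-1])
        return np.digitize(f, edges).astype(float)
    raise SpecError(f"unknown variable kind {kind!r}")


def _true_logit(spec: LandscapeSpec, layers: dict[str, np.ndarray]) -> np.ndarray:
    tm = spec.true_model
    logit = np.full(next(iter(layers.values())).shape, float(tm["intercept"]))
    for name, term in tm["terms"].items():
        x = layers[name]
        if term["kind"] == "band":
            logit += -term.get("weight", 1.0) * ((x - term["opt"]) / term["scale"]) ** 2
        elif term["kind"] == "linear":
            logit += term["slope"] * x * term.get("weight", 1.0)
        else:
            raise SpecError(f"unknown true-model term kind {term['kind']!r}")
    return logit


# -- public operations -------------------------------------------------------

def make_landscape(spec: LandscapeSpec | None = None, seed: int = 0,
                   ) -> SyntheticLandscape:
    """Generate the aligned layer stack and the true suitability surface.

    All randomness flows from one seed; the same (spec, seed) pair is
    bit-identical.  A smoothed random blob of cells becomes shared nodata
    when ``nodata_fraction`` > 0.
    """
    spec = spec or LandscapeSpec()
    rng = np.random.default_rng(seed)
    lon, lat = _latlon_fields(spec)

    raw: dict[str, np.ndarray] = {}
    for name, vspec in spec.variables.items():
        raw[name] = _make_variable(name, vspec, spec, lon, lat, rng)

    with np.errstate(over="ignore"):
        truth = 1.0 / (1.0 + np.exp(-_true_logit(spec, raw)))

    mask = np.zeros((spec.nrows, spec.ncols), dtype=bool)
    if spec.nodata_fraction > 0:
        blob = _smooth_noise((spec.nrows, spec.ncols), 6.0, rng)
        cut = np.quantile(blob, spec.nodata_fraction)
        mask = blob < cut

    grids: dict[str, Grid] = {}
    for name, vals in raw.items():
        v = vals.copy()
        v[mask] = NODATA
        grids[name] = Grid(spec.ncols, spec.nrows, spec.xllcorner,
                           spec.yllcorner, spec.cellsize, NODATA, v)
    stack = harmonize_stack(grids, categorical=spec.categorical_names())

    t = truth.copy()
    t[mask] = NODATA
    truth_grid = stack.grid.copy_with(t)

    meta = {"seed": seed, "n_valid": int((~mask).sum())}
    return SyntheticLandscape(stack, truth_grid, spec, meta)


def sample_presences(truth: Grid, n: int, seed: int = 0) -> OccurrenceSet:
    """Draw n occurrence points from the true suitability surface.

    Cells are drawn (with replacement) with probability proportional to
    true suitability × cell area; each point is then placed uniformly
    within its cell, so no presence can land on a nodata cell.
    """
    if n == 0:
        return OccurrenceSet(np.empty((0, 2)))
    from .grid_io import area_grid_km2
    mask = truth.mask
    w = np.where(mask, 0.0, truth.values) * area_grid_km2(truth)
    total = w.sum()
    if total <= 0:
        raise SpecError("true suitability sums to zero")
    flat = (w / total).ravel()
    rng = np.random.default_rng(seed)
    draws = rng.choice(flat.size, size=n, p=flat, replace=True)
    rows, cols = np.unravel_index(draws, w.shape)
    u = rng.random((n, 2))
    lon = truth.xllcorner + (cols + u[:, 0]) * truth.cellsize
    lat = truth.yllcorner + (truth.nrows - 1 - rows + u[:, 1]) * truth.cellsize
    return OccurrenceSet(np.column_stack([lon, lat]))


def make_future(landscape: SyntheticLandscape,
                deltas: dict[str, tuple[str, float]] | None = None,
                seed: int = 0) -> SyntheticLandscape:
    """Apply climate deltas and recompute truth under the same true model.

    Only dynamic layers may be perturbed ("add" or "mul"); static layers
    (altitude, water distance, land use, noise) pass through byte-identical
    as conservative prognoses.  Metadata records the imposed northward shift
    of the temperature optimum, Δ/gradient degrees of latitude, when a
    latitudinal-gradient layer is warmed additively.
    """
    spec = landscape.spec
    deltas = spec.future_deltas if deltas is None else deltas
    dynamic = set(spec.dynamic_names())
    bad = set(deltas) - dynamic
    if bad:
        raise SpecError(f"deltas on static layers: {sorted(bad)}")

    mask = landscape.stack.mask
    new_layers: dict[str, np.ndarray] = {}
    for name, g in landscape.stack.layers.items():
        vals = g.values.copy()
        if name in deltas:
            op, amount = deltas[name]
            valid = ~mask
            if op == "add":
                vals[valid] += amount
            elif op == "mul":
                vals[valid] *= amount
            else:
                raise SpecError(f"unknown delta op {op!r}")
        new_layers[name] = vals

    with np.errstate(over="ignore"):
        truth = 1.0 / (1.0 + np.exp(-_true_logit(spec, new_layers)))
    grids = {name: landscape.stack.layers[name].copy_with(v)
             for name, v in new_layers.items()}
    for g in grids.values():
        g.values[mask] = g.nodata_value
    stack = harmonize_stack(grids, categorical=spec.categorical_names())
    t = truth.copy()
    t[mask] = NODATA
    truth_grid = stack.grid.copy_with(t)

    meta = dict(landscape.metadata)
    meta["deltas"] = {k: list(v) for k, v in deltas.items()}
    # closed-form displacement of each gradient layer's optimum:
    #   additive Δ on base + g·(lat_mid − lat)  → band moves north by Δ/g
    #   multiplicative a on base + g·(lon − lon_mid) → optimum moves to
    #   lon_mid + base(1 − a)/(a·g)
    dlat = dlon = 0.0
    for name, (op, amount) in deltas.items():
        vspec = spec.variables[name]
        g = vspec.get("gradient", 0.0)
        if g == 0:
            continue
        if vspec["kind"] == "gradient_lat" and op == "add":
            dlat += amount / g
        elif vspec["kind"] == "gradient_lon" and op == "mul" and amount != 0:
            dlon += vspec["base"] * (1.0 - amount) / (amount * g)
        elif vspec["kind"] == "gradient_lon" and op == "add":
            dlon += -amount / g
        elif vspec["kind"] == "gradient_lat" and op == "mul" and amount != 0:
            dlat += -vspec["base"] * (1.0 - amount) / (amount * g)
    lat_mid = spec.yllcorner + spec.nrows * spec.cellsize / 2
    km_per_deg = np.pi / 180.0 * 6371.0088
    dx = dlon * km_per_deg * np.cos(np.radians(lat_mid))
    dy = dlat * km_per_deg
    meta["imposed_lat_shift_deg"] = dlat
    meta["imposed_lon_shift_deg"] = dlon
    meta["imposed_shift_km"] = float(np.hypot(dx, dy))
    return SyntheticLandscape(stack, truth_grid, spec, meta)
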