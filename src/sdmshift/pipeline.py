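"""End-to-end orchestration: thin → filter → replicate-fit → average →
classify → per-scenario project/classify/change/centroid, plus the synthetic
input generator that produces a ready-to-run directory.

Every run writes a machine-readable manifest (config, seeds) alongside the
output grids and tables, so each table is re-derivable from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collinearity import greedy_filter, pearson_matrix
from .evaluation import run_replicates
from .grid_io import GridStack, harmonize_stack, read_ascii_grid, write_ascii_grid
from .habitat_change import (
    CLASS_LABELS, DEFAULT_THRESHOLDS, centroid, centroid_shift, change_accounting,
    change_map, class_areas, classify,
)
from .maxent_engine import TrainConfig, percent_contribution, sample_background
from .occurrence_prep import load_occurrences, save_occurrences, thin_occurrences
from .synthetic_scenarios import (
    LandscapeSpec, make_future, make_landscape, sample_presences,
)

log = logging.getLogger("sdmshift")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study settings
    (2 km thinning, r > 0.8, 25% test, 500 iterations, 10,000 background,
    15 replicates, thresholds 0.2/0.4/0.6)."""

    occurrences: str = "occurrences.csv"
    current_dir: str = "current"
    scenario_dirs: dict[str, str] = field(default_factory=dict)
    categorical: list[str] = field(default_factory=list)
    thinning_km: float = 2.0
    correlation_threshold: float = 0.8
    keep_priority: list[str] | None = None
    test_fraction: float = 0.25
    n_replicates: int = 15
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    seed: int = 0
    output_dir: str = "run_output"
    # TrainConfig fields
    max_iterations: int = 500
    n_background: int = 10_000
    beta_multiplier: float = 1.0
    n_hinge_knots: int = 20
    convergence_tol: float = 1e-5

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            max_iterations=self.max_iterations, n_background=self.n_background,
            beta_multiplier=self.beta_multiplier, n_hinge_knots=self.n_hinge_knots,
            convergence_tol=self.convergence_tol, seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)


def _read_layer_dir(path: str | Path, categorical: list[str]) -> GridStack:
    files = sorted(Path(path).glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc layers in {path}")
    grids = {f.stem: read_ascii_grid(f) for f in files}
    return harmonize_stack(grids, categorical=[c for c in categorical if c in grids])


def _stage(name: str, t0: float, **info) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s wall=%.2fs %s", name, time.time() - t0, extra)


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> dict:
    """Execute the full analysis; returns a summary dict (also written to
    ``output_dir/manifest.json``)."""
    base = Path(base_dir)
    out = base / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    occ = load_occurrences(base / config.occurrences)
    thinned = thin_occurrences(occ, config.thinning_km)
    _stage("thin", t0, n_in=len(occ), n_out=len(thinned))

    stack = _read_layer_dir(base / config.current_dir, config.categorical)
    tcfg = config.train_config()

    # collinearity screen at the background sample; categorical layers exempt
    bg = sample_background(stack, tcfg.n_background, seed=config.seed)
    continuous = stack.continuous_names()
    cm = pearson_matrix(bg[continuous])
    retained_cont = greedy_filter(cm, config.correlation_threshold,
                                  config.keep_priority)
    retained = [n for n in stack.names
                if n in retained_cont or n in stack.categorical]
    cm.to_frame().to_csv(out / "correlation_matrix.csv")
    pd.Series(retained, name="variable").to_csv(out / "retained_variables.csv",
                                                index=False)
    stack = stack.subset(retained)
    _stage("filter", t0, retained=len(retained))

    mean_grid, eval_result, models = run_replicates(
        thinned, stack, tcfg, n_replicates=config.n_replicates,
        base_seed=config.seed, test_fraction=config.test_fraction)
    write_ascii_grid(mean_grid, out / "suitability_current.asc")
    eval_result.per_replicate.to_csv(out / "auc_replicates.csv", index=False)
    contrib = pd.concat([percent_contribution(m) for m in models], axis=1).mean(axis=1)
    contrib = contrib.sort_values(ascending=False)
    contrib.rename("contribution_pct").to_csv(out / "percent_contribution.csv")
    _stage("fit", t0, auc_test=round(eval_result.auc_test_mean, 4))

    classified = classify(mean_grid, config.thresholds)
    write_ascii_grid(classified, out / "classified_current.asc")
    areas = class_areas(classified)
    areas.to_csv(out / "class_areas_current.csv")
    current_suitable = float(areas.attrs["suitable_km2"])
    cur_centroid = centroid(mean_grid, config.thresholds[0])
    (out / "legend.txt").write_text(
        "\n".join(f"{k} {v}" for k, v in CLASS_LABELS.items()) + "\n")
    _stage("classify", t0, suitable_km2=round(current_suitable, 1))

    change_rows = []
    centroid_rows = [{"scenario": "current", "lon": cur_centroid.lon,
                      "lat": cur_centroid.lat, "shift_km": 0.0, "bearing_deg": np.nan}]
    scenario_areas = {}
    for name, sdir in config.scenario_dirs.items():
        fstack = _read_layer_dir(base / sdir, config.categorical).subset(retained)
        fmaps = [m.predict(fstack.table()) for m in models]
        table = fstack.table()
        ref = fstack.grid
        vals = np.full((ref.nrows, ref.ncols), ref.nodata_value)
        vals[table["row"], table["col"]] = np.mean(fmaps, axis=0)
        fmean = ref.copy_with(vals)
        write_ascii_grid(fmean, out / f"suitability_{name}.asc")
        fcls = classify(fmean, config.thresholds)
        write_ascii_grid(fcls, out / f"classified_{name}.asc")
        scenario_areas[name] = class_areas(fcls)
        scenario_areas[name].to_csv(out / f"class_areas_{name}.csv")

        ch = change_map(classified, fcls)
        write_ascii_grid(ch, out / f"change_{name}.asc")
        acct = change_accounting(ch, current_suitable)
        change_rows.append({"scenario": name, **acct.to_row()})

        fcent = centroid(fmean, config.thresholds[0])
        dist, bearing = centroid_shift(cur_centroid, fcent)
        centroid_rows.append({"scenario": name, "lon": fcent.lon,
                              "lat": fcent.lat, "shift_km": dist,
                              "bearing_deg": bearing})
        _stage(f"scenario:{name}", t0, net_km2=round(acct.net_change_km2, 1))

    change_df = pd.DataFrame(change_rows)
    if len(change_df):
        change_df.to_csv(out / "change_accounts.csv", index=False)
    centroid_df = pd.DataFrame(centroid_rows)
    centroid_df.to_csv(out / "centroids.csv", index=False)

    cfg_doc = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_doc,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "n_occurrences": len(occ), "n_thinned": len(thinned),
        "retained_variables": retained,
        "auc_test_mean": eval_result.auc_test_mean,
        "auc_test_sd": eval_result.auc_test_sd,
        "current_suitable_km2": current_suitable,
        "percent_contribution": contrib.to_dict(),
        "current_centroid": [cur_centroid.lon, cur_centroid.lat],
        "change_accounts": change_rows,
        "centroids": centroid_rows,
        "wall_seconds": time.time() - t0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest


def simulate_inputs(spec: LandscapeSpec | None = None, seed: int = 0,
                    out_dir: str | Path = "synthetic_inputs",
                    n_presences: int = 100) -> dict:
    """Write a complete ready-to-run input set from the synthetic generator:
    current layers, one warmed scenario, occurrences, and truth metadata."""
    spec = spec or LandscapeSpec()
    out = Path(out_dir)
    (out / "current").mkdir(parents=True, exist_ok=True)
    (out / "future_warm").mkdir(parents=True, exist_ok=True)

    land = make_landscape(spec, seed=seed)
    for name, g in land.stack.layers.items():
        write_ascii_grid(g, out / "current" / f"{name}.asc")
    write_ascii_grid(land.truth, out / "truth_current.asc")

    fut = make_future(land, seed=seed)
    for name, g in fut.stack.layers.items():
        write_ascii_grid(g, out / "future_warm" / f"{name}.asc")
    write_ascii_grid(fut.truth, out / "truth_future_warm.asc")

    occ = sample_presences(land.truth, n_presences, seed=seed)
    save_occurrences(occ, out / "occurrences.csv")

    meta = {
        "seed": seed, "n_presences": n_presences,
        "categorical": spec.categorical_names(),
        "imposed_lat_shift_deg": fut.metadata["imposed_lat_shift_deg"],
        "imposed_shift_km": fut.metadata["imposed_shift_km"],
    }
    (out / "truth_metadata.json").write_text(json.dumps(meta, indent=1))
    return meta
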