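"""Train/test splitting, replicate orchestration, and presence-background AUC.

With no true absences, model discrimination is scored against the background
sample: AUC is the probability that a random presence cell outscores a
random background cell, the rank-based Mann–Whitney estimate with ties
counted half.  The final suitability surface is the cell-wise mean over
replicate models, each fitted on a fresh random 75/25 occurrence split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid_io import Grid, GridStack, extract_values
from .maxent_engine import (
    DataError, MaxentModel, TrainConfig, build_features, fit_maxent,
    predict_grid, sample_background,
)
from .occurrence_prep import OccurrenceSet


@dataclass
class EvalResult:
    per_replicate: pd.DataFrame  # columns: replicate, seed, auc_train, auc_test

    @property
    def auc_test_mean(self) -> float:
        return float(self.per_replicate["auc_test"].mean())

    @property
    def auc_test_sd(self) -> float:
        return float(self.per_replicate["auc_test"].std(ddof=1)) \
            if len(self.per_replicate) > 1 else 0.0

    @property
    def auc_train_mean(self) -> float:
        return float(self.per_replicate["auc_train"].mean())


def split_occurrences(occ: OccurrenceSet, test_fraction: float = 0.25,
                      seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint, exhaustive train/test split.

    Test size is round-half-up of ``test_fraction · n`` (87 points → 22
    test, 65 train).  Deterministic per seed.
    """
    n = len(occ)
    if n < 4:
        raise DataError("need at least 4 occurrence points to split")
    n_test = int(np.floor(test_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (OccurrenceSet(occ.points[train_idx]), OccurrenceSet(occ.points[test_idx]))


def auc_presence_background(presence_scores, background_scores) -> float:
    """Mann–Whitney AUC: (#presence>background pairs + 0.5·ties) / (n_p·n_b).

    Invariant under strictly monotone transforms of the scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise DataError("empty score list")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(b))):
        raise DataError("non-finite scores")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def run_replicates(occ: OccurrenceSet, stack: GridStack,
                   config: TrainConfig | None = None,
                   n_replicates: int = 15, base_seed: int = 0,
                   test_fraction: float = 0.25,
                   ) -> tuple[Grid, EvalResult, list[MaxentModel]]:
    """Fit ``n_replicates`` models on fresh splits and average the maps.

    Replicate i uses seed ``base_seed + i`` for its split and background
    sample; presence cells are appended to the background (target-background
    union) for the normalizer.  Returns the cell-wise mean suitability grid,
    per-replicate AUCs, and the fitted models.
    """
    config = config or TrainConfig()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    maps: list[np.ndarray] = []
    rows = []
    models: list[MaxentModel] = []
    var_names = stack.names
    categorical = sorted(stack.categorical)

    for i in range(n_replicates):
        seed = base_seed + i
        train, test = split_occurrences(occ, test_fraction, seed=seed)
        bg = sample_background(stack, config.n_background, seed=seed)

        pres = extract_values(stack, train.points)
        pres = pres[pres["in_bounds"] & ~pres["nodata"]]
        if len(pres) < 2:
            raise DataError(f"replicate {i}: fewer than 2 usable presence cells")
        test_vals = extract_values(stack, test.points)
        test_vals = test_vals[test_vals["in_bounds"] & ~test_vals["nodata"]]

        train_table = pd.concat([pres[var_names], bg[var_names]], ignore_index=True)
        fs = build_features(train_table, config, categorical=categorical)
        Xp = fs.design_matrix(pres[var_names])
        Xb = fs.design_matrix(train_table)  # target-background union
        model = fit_maxent(Xp, Xb, config, feature_set=fs)
        models.append(model)

        score_bg = model.predict(bg[var_names])
        auc_train = auc_presence_background(model.predict(pres[var_names]), score_bg)
        auc_test = auc_presence_background(model.predict(test_vals[var_names]),
                                           score_bg) if len(test_vals) else np.nan
        rows.append({"replicate": i, "seed": seed,
                     "auc_train": auc_train, "auc_test": auc_test})

        grid_i = predict_grid(model, stack)
        maps.append(grid_i.data)  # nodata → NaN

    ref = stack.grid
    stacked = np.stack(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN at nodata cells
        mean_map = np.nanmean(stacked, axis=0)
    out = np.where(np.isnan(mean_map), ref.nodata_value, mean_map)
    return ref.copy_with(out), EvalResult(pd.DataFrame(rows)), models
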