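"""Presence-background maximum-entropy (MaxEnt) model, built from scratch.

The model estimates a Gibbs distribution q(x) = exp(λ·f(x)) / Z over the
cells of a landscape, constrained to match presence-sample feature means and
shrunk toward uniform by an L1 penalty.  Fitting minimizes the convex
objective

    J(λ) = −(1/m) Σ_presences λ·f(x_i) + log Z(λ) + Σ_j β_j |λ_j|,

with Z(λ) = Σ_background exp(λ·f(x)) and β_j = beta_multiplier · s_j/√m,
where s_j is feature j's standard deviation over the presence sample
(floored at 0.001 of the feature's training range) and m the presence count.
The optimizer is cyclic coordinate descent: each coordinate takes a
soft-threshold step on a local quadratic bound, then backtracks on the exact
one-dimensional objective.  Per-coordinate gain improvements are logged so
that training gain can later be credited to the environmental variables
(percent contribution).

Outputs: the raw distribution q (sums to 1 over the background sample) and
the logistic transform p = c·q / (1 + c·q) with c = e^H, H the entropy of
the raw distribution — the relative-suitability value in [0, 1] that all
downstream classification uses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grid_io import Grid, GridStack

ALL_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "categorical")


class DataError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Fitting knobs; defaults mirror the study configuration where stated
    (500 iterations, 10,000 background points) and standard practice
    elsewhere."""

    max_iterations: int = 500          # full coordinate cycles
    n_background: int = 10_000
    beta_multiplier: float = 1.0
    feature_classes: tuple[str, ...] = ALL_FEATURE_CLASSES
    n_hinge_knots: int = 20            # per direction, interior knots
    convergence_tol: float = 1e-5      # on gain change per full cycle
    seed: int = 0
    output: str = "logistic"           # {"raw", "logistic"}

    def __post_init__(self) -> None:
        bad = set(self.feature_classes) - set(ALL_FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")


@dataclass(frozen=True)
class Feature:
    """One basis function of the Gibbs model.

    kind ∈ {linear, quadratic, product, hinge_forward, hinge_reverse,
    categorical_indicator}; ``knot`` is in scaled [0,1] units for hinges and
    the level value for categorical indicators.
    """

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def label(self) -> str:
        v = "*".join(self.variables)
        if self.knot is None:
            return f"{self.kind}({v})"
        return f"{self.kind}({v}@{self.knot:g})"


@dataclass
class FeatureSet:
    """Feature definitions plus the training-data scaling bounds.

    Continuous variables are min-max scaled to [0,1] with bounds frozen from
    the training sample; projection data outside the bounds are clamped
    rather than extrapolated.  ``reference`` stores per-variable training
    means (continuous) and modal levels (categorical) for response curves.
    """

    features: list[Feature]
    bounds: dict[str, tuple[float, float]]
    categorical_levels: dict[str, list[float]]
    reference: dict[str, float]

    @property
    def names(self) -> list[str]:
        return [f.label for f in self.features]

    def variables(self) -> list[str]:
        out: list[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in out:
                    out.append(v)
        return out

    def scale(self, var: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[var]
        return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        """(n, n_features) matrix of feature values, all in [0,1]."""
        cols = []
        cache: dict[str, np.ndarray] = {}

        def scaled(v: str) -> np.ndarray:
            if v not in cache:
                cache[v] = self.scale(v, data[v].to_numpy())
            return cache[v]

        for f in self.features:
            if f.kind == "linear":
                cols.append(scaled(f.variables[0]))
            elif f.kind == "quadratic":
                cols.append(scaled(f.variables[0]) ** 2)
            elif f.kind == "product":
                cols.append(scaled(f.variables[0]) * scaled(f.variables[1]))
            elif f.kind == "hinge_forward":
                xs, k = scaled(f.variables[0]), f.knot
                cols.append(np.maximum(0.0, xs - k) / (1.0 - k))
            elif f.kind == "hinge_reverse":
                xs, k = scaled(f.variables[0]), f.knot
                cols.append(np.maximum(0.0, k - xs) / k)
            elif f.kind == "categorical_indicator":
                x = data[f.variables[0]].to_numpy(dtype=float)
                cols.append((x == f.knot).astype(float))
            else:  # pragma: no cover
                raise ValueError(f.kind)
        X = np.column_stack(cols) if cols else np.empty((len(data), 0))
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite feature values")
        return X


def build_features(train_values: pd.DataFrame, config: TrainConfig,
                   categorical: Sequence[str] = ()) -> FeatureSet:
    """Construct the feature basis from a training-value table.

    Continuous variables get linear + quadratic terms, pairwise products
    (when enabled), and forward/reverse hinges at ``n_hinge_knots`` evenly
    spaced interior knots of the scaled range.  Categorical variables get
    one indicator per level observed in training.  Constant variables are
    excluded with a warning.
    """
    categorical = [c for c in categorical if c in train_values.columns]
    continuous = [c for c in train_values.columns if c not in categorical]

    bounds: dict[str, tuple[float, float]] = {}
    reference: dict[str, float] = {}
    keep_cont: list[str] = []
    for v in continuous:
        x = train_values[v].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            warnings.warn(f"variable {v!r} is constant over training data; excluded")
            continue
        bounds[v] = (lo, hi)
        reference[v] = float(np.mean(x))
        keep_cont.append(v)

    levels: dict[str, list[float]] = {}
    for v in categorical:
        x = train_values[v].to_numpy(dtype=float)
        vals, counts = np.unique(x, return_counts=True)
        levels[v] = [float(u) for u in vals]
        reference[v] = float(vals[np.argmax(counts)])  # modal level

    feats: list[Feature] = []
    classes = set(config.feature_classes)
    if "linear" in classes:
        feats += [Feature("linear", (v,)) for v in keep_cont]
    if "quadratic" in classes:
        feats += [Feature("quadratic", (v,)) for v in keep_cont]
    if "product" in classes:
        for i, a in enumerate(keep_cont):
            for b in keep_cont[i + 1:]:
                feats.append(Feature("product", (a, b)))
    if "hinge" in classes and config.n_hinge_knots > 0:
        knots = np.linspace(0.0, 1.0, config.n_hinge_knots + 2)[1:-1]
        for v in keep_cont:
            feats += [Feature("hinge_forward", (v,), float(k)) for k in knots]
            feats += [Feature("hinge_reverse", (v,), float(k)) for k in knots]
    if "categorical" in classes:
        for v in categorical:
            feats += [Feature("categorical_indicator", (v,), lv) for lv in levels[v]]

    return FeatureSet(feats, bounds, levels, reference)


@dataclass
class MaxentModel:
    """Fitted Gibbs model: weights λ, normalizer Z, background entropy H."""

    feature_set: FeatureSet
    lam: np.ndarray
    log_z: float
    entropy: float
    n_background: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    config: TrainConfig = field(default_factory=TrainConfig)
    gain: float = 0.0

    # -- outputs -------------------------------------------------------------

    def raw_from_design(self, X: np.ndarray) -> np.ndarray:
        return np.exp(X @ self.lam - self.log_z)

    def raw_output(self, data: pd.DataFrame) -> np.ndarray:
        """Gibbs probability q(x) = exp(λ·f(x)) / Z."""
        return self.raw_from_design(self.feature_set.design_matrix(data))

    def logistic_from_raw(self, q: np.ndarray) -> np.ndarray:
        cq = np.exp(self.entropy) * np.asarray(q, dtype=float)
        return cq / (1.0 + cq)

    def logistic_output(self, data: pd.DataFrame) -> np.ndarray:
        """Relative suitability p = c·q/(1+c·q), c = e^H."""
        return self.logistic_from_raw(self.raw_output(data))

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        q = self.raw_output(data)
        return q if self.config.output == "raw" else self.logistic_from_raw(q)

    # -- persistence ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "lambda": self.lam.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "n_background": self.n_background,
            "config": asdict(self.config),
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "knot": f.knot}
                for f in self.feature_set.features
            ],
            "bounds": {k: list(v) for k, v in self.feature_set.bounds.items()},
            "categorical_levels": self.feature_set.categorical_levels,
            "reference": self.feature_set.reference,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        doc = json.loads(Path(path).read_text())
        cfg = doc["config"]
        cfg["feature_classes"] = tuple(cfg["feature_classes"])
        fs = FeatureSet(
            [Feature(f["kind"], tuple(f["variables"]), f["knot"]) for f in doc["features"]],
            {k: (v[0], v[1]) for k, v in doc["bounds"].items()},
            doc["categorical_levels"],
            doc["reference"],
        )
        return cls(fs, np.asarray(doc["lambda"]), doc["log_z"], doc["entropy"],
                   doc["n_background"], [], TrainConfig(**cfg), doc["gain"])


# -- background sampling -----------------------------------------------------

def sample_background(stack: GridStack, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of n valid cells, without replacement.

    If n exceeds the number of valid cells, every valid cell is used once
    (with a warning).  Returns the same columns as ``GridStack.table``.
    """
    table = stack.table()
    if len(table) == 0:
        raise DataError("no valid (non-nodata) cells to sample from")
    if n >= len(table):
        if n > len(table):
            warnings.warn(
                f"requested {n} background points but only {len(table)} valid cells; using all"
            )
        return table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    return table.iloc[np.sort(idx)].reset_index(drop=True)


# -- fitting -----------------------------------------------------------------

def regularization_weights(X_pres: np.ndarray, X_bg: np.ndarray,
                           beta_multiplier: float) -> np.ndarray:
    """β_j = multiplier · s_j/√m, s_j floored at 0.001 of the training range."""
    m = X_pres.shape[0]
    s = X_pres.std(axis=0, ddof=0)
    allx = np.vstack([X_pres, X_bg])
    rng_j = allx.max(axis=0) - allx.min(axis=0)
    floor = 0.001 * np.maximum(rng_j, 1e-12)
    return beta_multiplier * np.maximum(s, floor) / np.sqrt(m)


def fit_maxent(presence_features: np.ndarray, background_features: np.ndarray,
               config: TrainConfig | None = None,
               feature_set: FeatureSet | None = None) -> MaxentModel:
    """Fit λ by cyclic coordinate descent with soft-threshold steps.

    The trace logs (feature index, gain improvement) per accepted update;
    training gain = log N − J(λ) is non-decreasing over cycles and the raw
    distribution stays normalized throughout.
    """
    config = config or TrainConfig()
    X_p = np.asarray(presence_features, dtype=float)
    X_b = np.asarray(background_features, dtype=float)
    if not (np.all(np.isfinite(X_p)) and np.all(np.isfinite(X_b))):
        raise DataError("non-finite feature values")
    if X_p.shape[0] < 2:
        raise DataError("need at least 2 presence points")
    m, n_feat = X_p.shape
    N = X_b.shape[0]

    pbar = X_p.mean(axis=0)
    beta = regularization_weights(X_p, X_b, config.beta_multiplier)

    lam = np.zeros(n_feat)
    s = np.zeros(N)                     # λ·f(x) per background point
    log_z = np.log(N)
    obj = log_z                          # J at λ = 0
    trace: list[tuple[int, float]] = []

    for _cycle in range(config.max_iterations):
        cycle_gain = 0.0
        for j in range(n_feat):
            xj = X_b[:, j]
            w = np.exp(s - log_z)        # current q over background
            ej = float(w @ xj)
            grad = -pbar[j] + ej
            var = float(w @ (xj * xj)) - ej * ej
            h = max(var, 1e-12)
            # soft-threshold on the local quadratic model
            z = h * lam[j] - grad
            new_lam = np.sign(z) * max(abs(z) - beta[j], 0.0) / h
            delta = new_lam - lam[j]
            if abs(delta) < 1e-15:
                continue
            # backtrack on the exact 1-D objective until it decreases
            improved = False
            for _ in range(40):
                with np.errstate(over="ignore"):
                    d_logz = float(logsumexp(s + delta * xj)) - log_z
                d_obj = (-pbar[j] * delta + d_logz
                         + beta[j] * (abs(lam[j] + delta) - abs(lam[j])))
                if np.isfinite(d_obj) and d_obj <= 0.0:
                    improved = True
                    break
                delta *= 0.5
            if not improved or d_obj == 0.0:
                continue
            lam[j] += delta
            s = s + delta * xj
            log_z += d_logz
            obj += d_obj
            cycle_gain += -d_obj
            trace.append((j, -d_obj))
        # periodic renormalization guards drift in the running log Z
        log_z_exact = float(logsumexp(s))
        obj += log_z_exact - log_z
        log_z = log_z_exact
        if cycle_gain < config.convergence_tol:
            break

    w = np.exp(s - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(w * np.where(w > 0, np.log(w), 0.0)).sum())
    gain = float(np.log(N) - obj)
    model = MaxentModel(
        feature_set or _anonymous_feature_set(n_feat),
        lam, float(log_z), entropy, N, trace, config, gain,
    )
    return model


def _anonymous_feature_set(n_feat: int) -> FeatureSet:
    """Placeholder definitions for fits driven by raw design matrices."""
    feats = [Feature("linear", (f"f{j}",)) for j in range(n_feat)]
    return FeatureSet(feats, {f"f{j}": (0.0, 1.0) for j in range(n_feat)}, {}, {})


# -- interpretation ----------------------------------------------------------

def _variable_shares(feature: Feature) -> dict[str, float]:
    if feature.kind == "product":
        a, b = feature.variables
        return {a: 0.5, b: 0.5}
    return {feature.variables[0]: 1.0}


def percent_contribution(model: MaxentModel) -> pd.Series:
    """Credit each variable with its share of the training-gain improvements
    accrued during coordinate descent; normalized to sum to 100."""
    feats = model.feature_set.features
    acc: dict[str, float] = {v: 0.0 for v in model.feature_set.variables()}
    for j, dg in model.trace:
        for v, share in _variable_shares(feats[j]).items():
            acc[v] += share * dg
    for v in acc:
        acc[v] = max(acc[v], 0.0)
    total = sum(acc.values())
    if total <= 0:
        return pd.Series({v: 0.0 for v in acc})
    return pd.Series({v: 100.0 * g / total for v, g in acc.items()}).sort_values(
        ascending=False)


def jackknife_importance(presence_values: pd.DataFrame,
                         background_values: pd.DataFrame,
                         variables: Sequence[str],
                         config: TrainConfig,
                         categorical: Sequence[str] = (),
                         test_presence_values: pd.DataFrame | None = None,
                         ) -> pd.DataFrame:
    """With-only and without-each-variable refits.

    Returns one row per variable with the regularized training gain of the
    only-v and all-but-v models and their presence-background test AUC
    (computed on ``test_presence_values`` when given, else on the training
    presences).  The full model's gain is attached as ``full_gain``.
    """
    from .evaluation import auc_presence_background

    variables = list(variables)
    if len(variables) < 2:
        raise DataError("jackknife needs at least 2 variables")

    def fit_on(cols: list[str]):
        fs = build_features(
            pd.concat([presence_values[cols], background_values[cols]],
                      ignore_index=True),
            config, categorical=[c for c in categorical if c in cols])
        Xp = fs.design_matrix(presence_values[cols])
        Xb = fs.design_matrix(background_values[cols])
        model = fit_maxent(Xp, Xb, config, feature_set=fs)
        test = test_presence_values if test_presence_values is not None \
            else presence_values
        auc = auc_presence_background(
            model.logistic_output(test[cols]),
            model.logistic_output(background_values[cols]))
        return model.gain, auc

    full_gain, full_auc = fit_on(variables)
    rows = []
    for v in variables:
        gain_only, auc_only = fit_on([v])
        rest = [u for u in variables if u != v]
        gain_without, auc_without = fit_on(rest)
        rows.append({
            "variable": v, "gain_only": gain_only, "auc_only": auc_only,
            "gain_without": gain_without, "auc_without": auc_without,
            "full_gain": full_gain, "full_auc": full_auc,
        })
    return pd.DataFrame(rows).set_index("variable")


def response_curve(model: MaxentModel, variable: str, n_steps: int = 100,
                   ) -> pd.DataFrame:
    """Marginal response: sweep one variable over its training range with
    every other variable pinned at its background mean (categorical at the
    modal level).  Categorical targets get one row per level instead."""
    fs = model.feature_set
    others = {v: fs.reference[v] for v in fs.variables() if v != variable}
    if variable in fs.categorical_levels:
        sweep = np.asarray(fs.categorical_levels[variable], dtype=float)
    else:
        lo, hi = fs.bounds[variable]
        sweep = np.linspace(lo, hi, n_steps)
    data = pd.DataFrame({variable: sweep})
    for v, val in others.items():
        data[v] = val
    return pd.DataFrame({"value": sweep, "p": model.predict(data)})


def averaged_response_curves(models: Sequence[MaxentModel], variable: str,
                             n_steps: int = 100) -> pd.DataFrame:
    """Replicate-averaged marginal response: the sweep of the first model's
    training range evaluated under every model, reported as mean and SD."""
    if not models:
        raise ValueError("need at least one model")
    base = response_curve(models[0], variable, n_steps)
    sweep = base["value"].to_numpy()
    curves = [base["p"].to_numpy()]
    for m in models[1:]:
        fs = m.feature_set
        data = pd.DataFrame({variable: sweep})
        for v in fs.variables():
            if v != variable:
                data[v] = fs.reference[v]
        curves.append(m.predict(data))
    arr = np.vstack(curves)
    return pd.DataFrame({"value": sweep, "p_mean": arr.mean(axis=0),
                         "p_sd": arr.std(axis=0, ddof=1) if len(models) > 1
                         else np.zeros(len(sweep))})


def predict_grid(model: MaxentModel, stack: GridStack) -> Grid:
    """Logistic (or raw, per config) suitability over every valid cell."""
    table = stack.table()
    p = model.predict(table)
    ref = stack.grid
    out = np.full((ref.nrows, ref.ncols), ref.nodata_value)
    out[table["row"].to_numpy(), table["col"].to_numpy()] = p
    return ref.copy_with(out)
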