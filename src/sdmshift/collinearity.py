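"""Pearson correlation screening of continuous predictors.

Highly correlated environmental layers destabilize variable-importance
readings, so predictors with |r| above a threshold (0.8 by default) are
greedily eliminated before model fitting.  Categorical layers bypass the
filter — Pearson r is meaningless for unordered levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray
    undefined: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.names)
        if self.r.shape != (k, k):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(self.r, self.r.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix not symmetric")
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise ValueError("|r| > 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


def pearson_matrix(samples: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations over a complete-case sample.

    Zero-variance variables get NaN correlations and are reported in
    ``undefined`` rather than silently contributing zeros.
    """
    df = samples.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete sample points")
    names = list(df.columns)
    x = df.to_numpy(dtype=float)
    std = x.std(axis=0)
    undefined = {names[j] for j in np.nonzero(std == 0)[0]}
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    for j, name in enumerate(names):
        if name in undefined:
            r[j, :] = np.nan
            r[:, j] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(names, r, undefined)


def greedy_filter(cm: CorrelationMatrix, threshold: float = 0.8,
                  keep_priority: list[str] | None = None) -> list[str]:
    """Drop variables until no retained pair has |r| > threshold.

    Violating pairs are resolved worst-first.  The dropped member is the
    lower-priority one if ``keep_priority`` is given (absent names rank
    below all listed ones); otherwise the member with the larger mean |r|
    against all other retained variables, ties broken lexicographically.
    The strict inequality means |r| equal to the threshold is retained.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    names = list(cm.names)
    rank = {n: i for i, n in enumerate(keep_priority or [])}
    retained = list(names)

    def absr(a: str, b: str) -> float:
        v = cm.r[names.index(a), names.index(b)]
        return abs(v) if np.isfinite(v) else 0.0

    while True:
        pairs = [(a, b) for a, b in combinations(retained, 2) if absr(a, b) > threshold]
        if not pairs:
            return retained
        worst = max(pairs, key=lambda p: (absr(*p), tuple(sorted(p))))
        a, b = sorted(worst)
        if keep_priority is not None and (a in rank or b in rank):
            drop = a if rank.get(a, len(rank)) > rank.get(b, len(rank)) else b
        else:
            def mean_abs(v: str) -> float:
                others = [o for o in names if o != v]
                return float(np.mean([absr(v, o) for o in others])) if others else 0.0
            ma, mb = mean_abs(a), mean_abs(b)
            if ma > mb:
                drop = a
            elif mb > ma:
                drop = b
            else:
                drop = max(a, b)  # lexicographic tie-break: drop the later name
        retained.remove(drop)
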