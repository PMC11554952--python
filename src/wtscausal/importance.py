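"""Raw per-method feature-importance scores.

Five base scorers are provided, matching the common ensemble of filter,
embedded and resampling methods for regression targets:

- ``pearson``    : absolute Pearson correlation with the target,
- ``distance``   : sample distance correlation with the target,
- ``lasso``      : absolute lasso coefficients at a cross-validated penalty,
- ``rf``         : random-forest permutation importance (mean decrease in
                   accuracy), negatives clipped to zero,
- ``stability``  : stability selection — the fraction of half-subsamples in
                   which the feature enters the lasso support.

All scorers return nonnegative rows so the downstream min-max
normalisation treats "strongly anticorrelated" as important.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LassoCV

from .dataset import Dataset, require_nonconstant


@dataclass(frozen=True)
class ImportanceTable:
    """Raw importance scores, one row per method, one column per feature.

    All entries are finite and nonnegative; signed raw scores (correlations,
    regression coefficients) are stored as magnitudes.
    """

    scores: np.ndarray
    method_names: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.method_names), len(self.feature_names)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.method_names)} methods x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("importance scores must be finite")
        if np.any(scores < 0):
            raise ValueError("importance scores must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.method_names, columns=self.feature_names)


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation between two 1-D variables.

    Double-centres the pairwise Euclidean distance matrices of ``x`` and
    ``y`` and returns ``sqrt(dCov^2 / sqrt(dVar_x * dVar_y))``, the biased
    V-statistic estimator. Zero when either variable is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    denom = np.sqrt(dvarx * dvary)
    if denom <= 0.0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def score_pearson(data: Dataset) -> np.ndarray:
    """|Pearson r| of each feature with the target, in [0, 1]."""
    require_nonconstant(data.y, data.target_name)
    out = np.empty(data.n_features)
    for j, name in enumerate(data.feature_names):
        col = data.X[:, j]
        require_nonconstant(col, name)
        out[j] = abs(stats.pearsonr(col, data.y).statistic)
    return out


def score_distance_correlation(data: Dataset) -> np.ndarray:
    """Distance correlation of each feature with the target, in [0, 1]."""
    require_nonconstant(data.y, data.target_name)
    out = np.empty(data.n_features)
    for j, name in enumerate(data.feature_names):
        col = data.X[:, j]
        require_nonconstant(col, name)
        out[j] = distance_correlation(col, data.y)
    return out


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def score_lasso(data: Dataset, seed: int = 0) -> np.ndarray:
    """|lasso coefficient| per feature at a cross-validated penalty.

    Features are standardised internally so the penalty acts evenly;
    irrelevant features shrink to exactly zero.
    """
    X = _standardize(data.X)
    y = data.y - data.y.mean()
    model = LassoCV(cv=5, random_state=seed, alphas=50, max_iter=5000)
    model.fit(X, y)
    return np.abs(model.coef_)


def score_rf_mda(
    data: Dataset,
    seed: int = 0,
    n_estimators: int = 100,
    n_repeats: int = 10,
) -> np.ndarray:
    """Random-forest permutation importance (mean decrease in accuracy).

    A forest is fit on the full data and each feature column is permuted
    ``n_repeats`` times; the mean drop in R^2 is the score. Negative drops
    (feature no better than noise) are clipped to zero.
    """
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    rf.fit(data.X, data.y)
    perm = permutation_importance(
        rf, data.X, data.y, n_repeats=n_repeats, random_state=seed
    )
    return np.clip(perm.importances_mean, 0.0, None)


def score_stability(
    data: Dataset,
    seed: int = 0,
    n_subsamples: int = 100,
) -> np.ndarray:
    """Stability-selection frequency per feature, in [0, 1].

    The lasso penalty is chosen once by cross-validation on the full data;
    the model is then refit on ``n_subsamples`` random half-subsamples and
    each feature's score is the fraction of fits in which its coefficient
    is nonzero.
    """
    if data.n_samples < 10:
        raise ValueError("stability selection needs at least 10 samples")
    rng = np.random.default_rng(seed)
    X = _standardize(data.X)
    y = data.y - data.y.mean()
    alpha = LassoCV(cv=5, random_state=seed, alphas=50, max_iter=5000).fit(X, y).alpha_
    half = data.n_samples // 2
    counts = np.zeros(data.n_features)
    for _ in range(n_subsamples):
        idx = rng.choice(data.n_samples, size=half, replace=False)
        m = Lasso(alpha=alpha, max_iter=5000).fit(X[idx], y[idx])
        counts += m.coef_ != 0.0
    return counts / n_subsamples


SCORERS = {
    "pearson": lambda data, seed: score_pearson(data),
    "distance": lambda data, seed: score_distance_correlation(data),
    "lasso": lambda data, seed: score_lasso(data, seed),
    "rf": lambda data, seed: score_rf_mda(data, seed),
    "stability": lambda data, seed: score_stability(data, seed),
}

DEFAULT_METHODS = list(SCORERS)


def build_importance_table(
    data: Dataset,
    methods: list[str] | None = None,
    seed: int = 0,
) -> ImportanceTable:
    """Stack the requested scorers' rows into an ImportanceTable.

    ``methods`` must be a nonempty subset of ``SCORERS``; rows appear in the
    requested order. The same base seed is passed to every stochastic
    scorer, so repeated calls are bitwise identical.
    """
    methods = list(methods) if methods is not None else list(DEFAULT_METHODS)
    if not methods:
        raise ValueError("need at least one method")
    unknown = [m for m in methods if m not in SCORERS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; available: {list(SCORERS)}")
    rows = [SCORERS[m](data, seed) for m in methods]
    return ImportanceTable(
        scores=np.vstack(rows), method_names=methods, feature_names=list(data.feature_names)
    )
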