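"""Validated container for a numeric regression table (features plus one target)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Dataset:
    """A numeric design matrix ``X`` with a regression target ``y``.

    Parameters
    ----------
    X : ndarray of shape (n_samples, p_features)
        Feature matrix; must be finite.
    y : ndarray of shape (n_samples,)
        Target vector; must be finite.
    feature_names : list of str
        Unique names, one per column of ``X``.
    target_name : str
        Name of the target variable; must not collide with a feature name.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    target_name: str = "target"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        n, p = X.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if p < 1:
            raise ValueError("need at least one feature")
        if y.shape[0] != n:
            raise ValueError(f"y has {y.shape[0]} rows, X has {n}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite (no NaN/inf)")
        names = list(self.feature_names) or [f"x{j}" for j in range(p)]
        object.__setattr__(self, "feature_names", names)
        if len(names) != p:
            raise ValueError(f"{len(names)} feature names for {p} columns")
        if len(set(names)) != p:
            raise ValueError("feature names must be unique")
        if self.target_name in names:
            raise ValueError(f"target name {self.target_name!r} collides with a feature")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return the feature column with the given name."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.X[:, j]

    def subset(self, names: list[str]) -> np.ndarray:
        """Return the columns of the named features, in the given order."""
        idx = [self.feature_names.index(n) if n in self.feature_names else -1 for n in names]
        missing = [n for n, i in zip(names, idx) if i < 0]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return self.X[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[self.target_name] = self.y
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str) -> "Dataset":
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not in data ({list(df.columns)})")
        feats = [c for c in df.columns if c != target]
        return cls(
            X=df[feats].to_numpy(dtype=float),
            y=df[target].to_numpy(dtype=float),
            feature_names=feats,
            target_name=target,
        )

    @classmethod
    def from_csv(cls, path, target: str) -> "Dataset":
        return cls.from_dataframe(pd.read_csv(path), target)


def require_nonconstant(values: np.ndarray, name: str) -> None:
    """Raise if a column has (numerically) zero variance."""
    if np.ptp(values) == 0.0:
        raise ValueError(f"column {name!r} is constant (zero variance)")


def minmax_scale(a: np.ndarray) -> np.ndarray:
    """Rescale each column of ``a`` to [0, 1]; constant columns map to 0."""
    a = np.asarray(a, dtype=float)
    lo = a.min(axis=0)
    span = a.max(axis=0) - lo
    span = np.where(span == 0.0, 1.0, span)
    return (a - lo) / span
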