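"""Weighted Total Score: min-max normalisation, exponential aggregation, top-k selection.

Each method's raw importance row is min-max scaled to [0, 1]; a weight
vector ``W`` on the probability simplex then aggregates the methods as

    WTS_j = sum_i W_i * exp(F~_ij)

so every feature's score lies in [1, e]. The exponential map widens small
gaps near the top of each method's ranking before the weighted average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .importance import ImportanceTable

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class NormalizedTable:
    """Per-row min-max normalised importance scores, entries in [0, 1]."""

    tilde_scores: np.ndarray
    method_names: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.tilde_scores, dtype=float))
        object.__setattr__(self, "tilde_scores", t)
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("normalised scores must lie in [0, 1]")


@dataclass(frozen=True)
class WTSRanking:
    """WTS values with a deterministic descending order.

    ``order[r]`` is the feature index at rank ``r``; ties are broken by
    original column position (stable sort).
    """

    wts: np.ndarray
    order: np.ndarray
    feature_names: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [self.feature_names[j] for j in self.order],
                "wts": self.wts[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def check_weights(w: np.ndarray, n_methods: int | None = None) -> np.ndarray:
    """Validate a simplex weight vector (nonnegative, sums to 1)."""
    w = np.asarray(w, dtype=float).ravel()
    if n_methods is not None and w.shape[0] != n_methods:
        raise ValueError(f"expected {n_methods} weights, got {w.shape[0]}")
    if np.any(w < -WEIGHT_TOL):
        raise ValueError(f"weights must be nonnegative, got {w}")
    if abs(w.sum() - 1.0) > WEIGHT_TOL:
        raise ValueError(f"weights must sum to 1, got sum {w.sum()!r}")
    return np.clip(w, 0.0, None)


def normalize(table: ImportanceTable) -> NormalizedTable:
    """Min-max scale each method's row to [0, 1].

    A constant row carries no ranking information; it is mapped to all
    zeros (every feature then receives the same contribution ``W_i * 1``)
    and a warning is emitted.
    """
    raw = table.scores
    if not np.all(np.isfinite(raw)):
        raise ValueError("importance scores must be finite")
    lo = raw.min(axis=1, keepdims=True)
    span = raw.max(axis=1, keepdims=True) - lo
    flat = span.ravel() == 0.0
    if np.any(flat):
        names = [table.method_names[i] for i in np.flatnonzero(flat)]
        warnings.warn(
            f"constant importance rows mapped to zeros: {names}", stacklevel=2
        )
    safe_span = np.where(span == 0.0, 1.0, span)
    tilde = (raw - lo) / safe_span
    return NormalizedTable(
        tilde_scores=tilde,
        method_names=list(table.method_names),
        feature_names=list(table.feature_names),
    )


def compute_wts(normed: NormalizedTable, w: np.ndarray) -> WTSRanking:
    """Aggregate normalised scores into per-feature WTS values and rank them."""
    w = check_weights(w, len(normed.method_names))
    wts = w @ np.exp(normed.tilde_scores)
    order = np.argsort(-wts, kind="stable")
    return WTSRanking(wts=wts, order=order, feature_names=list(normed.feature_names))


def select_top_k(ranking: WTSRanking, k: int) -> list[str]:
    """The first ``k`` feature names of the ranking, in rank order."""
    p = len(ranking.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return [ranking.feature_names[j] for j in ranking.order[:k]]
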