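"""Multicollinearity screening: Spearman correlations and iterative VIF pruning.

The variance inflation factor of feature j within a subset is
``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from regressing feature j
on the other subset features (with intercept). Values above ~10 flag
serious multicollinearity; pruning repeatedly removes the worst offender
and recomputes until all survivors pass. VIF is invariant to affine
rescaling of the columns, so it is computed on the data as loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset, require_nonconstant

_PERFECT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class VifReport:
    """Outcome of iterative VIF pruning."""

    surviving: list[str]
    vifs: dict[str, float]
    removal_trace: list[tuple[str, float]] = field(default_factory=list)
    threshold: float = 10.0


def spearman_matrix(data: Dataset, subset: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations among the named features."""
    subset = list(subset) if subset is not None else list(data.feature_names)
    if len(subset) < 2:
        raise ValueError("need at least two features for a correlation matrix")
    X = data.subset(subset)
    for j, name in enumerate(subset):
        require_nonconstant(X[:, j], name)
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-feature case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=subset, columns=subset)


def compute_vif(data: Dataset, subset: list[str]) -> dict[str, float]:
    """VIF of every feature in the subset, via per-feature OLS R^2.

    Perfectly collinear features get ``inf`` rather than an exception, so
    the pruning loop can remove them.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("VIF needs at least two features")
    X = data.subset(subset)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than features ({p}) for VIF")
    out: dict[str, float] = {}
    for j, name in enumerate(subset):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0.0:
            raise ValueError(f"column {name!r} is constant (zero variance)")
        one_minus_r2 = np.sum(resid**2) / ss_tot
        out[name] = float("inf") if one_minus_r2 < _PERFECT_FIT_TOL else float(1.0 / one_minus_r2)
    return out


def prune_by_vif(data: Dataset, subset: list[str], threshold: float = 10.0) -> VifReport:
    """Iteratively drop the highest-VIF feature until all VIFs <= threshold.

    Ties in the maximum VIF are broken by original column order. Stops when
    only one feature remains (a single feature has no VIF).
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    remaining = list(subset)
    trace: list[tuple[str, float]] = []
    while len(remaining) >= 2:
        vifs = compute_vif(data, remaining)
        worst = max(remaining, key=lambda f: vifs[f])  # first max wins ties
        if vifs[worst] <= threshold:
            return VifReport(
                surviving=remaining, vifs=vifs, removal_trace=trace, threshold=threshold
            )
        trace.append((worst, vifs[worst]))
        remaining.remove(worst)
    return VifReport(surviving=remaining, vifs={}, removal_trace=trace, threshold=threshold)
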