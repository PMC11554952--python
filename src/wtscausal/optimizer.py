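"""Greedy search over method weights and feature count.

The weight simplex is discretised with step ``delta`` (``1/delta`` must be
an integer, so every lattice point is an integer combination of delta
units). For each candidate feature count ``k`` the search starts at equal
weights, ranks features by WTS, evaluates the induced top-k subset with
seeded cross-validated linear regression, and hill-climbs over single-unit
weight transfers, accepting a move only when it improves (lower MSE, then
higher R^2). Subset evaluations are memoized, since many weight vectors
induce the same top-k subset.

The global winner over all ``k`` is chosen by (MSE asc, R^2 desc, k asc,
lexicographically smallest weights) — a total preorder, so the result is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, cross_val_predict

from .dataset import Dataset, minmax_scale
from .importance import ImportanceTable
from .wts import NormalizedTable, check_weights, compute_wts, normalize, select_top_k


@dataclass(frozen=True)
class OptimizerConfig:
    """Search and evaluation settings.

    delta : weight lattice step; 1/delta must be an integer.
    max_iter : cap on accepted hill-climb moves per (k, start).
    k_range : inclusive (lo, hi) interval of feature counts; None = [1, p].
    seed : controls CV fold shuffling and any stochastic scorer.
    cv_folds : folds for the evaluation protocol.
    scale_target : min-max scale y to [0, 1] before evaluation (features
        are always scaled); keeps MSE on a comparable unitless scale.
    n_restarts : extra seeded random lattice starts per k, beyond the
        equal-weight start.
    """

    delta: float = 0.1
    max_iter: int = 1000
    k_range: tuple[int, int] | None = None
    seed: int = 0
    cv_folds: int = 5
    scale_target: bool = True
    n_restarts: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        units = 1.0 / self.delta
        if abs(units - round(units)) > 1e-9:
            raise ValueError(f"1/delta must be an integer, got 1/{self.delta}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.k_range is not None:
            lo, hi = self.k_range
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid k_range {self.k_range}")

    @property
    def n_units(self) -> int:
        return round(1.0 / self.delta)


@dataclass(frozen=True)
class MetricSet:
    """Cross-validated regression metrics on min-max-scaled data."""

    mse: float
    rmse: float
    mae: float
    r2: float
    ev: float

    def as_dict(self) -> dict[str, float]:
        return {"mse": self.mse, "rmse": self.rmse, "mae": self.mae, "r2": self.r2, "ev": self.ev}


@dataclass
class EvalCache:
    """Memo of subset evaluations keyed by the sorted feature-name tuple."""

    store: dict[tuple[str, ...], MetricSet] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def key(self, subset: list[str]) -> tuple[str, ...]:
        return tuple(sorted(subset))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the weight/feature-count search."""

    w_star: np.ndarray
    k_star: int
    selected: list[str]
    metrics: MetricSet
    method_names: list[str]
    iterations_used: int
    cache_hits: int
    n_evaluations: int


def metrics_from_predictions(y: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """All five metrics from out-of-fold predictions."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    resid = y - y_pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    var_y = float(np.var(y))
    ev = 1.0 - float(np.var(resid)) / var_y if var_y > 0 else 0.0
    return MetricSet(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(resid))),
        r2=r2,
        ev=ev,
    )


def evaluate_subset(
    data: Dataset,
    subset: list[str],
    config: OptimizerConfig,
    cache: EvalCache | None = None,
) -> MetricSet:
    """Seeded k-fold CV linear regression of scaled y on the scaled subset.

    Results are cached under the canonical (sorted) subset key; repeated
    calls return the stored MetricSet without refitting.
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    if cache is not None:
        key = cache.key(subset)
        if key in cache.store:
            cache.hits += 1
            return cache.store[key]
    X = minmax_scale(data.subset(sorted(subset)))
    y = minmax_scale(data.y[:, None]).ravel() if config.scale_target else data.y
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    y_pred = cross_val_predict(LinearRegression(), X, y, cv=kf)
    result = metrics_from_predictions(y, y_pred)
    if cache is not None:
        cache.store[cache.key(subset)] = result
        cache.misses += 1
    return result


def _units_to_weights(units: tuple[int, ...], n_units: int) -> np.ndarray:
    return np.asarray(units, dtype=float) / n_units


def equal_weight_start(n_methods: int, n_units: int) -> tuple[int, ...]:
    """The lattice point closest to equal weights.

    When ``n_methods`` divides ``n_units`` this is exactly equal weights;
    otherwise the remainder units go to the first methods in order.
    """
    base, rem = divmod(n_units, n_methods)
    return tuple(base + (1 if i < rem else 0) for i in range(n_methods))


def enumerate_weight_moves(w: np.ndarray, delta: float) -> list[np.ndarray]:
    """All neighbours reached by moving one delta unit between two methods.

    Weights stay nonnegative and keep summing to 1. Neighbours are listed
    in a fixed (donor, recipient) order for determinism.
    """
    w = check_weights(w)
    n_units = round(1.0 / delta)
    units = tuple(int(round(x * n_units)) for x in w)
    moves = []
    for i, ui in enumerate(units):
        if ui == 0:
            continue
        for j in range(len(units)):
            if i == j:
                continue
            nb = list(units)
            nb[i] -= 1
            nb[j] += 1
            moves.append(_units_to_weights(tuple(nb), n_units))
    return moves


def _unit_neighbors(units: tuple[int, ...]) -> list[tuple[int, ...]]:
    out = []
    for i, ui in enumerate(units):
        if ui == 0:
            continue
        for j in range(len(units)):
            if i == j:
                continue
            nb = list(units)
            nb[i] -= 1
            nb[j] += 1
            out.append(tuple(nb))
    return out


def _enumerate_lattice(n_methods: int, n_units: int) -> list[tuple[int, ...]]:
    """Every composition of n_units into n_methods nonnegative parts."""
    if n_methods == 1:
        return [(n_units,)]
    out = []
    for first in range(n_units + 1):
        for rest in _enumerate_lattice(n_methods - 1, n_units - first):
            out.append((first,) + rest)
    return out


def result_key(metrics: MetricSet, k: int, units: tuple[int, ...]):
    """Total preorder: MSE asc, R^2 desc, k asc, lexicographic weights."""
    return (metrics.mse, -metrics.r2, k, units)


def _eval_point(
    data: Dataset,
    normed: NormalizedTable,
    units: tuple[int, ...],
    k: int,
    config: OptimizerConfig,
    cache: EvalCache,
) -> tuple[MetricSet, list[str]]:
    w = _units_to_weights(units, config.n_units)
    subset = select_top_k(compute_wts(normed, w), k)
    return evaluate_subset(data, subset, config, cache), subset


def _resolve_k_range(config: OptimizerConfig, p: int) -> range:
    lo, hi = config.k_range if config.k_range is not None else (1, p)
    if hi > p:
        raise ValueError(f"k_range upper bound {hi} exceeds {p} features")
    return range(lo, hi + 1)


def optimize(
    data: Dataset,
    table: ImportanceTable,
    config: OptimizerConfig | None = None,
    cache: EvalCache | None = None,
) -> SelectionResult:
    """Greedy weight search nested in a loop over the feature count.

    For each ``k`` the hill-climb starts at the equal-weight lattice point
    (plus ``n_restarts`` seeded random lattice starts) and repeatedly takes
    the best strictly-improving single-unit transfer, stopping at a local
    optimum or after ``max_iter`` accepted moves. The returned result is
    the best (weights, k) pair seen anywhere, so it can never be worse than
    the equal-weight start at any k.
    """
    config = config or OptimizerConfig()
    if list(table.feature_names) != list(data.feature_names):
        raise ValueError("importance table and dataset feature names differ")
    cache = cache if cache is not None else EvalCache()
    normed = normalize(table)
    n_methods = len(table.method_names)
    rng = np.random.default_rng(config.seed)

    best = None  # (key, units, k, subset, metrics)
    total_iters = 0
    for k in _resolve_k_range(config, data.n_features):
        starts = [equal_weight_start(n_methods, config.n_units)]
        for _ in range(config.n_restarts):
            # random composition of n_units into n_methods parts
            cuts = np.sort(rng.integers(0, config.n_units + 1, size=n_methods - 1))
            parts = np.diff(np.concatenate(([0], cuts, [config.n_units])))
            starts.append(tuple(int(x) for x in parts))
        for start in starts:
            units = start
            metrics, subset = _eval_point(data, normed, units, k, config, cache)
            key = result_key(metrics, k, units)
            if best is None or key < best[0]:
                best = (key, units, k, subset, metrics)
            for _ in range(config.max_iter):
                candidates = []
                for nb in _unit_neighbors(units):
                    m_nb, s_nb = _eval_point(data, normed, nb, k, config, cache)
                    candidates.append((result_key(m_nb, k, nb), nb, s_nb, m_nb))
                candidates.sort(key=lambda c: c[0])
                cur_key = result_key(metrics, k, units)
                if not candidates or candidates[0][0] >= cur_key:
                    break  # local optimum
                _, units, subset, metrics = candidates[0]
                total_iters += 1
                key = result_key(metrics, k, units)
                if key < best[0]:
                    best = (key, units, k, subset, metrics)

    _, units, k_star, subset, metrics = best
    return SelectionResult(
        w_star=_units_to_weights(units, config.n_units),
        k_star=k_star,
        selected=subset,
        metrics=metrics,
        method_names=list(table.method_names),
        iterations_used=total_iters,
        cache_hits=cache.hits,
        n_evaluations=cache.misses,
    )


def exhaustive_search(
    data: Dataset,
    table: ImportanceTable,
    config: OptimizerConfig | None = None,
    cache: EvalCache | None = None,
) -> SelectionResult:
    """Evaluate every lattice point at every k; the brute-force oracle.

    Only practical for small lattices (few methods, coarse delta).
    """
    config = config or OptimizerConfig()
    if list(table.feature_names) != list(data.feature_names):
        raise ValueError("importance table and dataset feature names differ")
    cache = cache if cache is not None else EvalCache()
    normed = normalize(table)
    n_methods = len(table.method_names)
    lattice = _enumerate_lattice(n_methods, config.n_units)

    best = None
    for k in _resolve_k_range(config, data.n_features):
        for units in lattice:
            metrics, subset = _eval_point(data, normed, units, k, config, cache)
            key = result_key(metrics, k, units)
            if best is None or key < best[0]:
                best = (key, units, k, subset, metrics)
    _, units, k_star, subset, metrics = best
    return SelectionResult(
        w_star=_units_to_weights(units, config.n_units),
        k_star=k_star,
        selected=subset,
        metrics=metrics,
        method_names=list(table.method_names),
        iterations_used=0,
        cache_hits=cache.hits,
        n_evaluations=cache.misses,
    )


def baseline_results(
    data: Dataset,
    table: ImportanceTable,
    config: OptimizerConfig | None = None,
    cache: EvalCache | None = None,
) -> dict[str, SelectionResult]:
    """Equal-weight and single-method baselines at their own best k.

    Mirrors the comparison protocol used for the weighted-score approach:
    each baseline ranks features with a fixed weight vector (all mass on
    one method, or spread equally) and only searches over k.
    """
    config = config or OptimizerConfig()
    cache = cache if cache is not None else EvalCache()
    normed = normalize(table)
    n_methods = len(table.method_names)

    def k_search(units: tuple[int, ...]) -> SelectionResult:
        best = None
        for k in _resolve_k_range(config, data.n_features):
            metrics, subset = _eval_point(data, normed, units, k, config, cache)
            key = result_key(metrics, k, units)
            if best is None or key < best[0]:
                best = (key, units, k, subset, metrics)
        _, u, k_star, subset, metrics = best
        return SelectionResult(
            w_star=_units_to_weights(u, config.n_units),
            k_star=k_star,
            selected=subset,
            metrics=metrics,
            method_names=list(table.method_names),
            iterations_used=0,
            cache_hits=cache.hits,
            n_evaluations=cache.misses,
        )

    out = {"equal_weight": k_search(equal_weight_start(n_methods, config.n_units))}
    for i, name in enumerate(table.method_names):
        units = tuple(config.n_units if j == i else 0 for j in range(n_methods))
        out[name] = k_search(units)
    return out
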