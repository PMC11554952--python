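"""Causal structure over selected features: LiNGAM-style ordering, edge
estimation, and path-model significance tests.

The ordering step assumes a linear acyclic model with non-Gaussian noise
(x = Bx + e). The most exogenous variable is identified as the one whose
regression residuals in all other variables are least dependent on it
(dependence measured by distance correlation, which detects arbitrary
functional dependence, not just linear); the remaining variables are
replaced by those residuals and the step recurses. Under non-Gaussianity
this identifies the true causal order, which Gaussian methods cannot.

Edges are then estimated by OLS of each variable on its predecessors in
the order, keeping coefficients whose Wald test rejects at ``alpha``.

The path model implied by a DAG is fit by Gaussian maximum likelihood on
the covariance matrix: for a recursive model with independent residuals
and a saturated exogenous block, the ML point estimates coincide with
per-equation OLS, and standard errors come from the expected Fisher
information of the implied covariance. The resulting z-values are
invariant to per-variable affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import minmax_scale
from .importance import distance_correlation


class SingularModelError(ValueError):
    """Raised when a path model has a (numerically) zero residual variance."""


@dataclass(frozen=True)
class CausalGraph:
    """A weighted DAG over named variables.

    ``edges`` are (source, target, coefficient) triples; every edge must
    point from an earlier to a later variable in ``causal_order``, which
    makes the adjacency strictly triangular and the graph acyclic by
    construction.
    """

    nodes: list[str]
    causal_order: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sorted(self.nodes) != sorted(self.causal_order):
            raise ValueError("causal_order must be a permutation of nodes")
        pos = {v: i for i, v in enumerate(self.causal_order)}
        for src, dst, coef in self.edges:
            if src == dst:
                raise ValueError(f"self-loop {src!r} -> {dst!r}")
            if pos[src] >= pos[dst]:
                raise ValueError(
                    f"edge {src!r} -> {dst!r} violates the causal order"
                )
            if not np.isfinite(coef):
                raise ValueError(f"non-finite coefficient on {src!r} -> {dst!r}")

    def parents(self, node: str) -> list[str]:
        return [src for src, dst, _ in self.edges if dst == node]

    @property
    def adjacency(self) -> pd.DataFrame:
        """B[dst, src] = coefficient; strictly lower-triangular under causal_order."""
        B = pd.DataFrame(0.0, index=self.causal_order, columns=self.causal_order)
        for src, dst, coef in self.edges:
            B.loc[dst, src] = coef
        return B


@dataclass(frozen=True)
class PathTestResult:
    """Significance test for one directed path."""

    source: str
    target: str
    estimate: float
    std_err: float
    z_value: float
    p_value: float


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if hasattr(data, "to_dataframe"):
        return data.to_dataframe()
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def estimate_causal_order(data) -> list[str]:
    """Causal order of the columns via iterative exogeneity extraction.

    At each step, for every remaining variable j, every other remaining
    variable is regressed on j; the candidate minimising the summed
    distance correlation between itself and those residuals is appended to
    the order, all other variables are replaced by their residuals, and the
    procedure recurses. Ties break toward the earlier column.
    """
    df = _as_frame(data)
    names = list(df.columns)
    if len(names) < 1:
        raise ValueError("need at least one variable")
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    sd = X.std(axis=0)
    for j, name in enumerate(names):
        if sd[j] == 0.0:
            raise ValueError(f"variable {name!r} is constant")
    R = (X - X.mean(axis=0)) / sd
    remaining = list(range(len(names)))
    order: list[int] = []
    while len(remaining) > 1:
        best_j, best_score = None, np.inf
        resids = {}
        for j in remaining:
            xj = R[:, j]
            vj = xj @ xj
            total = 0.0
            rj = {}
            for k in remaining:
                if k == j:
                    continue
                b = (R[:, k] @ xj) / vj
                r = R[:, k] - b * xj
                rj[k] = r
                total += distance_correlation(xj, r)
            if total < best_score:
                best_j, best_score, resids = j, total, rj
        order.append(best_j)
        for k, r in resids.items():
            R[:, k] = r
        remaining.remove(best_j)
    order.extend(remaining)
    return [names[j] for j in order]


def estimate_edges(data, causal_order: list[str], alpha: float = 0.05) -> CausalGraph:
    """OLS along the causal order with Wald-test edge pruning.

    Each variable is regressed on all its predecessors; edges with
    two-sided p < alpha keep their coefficients, the rest are dropped.
    """
    import statsmodels.api as sm

    df = _as_frame(data)
    missing = [v for v in causal_order if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in data: {missing}")
    edges: list[tuple[str, str, float]] = []
    for i, dst in enumerate(causal_order):
        preds = causal_order[:i]
        if not preds:
            continue
        design = sm.add_constant(df[preds].to_numpy())
        fit = sm.OLS(df[dst].to_numpy(), design).fit()
        for j, src in enumerate(preds):
            if fit.pvalues[j + 1] < alpha:
                edges.append((src, dst, float(fit.params[j + 1])))
    return CausalGraph(nodes=list(causal_order), causal_order=list(causal_order), edges=edges)


def _ml_path_fit(S: np.ndarray, n: int, nodes: list[str], edges, scale_free_tol: float = 1e-10):
    """ML fit of a recursive path model given a covariance matrix.

    Returns per-edge (estimate, std_err). Point estimates are equation-wise
    OLS (exact ML here); SEs come from the expected Fisher information of
    the implied covariance Sigma(theta) = (I-B)^-1 Psi (I-B)^-T evaluated
    at the estimate, with the exogenous covariance block saturated and
    endogenous residuals independent.
    """
    p = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    parents: dict[str, list[str]] = {v: [] for v in nodes}
    for src, dst, *_ in edges:
        parents[dst].append(src)
    endo = [v for v in nodes if parents[v]]
    exo = [v for v in nodes if not parents[v]]

    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    for v in endo:
        pi = [idx[q] for q in parents[v]]
        vi = idx[v]
        beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, vi])
        B[vi, pi] = beta
        resid_var = S[vi, vi] - S[vi, pi] @ beta
        if resid_var <= scale_free_tol * S[vi, vi]:
            raise SingularModelError(
                f"residual variance of {v!r} is numerically zero; "
                "the path model is singular"
            )
        Psi[vi, vi] = resid_var
    ei = [idx[v] for v in exo]
    Psi[np.ix_(ei, ei)] = S[np.ix_(ei, ei)]

    # parameter layout: edge betas, endogenous residual variances,
    # exogenous variances and covariances
    layout: list[tuple[str, int, int]] = []
    theta: list[float] = []
    for src, dst, *_ in edges:
        layout.append(("B", idx[dst], idx[src]))
        theta.append(B[idx[dst], idx[src]])
    for v in endo:
        layout.append(("P", idx[v], idx[v]))
        theta.append(Psi[idx[v], idx[v]])
    for a in range(len(ei)):
        for b in range(a, len(ei)):
            layout.append(("P", ei[a], ei[b]))
            theta.append(Psi[ei[a], ei[b]])

    IB = np.linalg.inv(np.eye(p) - B)
    Sigma = IB @ Psi @ IB.T
    Sinv = np.linalg.inv(Sigma)

    derivs = []
    for kind, i, j in layout:
        if kind == "B":
            dB = np.zeros((p, p))
            dB[i, j] = 1.0
            M = IB @ dB @ IB @ Psi @ IB.T
            derivs.append(M + M.T)
        else:
            dP = np.zeros((p, p))
            dP[i, j] = 1.0
            dP[j, i] = 1.0
            derivs.append(IB @ dP @ IB.T)

    m = len(layout)
    half = [Sinv @ d for d in derivs]
    fim = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            fim[a, b] = fim[b, a] = 0.5 * n * np.trace(half[a] @ half[b])
    cov = np.linalg.inv(fim)
    se = np.sqrt(np.diag(cov))
    n_edges = len(edges)
    return np.array(theta[:n_edges]), se[:n_edges]


def fit_path_model(data, graph: CausalGraph, scale: str = "minmax") -> list[PathTestResult]:
    """Fit the recursive linear path model implied by a DAG and test each path.

    Variables are min-max scaled to [0, 1] by default (``scale`` may be
    "minmax", "standard" or "none"); z-values are invariant to the choice.
    Returns one result per graph edge, in edge order, with
    ``z = estimate / std_err`` and a two-sided normal p-value.
    """
    df = _as_frame(data)
    missing = [v for v in graph.nodes if v not in df.columns]
    if missing:
        raise ValueError(f"graph nodes not in data: {missing}")
    if not graph.edges:
        return []
    X = df[graph.nodes].to_numpy(dtype=float)
    if scale == "minmax":
        X = minmax_scale(X)
    elif scale == "standard":
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    n = X.shape[0]
    S = np.cov(X, rowvar=False, ddof=1)
    est, se = _ml_path_fit(S, n, graph.nodes, graph.edges)
    results = []
    for (src, dst, _), e, s in zip(graph.edges, est, se):
        z = e / s
        results.append(
            PathTestResult(
                source=src,
                target=dst,
                estimate=float(e),
                std_err=float(s),
                z_value=float(z),
                p_value=float(2.0 * stats.norm.sf(abs(z))),
            )
        )
    return results


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def export_graph(
    graph: CausalGraph, results: list[PathTestResult] | None = None
) -> tuple[str, pd.DataFrame]:
    """Render a DAG as DOT text plus an edge-list table.

    The DOT digraph labels each edge with its coefficient and, when path
    test results are supplied, significance stars. The DataFrame has
    columns source, target, estimate, std_err, z, p (test columns are NaN
    without results).
    """
    by_edge = {}
    if results:
        by_edge = {(r.source, r.target): r for r in results}
    lines = ["digraph causal {"]
    for v in graph.nodes:
        lines.append(f'  "{v}";')
    rows = []
    for src, dst, coef in graph.edges:
        r = by_edge.get((src, dst))
        if r is not None:
            label = f"{r.estimate:.3f}{_stars(r.p_value)}"
            rows.append((src, dst, r.estimate, r.std_err, r.z_value, r.p_value))
        else:
            label = f"{coef:.3f}"
            rows.append((src, dst, coef, np.nan, np.nan, np.nan))
        lines.append(f'  "{src}" -> "{dst}" [label="{label}"];')
    lines.append("}")
    df = pd.DataFrame(rows, columns=["source", "target", "estimate", "std_err", "z", "p"])
    return "\n".join(lines) + "\n", df


def graph_from_edge_list(text: str, nodes: list[str] | None = None) -> CausalGraph:
    """Build a CausalGraph from plain-text edges, one ``source -> target`` per line.

    The causal order is derived by topological sort (Kahn's algorithm);
    cycles raise an error. Coefficients default to 0 until estimated.
    """
    edges = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise ValueError(f"cannot parse edge line {line!r}")
        src, dst = (part.strip() for part in line.split("->", 1))
        edges.append((src, dst, 0.0))
    seen = list(dict.fromkeys([v for e in edges for v in e[:2]]))
    all_nodes = list(nodes) if nodes is not None else seen
    indeg = {v: 0 for v in all_nodes}
    succ = {v: [] for v in all_nodes}
    for src, dst, _ in edges:
        indeg[dst] += 1
        succ[src].append(dst)
    queue = [v for v in all_nodes if indeg[v] == 0]
    order = []
    while queue:
        v = queue.pop(0)
        order.append(v)
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    if len(order) != len(all_nodes):
        raise ValueError("edge list contains a cycle")
    return CausalGraph(nodes=all_nodes, causal_order=order, edges=edges)
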