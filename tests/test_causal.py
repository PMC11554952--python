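import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wtscausal import (
    CausalGraph,
    LingamSpec,
    SingularModelError,
    estimate_causal_order,
    estimate_edges,
    export_graph,
    fit_path_model,
    gen_lingam,
)
from wtscausal.causal import graph_from_edge_list


CHAIN_B = ((0.0, 0.0, 0.0), (0.8, 0.0, 0.0), (0.0, 0.8, 0.0))


class TestCausalOrder:
    def test_single_variable(self):
        df = pd.DataFrame({"a": np.random.default_rng(0).standard_normal(50)})
        assert estimate_causal_order(df) == ["a"]

    def test_two_variable_direction_identified(self):
        df, order, _ = gen_lingam(
            LingamSpec(b_matrix=((0.0, 0.0), (2.0, 0.0)), n_samples=2000, seed=1,
                       permute=True)
        )
        est = estimate_causal_order(df)
        assert est == [df.columns[j] for j in order]

    def test_three_variable_chain_recovered(self):
        df, order, _ = gen_lingam(
            LingamSpec(b_matrix=CHAIN_B, n_samples=2000, seed=2, permute=True)
        )
        assert estimate_causal_order(df) == [df.columns[j] for j in order]

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="constant"):
            estimate_causal_order(df)


class TestEstimateEdges:
    def test_two_node_closed_form_slope(self):
        df, order, _ = gen_lingam(
            LingamSpec(b_matrix=((0.0, 0.0), (2.0, 0.0)), n_samples=2000, seed=3)
        )
        graph = estimate_edges(df, ["v0", "v1"])
        assert len(graph.edges) == 1
        src, dst, coef = graph.edges[0]
        assert (src, dst) == ("v0", "v1")
        x, y = df["v0"].to_numpy(), df["v1"].to_numpy()
        ols = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert coef == pytest.approx(ols, rel=1e-9)
        assert coef == pytest.approx(2.0, abs=0.1)

    def test_coefficient_recovery_and_pruning(self):
        B = ((0.0, 0.0, 0.0), (0.7, 0.0, 0.0), (0.5, -0.6, 0.0))
        df, order, _ = gen_lingam(LingamSpec(b_matrix=B, n_samples=5000, seed=4))
        graph = estimate_edges(df, ["v0", "v1", "v2"])
        got = {(s, d): c for s, d, c in graph.edges}
        assert got[("v0", "v1")] == pytest.approx(0.7, abs=0.1)
        assert got[("v0", "v2")] == pytest.approx(0.5, abs=0.1)
        assert got[("v1", "v2")] == pytest.approx(-0.6, abs=0.1)

    def test_independent_variables_edge_rate_near_alpha(self):
        # under the null each potential edge is retained ~5% of the time
        kept = total = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.standard_normal((300, 3)), columns=["a", "b", "c"])
            g = estimate_edges(df, ["a", "b", "c"], alpha=0.05)
            kept += len(g.edges)
            total += 3
        assert kept / total < 0.15

    def test_output_always_acyclic(self):
        df, _, _ = gen_lingam(LingamSpec(b_matrix=CHAIN_B, n_samples=1000, seed=5))
        graph = estimate_edges(df, ["v0", "v1", "v2"])
        pos = {v: i for i, v in enumerate(graph.causal_order)}
        for src, dst, _ in graph.edges:
            assert pos[src] < pos[dst]


class TestCausalGraph:
    def test_order_violating_edge_rejected(self):
        with pytest.raises(ValueError, match="order"):
            CausalGraph(nodes=["a", "b"], causal_order=["a", "b"], edges=[("b", "a", 1.0)])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            CausalGraph(nodes=["a"], causal_order=["a"], edges=[("a", "a", 1.0)])


class TestFitPathModel:
    def test_single_path_matches_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        x = rng.standard_normal(400)
        y = 1.2 * x + 0.5 * rng.standard_normal(400)
        df = pd.DataFrame({"x": x, "y": y})
        graph = CausalGraph(nodes=["x", "y"], causal_order=["x", "y"],
                            edges=[("x", "y", 0.0)])
        (res,) = fit_path_model(df, graph, scale="none")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.estimate == pytest.approx(fit.params[1], rel=1e-9)
        assert res.z_value == pytest.approx(fit.tvalues[1], rel=0.02)

    def test_zero_residual_variance_raises_singular(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": x})
        graph = CausalGraph(nodes=["x", "y"], causal_order=["x", "y"],
                            edges=[("x", "y", 0.0)])
        with pytest.raises(SingularModelError):
            fit_path_model(df, graph)

    def test_z_p_consistency(self):
        df, _, _ = gen_lingam(LingamSpec(b_matrix=CHAIN_B, n_samples=1000, seed=7))
        graph = estimate_edges(df, ["v0", "v1", "v2"])
        for r in fit_path_model(df, graph):
            assert r.z_value == pytest.approx(r.estimate / r.std_err, rel=1e-6)
            assert r.p_value == pytest.approx(2 * stats.norm.sf(abs(r.z_value)), abs=1e-9)
            assert r.std_err > 0

    def test_z_invariant_to_affine_rescaling(self):
        df, _, _ = gen_lingam(LingamSpec(b_matrix=CHAIN_B, n_samples=800, seed=8))
        graph = estimate_edges(df, ["v0", "v1", "v2"])
        z_minmax = [r.z_value for r in fit_path_model(df, graph, scale="minmax")]
        z_std = [r.z_value for r in fit_path_model(df, graph, scale="standard")]
        np.testing.assert_allclose(z_minmax, z_std, rtol=1e-8)

    def test_empty_graph_returns_no_results(self):
        df = pd.DataFrame(np.random.default_rng(9).standard_normal((50, 2)),
                          columns=["a", "b"])
        graph = CausalGraph(nodes=["a", "b"], causal_order=["a", "b"], edges=[])
        assert fit_path_model(df, graph) == []


class TestMonteCarloRecovery:
    def test_chain_order_recovery_rate(self):
        """Uniform-noise 3-chain: order recovered in >= 90% of seeded replicates."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            df, order, _ = gen_lingam(
                LingamSpec(b_matrix=CHAIN_B, n_samples=2000, seed=100 + seed, permute=True)
            )
            hits += estimate_causal_order(df) == [df.columns[j] for j in order]
        assert hits / n_rep >= 0.9


class TestExportGraph:
    def _fitted(self):
        df, _, _ = gen_lingam(LingamSpec(b_matrix=CHAIN_B, n_samples=1000, seed=10))
        graph = estimate_edges(df, ["v0", "v1", "v2"])
        return graph, fit_path_model(df, graph)

    def test_nodes_only_when_no_edges(self):
        graph = CausalGraph(nodes=["a", "b"], causal_order=["a", "b"], edges=[])
        dot, edges = export_graph(graph)
        assert '"a";' in dot and '"b";' in dot
        assert "->" not in dot
        assert edges.empty

    def test_edge_csv_round_trips_into_graph(self, tmp_path):
        graph, results = self._fitted()
        dot, edges = export_graph(graph, results)
        path = tmp_path / "edges.csv"
        edges.to_csv(path, index=False)
        back = pd.read_csv(path)
        lines = "\n".join(f"{r.source} -> {r.target}" for r in back.itertuples())
        rebuilt = graph_from_edge_list(lines)
        assert {(s, d) for s, d, _ in rebuilt.edges} == {(s, d) for s, d, _ in graph.edges}

    def test_dot_structure_contains_labelled_edges(self):
        graph, results = self._fitted()
        dot, _ = export_graph(graph, results)
        assert dot.startswith("digraph")
        assert dot.rstrip().endswith("}")
        for src, dst, _ in graph.edges:
            assert f'"{src}" -> "{dst}"' in dot

    def test_cyclic_edge_list_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            graph_from_edge_list("a -> b\nb -> a")
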