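"""Weighted-network construction, PCST transformation, and the exact solver."""

import networkx as nx
import numpy as np
import pytest

from activemod.bum_model import BumFit, scoring_scheme
from activemod.errors import NoSignalError, SolverError, ValidationError
from activemod.module_detection import (
    brute_force_mwcs,
    build_weighted_network,
    detect_module,
    fdr_sweep,
    mwcs_to_pcst,
    solve_pcst,
    sweep_table,
)
from activemod.ppin_io import PValueTable
from activemod.simulate import generate_instance

from conftest import make_nwg, random_nwg


def _line(*names):
    G = nx.Graph()
    nx.add_path(G, names)
    return G


class TestBuildWeightedNetwork:
    def _table(self, entries):
        return PValueTable(entries=entries)

    def test_drop_policy_intersects(self):
        ppin = _line("a", "b", "c")
        table = self._table({"a": 0.001, "b": 0.2})
        nwg = build_weighted_network(
            ppin, table, fdr=0.1, scheme=_scheme(alpha=0.5, tau=0.01)
        )
        assert set(nwg.graph.nodes) == {"a", "b"}
        assert nwg.dropped == ["c"]

    def test_penalty_policy_keeps_unmeasured_at_min_score(self):
        ppin = _line("a", "b", "c")
        table = self._table({"a": 0.001, "b": 0.2})
        nwg = build_weighted_network(
            ppin,
            table,
            fdr=0.1,
            missing_policy="penalty",
            scheme=_scheme(alpha=0.5, tau=0.01),
        )
        assert set(nwg.graph.nodes) == {"a", "b", "c"}
        measured_min = min(nwg.weights["a"], nwg.weights["b"])
        assert nwg.weights["c"] == measured_min
        assert nwg.dropped == []

    def test_table_gene_absent_from_network_is_ignored(self):
        ppin = _line("a", "b")
        table = self._table({"a": 0.01, "b": 0.02, "zz": 0.5})
        nwg = build_weighted_network(
            ppin, table, fdr=0.1, scheme=_scheme(alpha=0.5, tau=0.01)
        )
        assert "zz" not in nwg.graph

    def test_empty_intersection_errors(self):
        with pytest.raises(ValidationError):
            build_weighted_network(
                _line("a", "b"),
                self._table({"x": 0.5}),
                fdr=0.1,
                scheme=_scheme(alpha=0.5, tau=0.01),
            )


def _scheme(alpha=0.5, tau=0.01):
    fit = BumFit(lambda_=0.7, alpha=alpha, n=500, log_likelihood=0.0)
    base = scoring_scheme(fit, min(0.05, fit.pi_upper / 2))
    return base.__class__(fit=fit, fdr=base.fdr, tau=tau)


class TestPcstTransformation:
    def test_hand_example(self):
        nwg = make_nwg(
            [("a", "b"), ("b", "c")], {"a": 2.0, "b": -1.0, "c": -1.0}
        )
        inst = mwcs_to_pcst(nwg)
        assert inst.offset == -1.0
        assert inst.prizes == {"a": 3.0, "b": 0.0, "c": 0.0}
        assert inst.edge_cost == 1.0

    def test_all_positive_weights_give_zero_edge_cost(self):
        nwg = make_nwg([("a", "b")], {"a": 1.0, "b": 2.0})
        inst = mwcs_to_pcst(nwg)
        assert inst.offset == 0.0
        assert inst.edge_cost == 0.0
        assert inst.prizes == nwg.weights

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_identity_on_random_instances(self, seed):
        """PCST tree objective equals MWCS objective minus the floor, always."""
        nwg = random_nwg(seed, n_max=12, p=0.5)
        inst = mwcs_to_pcst(nwg)
        rng = np.random.default_rng(seed)
        comps = list(nx.connected_components(nwg.graph))
        for _ in range(10):
            comp = sorted(comps[rng.integers(len(comps))])
            start = comp[rng.integers(len(comp))]
            size = int(rng.integers(1, len(comp) + 1))
            tree_nodes = set(
                list(nx.bfs_tree(nwg.graph.subgraph(comp), start))[:size]
            )
            mwcs_obj = sum(nwg.weights[v] for v in tree_nodes)
            assert inst.tree_objective(tree_nodes) == pytest.approx(
                mwcs_obj - inst.offset, abs=1e-9
            )


class TestSolver:
    def test_path_example(self, path_nwg):
        module = solve_pcst(mwcs_to_pcst(path_nwg))
        assert module.nodes == {"b", "c", "d"}
        assert module.objective == pytest.approx(7.0)
        assert module.exact

    def test_all_negative_returns_single_best_node(self):
        nwg = make_nwg(
            [("a", "b"), ("b", "c")], {"a": -3.0, "b": -0.5, "c": -1.0}
        )
        module = solve_pcst(mwcs_to_pcst(nwg))
        assert module.nodes == {"b"}
        assert module.objective == pytest.approx(-0.5)

    def test_all_positive_returns_whole_component(self):
        nwg = make_nwg([("a", "b"), ("b", "c")], {"a": 1.0, "b": 0.5, "c": 2.0})
        module = solve_pcst(mwcs_to_pcst(nwg))
        assert module.nodes == {"a", "b", "c"}

    def test_multi_component_returns_best_overall(self):
        nwg = make_nwg(
            [("a", "b"), ("x", "y")], {"a": 1.0, "b": 1.0, "x": 5.0, "y": -0.1}
        )
        module = solve_pcst(mwcs_to_pcst(nwg))
        assert module.nodes == {"x"}

    def test_module_invariants(self, path_nwg):
        module = solve_pcst(mwcs_to_pcst(path_nwg))
        assert len(module.tree_edges) == module.size() - 1
        sub = path_nwg.graph.subgraph(module.nodes)
        assert nx.is_connected(sub)
        assert module.recomputed_objective() == pytest.approx(module.objective, abs=1e-9)
        assert module.connectors == {"c"}

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_on_random_instances(self, seed):
        nwg = random_nwg(seed)
        exact = solve_pcst(mwcs_to_pcst(nwg))
        oracle = brute_force_mwcs(nwg)
        assert exact.objective == pytest.approx(oracle.objective, abs=1e-9)

    def test_greedy_backend_is_labelled_inexact(self):
        nwg = random_nwg(5)
        module = solve_pcst(mwcs_to_pcst(nwg), backend="greedy")
        assert module.backend == "greedy"
        sub = nwg.graph.subgraph(module.nodes)
        assert nx.is_connected(sub)

    def test_size_bound_enforced(self):
        nwg = random_nwg(3)
        with pytest.raises(SolverError, match="size bound"):
            solve_pcst(mwcs_to_pcst(nwg), size_bound=1)


class TestBruteForce:
    def test_single_node(self):
        nwg = make_nwg([], {"only": -2.0})
        module = brute_force_mwcs(nwg)
        assert module.nodes == {"only"}

    def test_path_example(self, path_nwg):
        assert brute_force_mwcs(path_nwg).objective == pytest.approx(7.0)

    def test_tie_break_is_lexicographic(self):
        nwg = make_nwg([("a", "z"), ("z", "b")], {"a": 1.0, "b": 1.0, "z": -5.0})
        assert brute_force_mwcs(nwg).nodes == {"a"}

    def test_size_bound(self):
        nwg = random_nwg(0, n_max=12)
        with pytest.raises(ValidationError):
            brute_force_mwcs(nwg, max_nodes=3)


class TestPipeline:
    def test_detect_recovers_most_of_planted_set(self):
        inst = generate_instance(seed=1)
        module = detect_module(inst.ppin, inst.table, fdr=0.3)
        overlap = len(module.nodes & inst.planted)
        assert overlap / len(inst.planted) >= 0.5
        assert module.tau is not None and module.fdr == 0.3
        assert set(module.pvalues) == module.nodes

    def test_detect_refuses_pure_noise_without_force(self):
        inst = generate_instance(seed=2)
        rng = np.random.default_rng(0)
        noise = PValueTable(
            entries={g: float(max(rng.uniform(), 1e-12)) for g in inst.table.entries}
        )
        with pytest.raises(NoSignalError):
            detect_module(inst.ppin, noise, fdr=0.1)
        # force bypasses the refusal; this sample's fit is fully degenerate
        # (alpha at its upper bound), so the threshold itself is infeasible
        from activemod.errors import ParameterError

        with pytest.raises(ParameterError, match="degenerate"):
            detect_module(inst.ppin, noise, fdr=0.1, force=True)

    def test_detect_propagates_infeasible_fdr(self):
        inst = generate_instance(seed=1)
        from activemod.errors import ParameterError

        with pytest.raises(ParameterError):
            detect_module(inst.ppin, inst.table, fdr=0.999)

    def test_sweep_sizes_non_decreasing_and_connector_counts(self):
        inst = generate_instance(seed=3, n_nodes=150, planted_size=10)
        grid = [0.01, 0.05, 0.2, 0.5]
        results = fdr_sweep(inst.ppin, inst.table, grid)
        sizes = [m.size() for _, m in results]
        assert sizes == sorted(sizes)
        df = sweep_table(results)
        assert list(df.columns) == [
            "fdr",
            "tau",
            "module_size",
            "n_significant",
            "n_connectors",
            "objective",
        ]
        assert (df["n_significant"] + df["n_connectors"] >= df["module_size"]).all()

    def test_sweep_single_point_matches_detect(self):
        inst = generate_instance(seed=4, n_nodes=150, planted_size=10)
        [(_, swept)] = fdr_sweep(inst.ppin, inst.table, [0.2])
        direct = detect_module(inst.ppin, inst.table, 0.2)
        assert swept.nodes == direct.nodes
        assert swept.objective == pytest.approx(direct.objective)

    def test_sweep_rejects_non_increasing_grid(self):
        inst = generate_instance(seed=4, n_nodes=150, planted_size=10)
        with pytest.raises(ValidationError):
            fdr_sweep(inst.ppin, inst.table, [0.2, 0.1])
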