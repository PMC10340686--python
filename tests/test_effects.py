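"""IDA adjustment estimates and exact total causal effects on linear SEMs."""

import numpy as np
import pytest

from gges import (
    Dag,
    Dataset,
    SemSpec,
    VariableSpec,
    cpdag_of,
    ida,
    ida_multiset,
    ida_table,
    sample_linear_sem,
    tce,
)
from helpers import make_roles


def sem(nodes, weighted_edges, noise=1.0):
    dag = Dag(nodes, [e for e, _ in weighted_edges])
    return SemSpec(dag, {e: w for e, w in weighted_edges},
                   {n: noise for n in nodes})


class TestTce:
    def test_single_edge(self):
        s = sem(["x", "y"], [(("x", "y"), 0.5)])
        assert tce(s, "x", "y") == pytest.approx(0.5)

    def test_path_product_sum(self):
        s = sem(["x", "m", "y"],
                [(("x", "m"), 0.5), (("m", "y"), 0.4), (("x", "y"), 0.1)])
        assert tce(s, "x", "y") == pytest.approx(0.5 * 0.4 + 0.1)

    def test_no_directed_path_gives_zero(self):
        s = sem(["x", "y", "z"], [(("z", "x"), 1.0), (("z", "y"), 1.0)])
        assert tce(s, "x", "y") == 0.0

    def test_matrix_route_equals_explicit_path_enumeration(self):
        """Closed-form (I−W)⁻¹ entries vs brute-force path products (networkx)."""
        import networkx as nx
        from gges import random_constrained_dag, random_sem_spec

        for seed in range(5):
            dag = random_constrained_dag(5, 1, seed=seed, n_edges=7)
            s = random_sem_spec(dag, seed=seed + 10)
            g = dag.to_networkx()
            for x in dag.nodes:
                for y in dag.nodes:
                    if x == y:
                        continue
                    brute = sum(
                        np.prod([s.weights[(u, v)] for u, v in zip(path, path[1:])])
                        for path in nx.all_simple_paths(g, x, y)
                    )
                    assert tce(s, x, y) == pytest.approx(brute, abs=1e-10)

    def test_linear_in_any_single_edge_weight(self):
        base = [(("x", "m"), 0.5), (("m", "y"), 0.4), (("x", "y"), 0.1)]
        nodes = ["x", "m", "y"]
        for i in range(len(base)):
            def at(w):
                weighted = [(e, w if j == i else b) for j, (e, b) in enumerate(base)]
                return tce(sem(nodes, weighted), "x", "y")
            # second finite difference of a linear function vanishes
            assert at(0.0) - 2 * at(0.5) + at(1.0) == pytest.approx(0.0, abs=1e-12)


class TestIda:
    def test_recovers_single_edge_coefficient(self):
        s = sem(["x", "y"], [(("x", "y"), 1.5)])
        d = sample_linear_sem(s, 10_000, seed=1)
        est = ida(d, s.dag, "x", "y")
        assert est.ida == pytest.approx(1.5, abs=3 * 2 / np.sqrt(10_000))
        assert est.n_equivalent == 1 and est.aggregation == "single"

    def test_parent_adjustment_blocks_backdoor(self):
        s = sem(["z", "x", "y"], [(("z", "x"), 1.0), (("z", "y"), 1.0)])
        d = sample_linear_sem(s, 10_000, seed=2)
        assert ida(d, s.dag, "x", "y").ida == pytest.approx(0.0, abs=0.05)

    def test_target_in_parents_gives_exact_zero(self):
        s = sem(["y", "x"], [(("y", "x"), 2.0)])
        d = sample_linear_sem(s, 500, seed=3)
        assert ida(d, s.dag, "x", "y").ida == 0.0


class TestIdaMultiset:
    def test_fully_directed_class_matches_single_ida(self):
        s = sem(["x", "m", "y"], [(("x", "m"), 1.0), (("m", "y"), 1.0)])
        d = sample_linear_sem(s, 2000, seed=4,
                              roles=make_roles(["x", "m", "y"], outcomes={"y"}))
        p = cpdag_of(Dag(["x", "m", "y"], [("x", "m")]), make_roles(["x", "m", "y"]))
        # x—m undirected in the class; both orientations enumerated
        est = ida_multiset(d, p, "x", "y")
        assert est.n_equivalent == 2 and est.aggregation == "min_abs"
        per_orientation = [
            ida(d, Dag(["x", "m", "y"], [("x", "m")]), "x", "y").ida,
            ida(d, Dag(["x", "m", "y"], [("m", "x")]), "x", "y").ida,
        ]
        assert est.ida == min(per_orientation, key=abs)

    def test_isolated_source_reduces_to_simple_regression(self):
        gen = np.random.default_rng(5)
        x = gen.standard_normal(1000)
        y = 0.7 * x + gen.standard_normal(1000)
        d = Dataset(np.column_stack([x, y]),
                    [VariableSpec("x"), VariableSpec("y")])
        p = cpdag_of(Dag(["x", "y"]), make_roles("xy"))
        est = ida_multiset(d, p, "x", "y")
        assert est.n_equivalent == 1
        assert est.ida == pytest.approx(float(np.polyfit(x, y, 1)[0]), rel=1e-9)

    def test_singleton_class_equals_dag_ida(self):
        s = sem(["x", "y"], [(("x", "y"), 1.0)])
        roles = make_roles("xy", outcomes={"y"})
        d = sample_linear_sem(s, 1000, seed=6, roles=roles)
        p = cpdag_of(s.dag, roles)
        assert p.is_fully_directed()
        assert ida_multiset(d, p, "x", "y").ida == ida(d, s.dag, "x", "y").ida


class TestIdaTceConsistency:
    def test_ida_converges_to_true_total_effect(self):
        """Parent adjustment recovers path-product effects on identifiable SEMs."""
        from gges import random_constrained_dag, random_sem_spec

        rel_errors, null_estimates = [], []
        for seed in range(10):
            dag = random_constrained_dag(6, 1, seed=seed, n_edges=8)
            s = random_sem_spec(dag, seed=seed + 100)
            roles = make_roles(dag.nodes, outcomes={"o0"})
            d = sample_linear_sem(s, 10_000, seed=seed + 200, roles=roles)
            for x in dag.nodes:
                if x == "o0":
                    continue
                true = tce(s, x, "o0")
                est = ida(d, dag, x, "o0").ida
                if abs(true) >= 0.5:
                    rel_errors.append(abs(est - true) / abs(true))
                elif not dag.has_path(x, "o0"):
                    null_estimates.append(est)
        assert np.mean(rel_errors) < 0.10
        assert np.max(np.abs(null_estimates)) < 0.1


class TestIdaTable:
    def test_sorted_by_absolute_effect_and_matches_pairwise_calls(self):
        s = sem(["a", "b", "c", "y"],
                [(("a", "y"), 2.0), (("b", "y"), -0.5), (("a", "b"), 1.0)])
        roles = make_roles("abcy", outcomes={"y"})
        d = sample_linear_sem(s, 5000, seed=7, roles=roles)
        table = ida_table(d, s.dag, "y", roles=roles)
        assert list(table.columns[:3]) == ["variable", "ida", "abs_ida"]
        assert list(table["rank"]) == [1, 2, 3]
        assert list(table["abs_ida"]) == sorted(table["abs_ida"], reverse=True)
        for _, row in table.iterrows():
            assert row["ida"] == ida(d, s.dag, row["variable"], "y").ida

    def test_unconnected_variables_have_zero_effect_rows(self):
        roles = make_roles("aby", outcomes={"y"})
        gen = np.random.default_rng(8)
        d = Dataset(gen.standard_normal((500, 3)), roles.specs)
        table = ida_table(d, Dag(["a", "b", "y"]), "y", roles=roles)
        # no causal paths: estimates are chance-level marginal regressions
        assert set(table["variable"]) == {"a", "b"}
        assert (table["abs_ida"] < 0.2).all()
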