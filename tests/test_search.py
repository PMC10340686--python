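"""Grouped greedy search: constraint, phases, oracle agreement, pruning."""

import numpy as np
import pytest

from gges import (
    Dag,
    Dataset,
    VariableSpec,
    allowed_edge,
    fit_gges,
    graph_score,
    greedy_backward,
    greedy_forward,
    is_acyclic,
    prune_isolated,
    random_constrained_dag,
    random_sem_spec,
    sample_linear_sem,
)
from helpers import make_roles, naive_gges


def pair_dataset(n, seed, slope=2.0, noise=0.1, names=("x", "y")):
    gen = np.random.default_rng(seed)
    x = gen.standard_normal(n)
    y = slope * x + gen.normal(0, noise, n)
    return Dataset(np.column_stack([x, y]), [VariableSpec(v) for v in names])


class TestAllowedEdge:
    @pytest.mark.parametrize(
        "role_x, role_y, expected",
        [("causal", "causal", True), ("causal", "outcome", True),
         ("outcome", "causal", False), ("outcome", "outcome", False)],
    )
    def test_only_causal_sources_admissible(self, role_x, role_y, expected):
        roles = make_roles(
            "xyz", outcomes={n for n, r in (("x", role_x), ("y", role_y)) if r == "outcome"})
        assert allowed_edge("x", "y", roles) is expected

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            allowed_edge("x", "nope", make_roles("xy"))


class TestGreedyForward:
    def test_independent_columns_give_empty_graph(self, iid_dataset):
        g, trace = greedy_forward(iid_dataset, make_roles("abcde"))
        assert not g.edges and not trace

    def test_strong_pair_gets_exactly_one_edge(self):
        d = pair_dataset(1000, seed=1)
        g, _ = greedy_forward(d, make_roles("xy"))
        assert len(g.edges) == 1 and g.adjacent("x", "y")

    def test_outcome_pair_is_oriented_into_outcome(self):
        d = pair_dataset(1000, seed=2)
        g, _ = greedy_forward(d, make_roles("xy", outcomes={"y"}))
        assert g.edges == {("x", "y")}

    def test_trace_scores_strictly_increase(self):
        dag = random_constrained_dag(5, 1, seed=4, n_edges=6)
        roles = make_roles(dag.nodes, outcomes={"o0"})
        d = sample_linear_sem(random_sem_spec(dag, seed=5), 2000, seed=6, roles=roles)
        _, trace = greedy_forward(d, roles)
        scores = [r.score_after for r in trace]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestGreedyBackward:
    def test_empty_graph_unchanged(self, iid_dataset):
        g0 = Dag(list("abcde"))
        g, trace = greedy_backward(iid_dataset, g0, make_roles("abcde"))
        assert g.edges == g0.edges and not trace

    def test_spurious_edge_between_independent_columns_deleted(self, iid_dataset):
        g0 = Dag(list("abcde"), [("a", "b")])
        g, trace = greedy_backward(iid_dataset, g0, make_roles("abcde"))
        assert not g.edges and len(trace) == 1

    def test_forward_result_on_faithful_data_is_stable(self):
        dag = random_constrained_dag(6, 1, seed=7, n_edges=7)
        roles = make_roles(dag.nodes, outcomes={"o0"})
        d = sample_linear_sem(random_sem_spec(dag, seed=8), 5000, seed=9, roles=roles)
        g_fwd, _ = greedy_forward(d, roles)
        g_final, trace = greedy_backward(d, g_fwd, roles)
        assert g_final.edges == g_fwd.edges and not trace


class TestFitGges:
    def test_single_causal_outcome_pair(self):
        d = pair_dataset(1000, seed=10, slope=3.0)
        r = fit_gges(d, make_roles("xy", outcomes={"y"}))
        assert r.graph.edges == {("x", "y")}
        assert r.score == pytest.approx(graph_score(d, r.graph), abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_full_rescoring_oracle(self, seed):
        """Final score equals an independently coded naive greedy oracle's."""
        dag = random_constrained_dag(3, 1, edge_prob=0.5, seed=30 + seed)
        roles = make_roles(dag.nodes, outcomes={"o0"})
        d = sample_linear_sem(random_sem_spec(dag, seed=40 + seed), 500,
                              seed=50 + seed, roles=roles)
        r = fit_gges(d, roles)
        idx = {n: i for i, n in enumerate(d.names)}
        _, oracle_score = naive_gges(d.values, {idx["o0"]})
        assert r.score == pytest.approx(oracle_score, abs=1e-6)

    def test_constraint_safety_and_acyclicity(self):
        d, sem = _cohort_like(n=800, seed=11)
        roles = make_roles(d.names, outcomes={"o0", "o1"})
        r = fit_gges(d, roles)
        assert is_acyclic(r.graph)
        assert all(u not in ("o0", "o1") for u, _ in r.graph.edges)
        for rec in r.trace:
            assert rec.edge[0] not in ("o0", "o1")

    def test_deterministic_given_data(self):
        d = pair_dataset(500, seed=12)
        r1, r2 = fit_gges(d, make_roles("xy")), fit_gges(d, make_roles("xy"))
        assert r1.graph.edges == r2.graph.edges and r1.score == r2.score


def _cohort_like(n, seed):
    dag = random_constrained_dag(6, 2, seed=seed, n_edges=8)
    roles = make_roles(dag.nodes, outcomes={"o0", "o1"})
    sem = random_sem_spec(dag, seed=seed + 1)
    return sample_linear_sem(sem, n, seed=seed + 2, roles=roles), sem


class TestPruneIsolated:
    def test_isolated_node_moved_to_pruned(self):
        d = pair_dataset(100, seed=13, names=("a", "b"))
        gen = np.random.default_rng(14)
        d3 = Dataset(np.column_stack([d.values, gen.standard_normal(100)]),
                     d.variables + [VariableSpec("c")])
        r = fit_gges(d3, make_roles("abc"))
        assert set(r.graph.nodes) == {"a", "b"} or len(r.graph.edges) >= 1
        pruned = prune_isolated(r, d3)
        assert pruned.pruned_variables == ["c"]
        assert pruned.retained_variables == ["a", "b"]
        assert set(pruned.pruned_marginal_scores) == {"c"}
        # retained-only score excludes exactly the pruned marginal terms
        assert pruned.score == pytest.approx(
            r.score - pruned.pruned_marginal_scores["c"], abs=1e-9)

    def test_identity_when_nothing_isolated(self):
        d = pair_dataset(500, seed=15)
        r = fit_gges(d, make_roles("xy"))
        assert prune_isolated(r, d) is r

    def test_empty_graph_prunes_everything(self, iid_dataset):
        r = fit_gges(iid_dataset, make_roles("abcde"))
        pruned = prune_isolated(r, iid_dataset)
        assert pruned.retained_variables == []
        assert pruned.pruned_variables == list("abcde")
        assert pruned.score == pytest.approx(0.0, abs=1e-9)
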