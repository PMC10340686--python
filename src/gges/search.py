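"""Grouped greedy structure search over directed acyclic graphs.

Variables are partitioned into a causal group and an outcome (predicted)
group.  Outcome variables may be influenced but never influence anything, so
the only admissible edges run causal→causal or causal→outcome.  Under that
constraint the search maximizes the decomposable Gaussian BIC graph score in
two phases: a greedy forward phase that, starting from the empty graph,
repeatedly inserts the single admissible acyclicity-preserving edge with the
largest strictly positive score gain, and a greedy backward phase that
repeatedly deletes the edge whose removal yields the largest strictly
positive gain.  Ties are broken lexicographically in input column order, so
results are fully deterministic.

Within the all-causal block the score cannot distinguish Markov-equivalent
orientations; the reported DAG resolves those by the tie-break order, and
:func:`gges.graphs.cpdag_of` reports the honest equivalence class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

from .graphs import Dag, GraphStructureError, is_acyclic
from .scoring import (
    Dataset,
    DegenerateModelError,
    ScoreCache,
    delta_delete,
    delta_insert,
    graph_score,
    local_score,
)

__all__ = [
    "VariableSpec",
    "RoleAssignment",
    "TraceRecord",
    "SearchTrace",
    "SearchResult",
    "allowed_edge",
    "greedy_forward",
    "greedy_backward",
    "fit_gges",
    "prune_isolated",
]

logger = logging.getLogger(__name__)

# Score differences smaller than this are treated as exactly zero: BIC already
# penalizes complexity, so no additional improvement slack is introduced.
SCORE_TOL = 1e-9

Role = Literal["causal", "outcome"]
Kind = Literal["continuous", "coded-categorical"]


@dataclass(frozen=True)
class VariableSpec:
    """A named variable with its group role and measurement kind."""

    name: str
    role: Role = "causal"
    kind: Kind = "continuous"

    def __post_init__(self) -> None:
        if self.role not in ("causal", "outcome"):
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind not in ("continuous", "coded-categorical"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")


class RoleAssignment:
    """Total partition of variables into the causal and outcome groups.

    Construct from an ordered sequence of :class:`VariableSpec`; order is the
    canonical variable order used for every deterministic tie-break.
    """

    def __init__(self, specs: Sequence[VariableSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in role assignment")
        if not specs:
            raise ValueError("empty role assignment")
        if all(s.role == "outcome" for s in specs):
            raise ValueError("at least one causal variable is required")
        self._specs = specs
        self._by_name = {s.name: s for s in specs}

    @classmethod
    def from_mapping(
        cls,
        roles: Mapping[str, str],
        order: Sequence[str],
        kinds: Mapping[str, str] | None = None,
    ) -> "RoleAssignment":
        """Build from a name→role mapping over columns in ``order``.

        Columns absent from ``roles`` default to causal (with a warning), the
        convention for clinical tables where only outcomes are annotated.
        """
        kinds = kinds or {}
        specs = []
        unknown = set(roles) - set(order)
        if unknown:
            raise ValueError(f"roles given for unknown variables: {sorted(unknown)}")
        for name in order:
            role = roles.get(name)
            if role is None:
                logger.warning("variable %r not in roles file; defaulting to causal", name)
                role = "causal"
            specs.append(VariableSpec(name, role, kinds.get(name, "continuous")))
        return cls(specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def specs(self) -> list[VariableSpec]:
        return list(self._specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def role_of(self, name: str) -> Role:
        try:
            return self._by_name[name].role
        except KeyError:
            raise ValueError(f"unknown variable {name!r}") from None

    @property
    def causal(self) -> list[str]:
        return [s.name for s in self._specs if s.role == "causal"]

    @property
    def outcomes(self) -> list[str]:
        return [s.name for s in self._specs if s.role == "outcome"]

    def restrict(self, keep: Sequence[str]) -> "RoleAssignment":
        keep_set = set(keep)
        return RoleAssignment([s for s in self._specs if s.name in keep_set])


@dataclass(frozen=True)
class TraceRecord:
    phase: Literal["forward", "backward"]
    edge: tuple[str, str]
    action: Literal["insert", "delete"]
    score_after: float


class SearchTrace(list):
    """Ordered accepted-move records; scores are non-decreasing within a phase."""

    def validate(self) -> None:
        by_phase: dict[str, list[float]] = {}
        for rec in self:
            by_phase.setdefault(rec.phase, []).append(rec.score_after)
        for phase, scores in by_phase.items():
            for a, b in zip(scores, scores[1:]):
                if b <= a:
                    raise AssertionError(f"non-increasing score in {phase} phase")


@dataclass
class SearchResult:
    """Outcome of a full grouped greedy search."""

    graph: Dag
    score: float
    trace: SearchTrace
    retained_variables: list[str]
    pruned_variables: list[str] = field(default_factory=list)
    pruned_marginal_scores: dict[str, float] = field(default_factory=dict)


def allowed_edge(x: str, y: str, roles: RoleAssignment) -> bool:
    """True iff an edge x→y is admissible: its source must be a causal variable."""
    if x == y:
        raise ValueError("self-edges are never considered")
    rx = roles.role_of(x)
    roles.role_of(y)  # raises for unknown y
    return rx == "causal"


def _validate(d: Dataset, roles: RoleAssignment) -> None:
    names = set(d.names)
    missing = [s.name for s in roles if s.name not in names]
    if missing:
        raise ValueError(f"role assignment names absent from dataset: {missing}")
    extra = names - {s.name for s in roles}
    if extra:
        raise ValueError(f"dataset columns without a role: {sorted(extra)}")
    if d.n < d.p:
        logger.warning("n (%d) < p (%d): scores may be unstable", d.n, d.p)


def greedy_forward(
    d: Dataset,
    roles: RoleAssignment,
    cache: ScoreCache | None = None,
) -> tuple[Dag, SearchTrace]:
    """Greedy forward search: single-edge insertions from the empty graph.

    Each iteration scores every absent admissible edge whose insertion keeps
    the graph acyclic and inserts the one with the largest strictly positive
    gain; stops when none remains.  Candidates whose scoring degenerates
    (collinear parents) are skipped with a warning.
    """
    _validate(d, roles)
    cache = cache if cache is not None else ScoreCache()
    nodes = [s.name for s in roles]
    g = Dag(nodes)
    score = graph_score(d, g, cache)
    trace = SearchTrace()
    while True:
        best: tuple[str, str] | None = None
        best_delta = 0.0
        for x in nodes:
            if roles.role_of(x) == "outcome":
                continue
            for y in nodes:
                if x == y or g.has_edge(x, y):
                    continue
                if g.has_path(y, x):  # insertion would close a cycle
                    continue
                try:
                    delta = delta_insert(d, g, x, y, cache)
                except DegenerateModelError as err:
                    logger.warning("skipping candidate %s→%s: %s", x, y, err)
                    continue
                if delta > best_delta + SCORE_TOL:
                    best, best_delta = (x, y), delta
        if best is None or best_delta <= SCORE_TOL:
            break
        g = g.with_edge(*best)
        score += best_delta
        trace.append(TraceRecord("forward", best, "insert", score))
        logger.info("FORWARD insert %s→%s score=%.6f", best[0], best[1], score)
    return g, trace


def greedy_backward(
    d: Dataset,
    g: Dag,
    roles: RoleAssignment,
    cache: ScoreCache | None = None,
) -> tuple[Dag, SearchTrace]:
    """Greedy backward search: single-edge deletions with the largest gain.

    Removal only relaxes the group constraint, so no admissibility check is
    needed; stops when no deletion strictly improves the score.
    """
    _validate(d, roles)
    if not is_acyclic(g):
        raise GraphStructureError("backward search requires an acyclic input graph")
    cache = cache if cache is not None else ScoreCache()
    score = graph_score(d, g, cache)
    trace = SearchTrace()
    while True:
        best: tuple[str, str] | None = None
        best_delta = 0.0
        for x, y in g.sorted_edges():
            try:
                delta = delta_delete(d, g, x, y, cache)
            except DegenerateModelError as err:
                logger.warning("skipping deletion %s→%s: %s", x, y, err)
                continue
            if delta > best_delta + SCORE_TOL:
                best, best_delta = (x, y), delta
        if best is None or best_delta <= SCORE_TOL:
            break
        g = g.without_edge(*best)
        score += best_delta
        trace.append(TraceRecord("backward", best, "delete", score))
        logger.info("BACKWARD delete %s→%s score=%.6f", best[0], best[1], score)
    return g, trace


def fit_gges(d: Dataset, roles: RoleAssignment) -> SearchResult:
    """Full grouped greedy search: forward phase, then backward phase.

    The final score is recomputed from scratch and checked against the phase
    ordering (final ≥ forward-final ≥ empty-graph score).
    """
    _validate(d, roles)
    cache = ScoreCache()
    empty_score = graph_score(d, Dag([s.name for s in roles]), cache)
    g_fwd, trace_fwd = greedy_forward(d, roles, cache)
    fwd_score = graph_score(d, g_fwd, cache)
    g_final, trace_bwd = greedy_backward(d, g_fwd, roles, cache)
    final_score = graph_score(d, g_final)  # fresh, uncached recomputation
    assert final_score >= fwd_score - SCORE_TOL
    assert fwd_score >= empty_score - SCORE_TOL
    trace = SearchTrace(trace_fwd + trace_bwd)
    trace.validate()
    for x, _y in g_final.edges:
        assert roles.role_of(x) == "causal", "edge out of an outcome variable"
    return SearchResult(
        graph=g_final,
        score=final_score,
        trace=trace,
        retained_variables=list(g_final.nodes),
    )


def prune_isolated(r: SearchResult, d: Dataset | None = None) -> SearchResult:
    """Drop degree-0 (unconnected) variables from a search result.

    Unconnected variables carry no causal information in the fitted graph and
    are treated as non-significant.  The reported score is recomputed over the
    retained variables only when a dataset is supplied; the dropped marginal
    local-score terms are recorded separately in ``pruned_marginal_scores``.
    """
    isolated = [n for n in r.graph.nodes if r.graph.degree(n) == 0]
    if not isolated:
        return r
    retained = [n for n in r.graph.nodes if n not in isolated]
    graph = r.graph.subgraph(retained)
    marginals = dict(r.pruned_marginal_scores)
    score = r.score
    if d is not None:
        for name in isolated:
            marginals[name] = local_score(d, name, ())
        score = r.score - sum(marginals[name] for name in isolated)
    logger.info("PRUNE removed %d unconnected variables: %s", len(isolated), isolated)
    return replace(
        r,
        graph=graph,
        score=score,
        retained_variables=retained,
        pruned_variables=r.pruned_variables + isolated,
        pruned_marginal_scores=marginals,
    )
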