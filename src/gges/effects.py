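"""Causal-effect quantification: IDA adjustment estimates and exact total effects.

IDA (intervention do-calculus adjustment) estimates the total causal effect of
a unit intervention on ``x`` upon ``y`` by the coefficient of ``x`` in the
least-squares regression of ``y`` on ``x`` together with ``x``'s graph
parents — the parent set blocks every back-door path, so under the linear
model the coefficient is the total effect.  On an equivalence class the parent
set of ``x`` is not unique; :func:`ida_multiset` enumerates the locally valid
parent configurations and summarizes them conservatively by the minimum
absolute estimate.

For a known weighted linear structural equation model, the total causal effect
(TCE) is exact: the sum over directed paths x ⇝ y of the products of edge
coefficients, computed in closed form from the weight matrix.  TCE is the
ground truth against which IDA estimates are validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .graphs import Dag, Pdag
from .scoring import Dataset, DegenerateModelError, regression_coefficients

__all__ = ["EffectEstimate", "SemSpec", "ida", "ida_multiset", "tce", "ida_table"]


@dataclass(frozen=True)
class EffectEstimate:
    """A single source→target causal-effect estimate.

    ``n_equivalent`` counts the equivalence-class parent configurations
    considered; it is 1 (and aggregation "single") whenever the graph is fully
    directed at the source.
    """

    source: str
    target: str
    ida: float
    n_equivalent: int = 1
    aggregation: Literal["single", "min_abs"] = "single"

    def __post_init__(self) -> None:
        if self.n_equivalent < 1:
            raise ValueError("n_equivalent must be >= 1")


@dataclass(frozen=True)
class SemSpec:
    """A weighted linear-Gaussian structural equation model.

    Each node equals its intercept plus the weighted sum of its parents plus
    independent Gaussian noise.  ``weights`` must be keyed exactly by the
    DAG's edges and every noise scale must be positive.
    """

    dag: Dag
    weights: Mapping[tuple[str, str], float]
    noise_sd: Mapping[str, float]
    intercepts: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.dag.edges):
            raise ValueError("weights must be keyed exactly by the DAG's edges")
        missing = [n for n in self.dag.nodes if n not in self.noise_sd]
        if missing:
            raise ValueError(f"missing noise scales for {missing}")
        bad = [n for n, s in self.noise_sd.items() if s <= 0]
        if bad:
            raise ValueError(f"non-positive noise scale for {bad}")

    def intercept_of(self, node: str) -> float:
        return 0.0 if self.intercepts is None else self.intercepts.get(node, 0.0)

    def weight_matrix(self) -> np.ndarray:
        """W with W[i, j] = coefficient of edge nodes[i] → nodes[j]."""
        idx = {n: i for i, n in enumerate(self.dag.nodes)}
        w = np.zeros((len(idx), len(idx)))
        for (u, v), b in self.weights.items():
            w[idx[u], idx[v]] = b
        return w


def _adjusted_coefficient(d: Dataset, x: str, y: str, parents: tuple[str, ...]) -> float:
    regressors = (x, *parents)
    coefs = regression_coefficients(d, y, regressors)
    return float(coefs[0])


def ida(d: Dataset, g: Dag, x: str, y: str) -> EffectEstimate:
    """Parent-adjustment IDA estimate of the effect of ``x`` on ``y`` in ``g``.

    Regresses ``y`` on ``{x} ∪ Pa_g(x)`` and reports the coefficient of ``x``.
    If ``y`` is a parent of ``x`` it is a non-descendant, so the effect is 0
    by definition.
    """
    if x == y:
        raise ValueError("source and target must differ")
    pa = g.parents(x)
    if y in pa:
        return EffectEstimate(x, y, 0.0)
    return EffectEstimate(x, y, _adjusted_coefficient(d, x, y, pa))


def _valid_parent_extensions(p: Pdag, x: str) -> list[tuple[str, ...]]:
    """Locally valid parent sets of ``x`` in the (maximally oriented) class.

    Each subset S of x's undirected neighbors may be oriented into x provided
    doing so creates no new collider at x: S must be a clique, and each member
    must be adjacent to every existing directed parent.  In a maximally
    oriented PDAG the latter holds automatically, but it is cheap to check.
    """
    base = p.directed_parents(x)
    sibs = p.undirected_neighbors(x)
    valid: list[tuple[str, ...]] = []
    for r in range(len(sibs) + 1):
        for s in combinations(sibs, r):
            clique = all(p.adjacent(a, b) for a, b in combinations(s, 2))
            linked = all(p.adjacent(a, b) for a in s for b in base)
            if clique and linked:
                valid.append(tuple((*base, *s)))
    return valid


def ida_multiset(d: Dataset, p: Pdag, x: str, y: str) -> EffectEstimate:
    """IDA over an equivalence class: one estimate per valid parent set of ``x``,
    aggregated by minimum absolute value."""
    if x == y:
        raise ValueError("source and target must differ")
    parent_sets = _valid_parent_extensions(p, x)
    estimates = []
    for pa in parent_sets:
        if y in pa:
            estimates.append(0.0)
        else:
            estimates.append(_adjusted_coefficient(d, x, y, pa))
    value = min(estimates, key=abs)
    agg: Literal["single", "min_abs"] = "single" if len(estimates) == 1 else "min_abs"
    return EffectEstimate(x, y, value, n_equivalent=len(estimates), aggregation=agg)


def tce(spec: SemSpec, x: str, y: str) -> float:
    """Exact total causal effect of ``x`` on ``y`` in a weighted linear SEM.

    Equals the sum over all directed paths x ⇝ y of the product of edge
    weights, evaluated in closed form as the (x, y) entry of (I − W)⁻¹ − I.
    Zero when no directed path exists.
    """
    nodes = spec.dag.nodes
    if x not in nodes or y not in nodes:
        raise ValueError(f"{x!r} or {y!r} not in the SEM")
    if x == y:
        return 1.0
    w = spec.weight_matrix()
    total = np.linalg.inv(np.eye(len(nodes)) - w) - np.eye(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    return float(total[idx[x], idx[y]])


def ida_table(
    d: Dataset,
    g: Dag,
    outcome: str,
    *,
    multiset: bool = False,
    roles=None,
    standardize: bool = False,
) -> pd.DataFrame:
    """Ranked per-variable IDA scores for ``outcome``.

    One row per non-outcome node of ``g``: variable, signed ida, |ida| and
    rank, sorted by |ida| descending with ties broken by input order.  With
    ``multiset=True`` (requires ``roles``) effects are aggregated over the
    equivalence class of ``g`` by minimum absolute value.  ``standardize``
    z-scores all columns first, giving effects in SD units.
    """
    if outcome not in g.nodes:
        raise ValueError(f"outcome {outcome!r} not in graph")
    if standardize:
        values = (d.values - d.values.mean(axis=0)) / d.values.std(axis=0)
        d = Dataset(values, d.variables)
    if multiset:
        if roles is None:
            raise ValueError("multiset IDA requires a role assignment")
        from .graphs import cpdag_of

        cls = cpdag_of(g, roles)
    sources = [n for n in g.nodes if n != outcome
               and (roles is None or roles.role_of(n) == "causal")]
    rows = []
    for order, x in enumerate(sources):
        try:
            est = ida_multiset(d, cls, x, outcome) if multiset else ida(d, g, x, outcome)
        except DegenerateModelError as err:
            raise DegenerateModelError(f"IDA for {x!r}: {err}") from err
        rows.append({"variable": x, "ida": est.ida, "abs_ida": abs(est.ida),
                     "n_equivalent": est.n_equivalent, "_order": order})
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=["variable", "ida", "abs_ida", "rank"])
    table = table.sort_values(
        ["abs_ida", "_order"], ascending=[False, True], kind="stable"
    ).drop(columns="_order").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
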