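"""Decomposable Gaussian BIC scoring of graphs against tabular data.

Each variable's local score is the maximized Gaussian log-likelihood of its
linear regression on its graph parents (with intercept), minus a BIC penalty
of (k/2)·log n where k counts the free parameters: the |Pa| coefficients, the
intercept and the residual variance.  The graph score is the sum of local
scores over nodes, so single-edge changes re-score exactly one node.

Regressions are solved from the centered cross-product (Gram) matrix, computed
once per dataset, so a local score costs O(|Pa|³) independent of n.  The ML
(1/n) residual-variance estimator is used inside the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .graphs import Dag

__all__ = [
    "Dataset",
    "ScoreCache",
    "DegenerateModelError",
    "local_score",
    "graph_score",
    "delta_insert",
    "delta_delete",
    "regression_coefficients",
]

# Residual variance below this fraction of the child's marginal variance is
# treated as an exact fit: the Gaussian log-likelihood is unbounded there.
_ZERO_RESIDUAL_REL_TOL = 1e-12


class DegenerateModelError(ValueError):
    """Singular design matrix or (numerically) zero residual variance."""


@dataclass
class Dataset:
    """An n×p complete numeric data table with per-variable metadata.

    Invariants enforced at construction: all values finite, every column has
    positive variance, n ≥ 3.  ``n < p`` is allowed (high-dimensional scoring
    still works for small parent sets) but worth a warning upstream.
    """

    values: np.ndarray
    variables: list  # list[VariableSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if p != len(self.variables):
            raise ValueError(f"{p} columns but {len(self.variables)} variable specs")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if n < 3:
            raise ValueError(f"need at least 3 rows, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dataset contains non-finite values")
        variances = self.values.var(axis=0)
        dead = [names[j] for j in np.flatnonzero(variances <= 0)]
        if dead:
            raise ValueError(f"constant columns not allowed: {dead}")
        self._index = {name: j for j, name in enumerate(names)}
        self._means = self.values.mean(axis=0)
        centered = self.values - self._means
        # centered cross-product matrix; all regressions are solved from it
        self._gram = centered.T @ centered

    # -- basic access ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._index[name]]

    def column_index(self, name: str) -> int:
        return self._index[name]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, variables: Sequence) -> "Dataset":
        names = [v.name for v in variables]
        return cls(frame.loc[:, names].to_numpy(dtype=float), list(variables))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def subset(self, keep: Sequence[str]) -> "Dataset":
        keep = list(keep)
        cols = [self._index[name] for name in keep]
        specs = [self.variables[j] for j in cols]
        return Dataset(self.values[:, cols], specs)

    # -- regression engine ----------------------------------------------
    def _solve(self, child: str, parents: Sequence[str]) -> tuple[np.ndarray, float]:
        """Return (coefficients for parents, ML residual variance) of the
        centered regression of child on parents; intercept handled by centering."""
        y = self._index[child]
        n = self.n
        if not parents:
            return np.empty(0), self._gram[y, y] / n
        idx = [self._index[v] for v in parents]
        sxx = self._gram[np.ix_(idx, idx)]
        sxy = self._gram[idx, y]
        try:
            coef = scipy.linalg.solve(sxx, sxy, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            raise DegenerateModelError(
                f"collinear parent set {sorted(parents)} for {child!r}")
        # guard against near-singular systems that solve without raising
        if not np.all(np.isfinite(coef)):
            raise DegenerateModelError(
                f"collinear parent set {sorted(parents)} for {child!r}")
        rss = self._gram[y, y] - float(sxy @ coef)
        if rss < -1e-6 * self._gram[y, y]:
            raise DegenerateModelError(
                f"ill-conditioned parent set {sorted(parents)} for {child!r}")
        return coef, max(rss, 0.0) / n


@dataclass
class ScoreCache:
    """Memoized local scores keyed by (child, sorted parent tuple)."""

    _store: dict = field(default_factory=dict)

    def get(self, child: str, parents: tuple[str, ...]):
        return self._store.get((child, parents))

    def put(self, child: str, parents: tuple[str, ...], value: float) -> None:
        self._store[(child, parents)] = value


def local_score(
    d: Dataset,
    child: str,
    parents: Iterable[str] = (),
    cache: ScoreCache | None = None,
) -> float:
    """Gaussian BIC local score of ``child`` given ``parents`` (larger is better).

    score = −(n/2)·(log(2π σ̂²) + 1) − (k/2)·log n with σ̂² the ML residual
    variance and k = |parents| + 2.

    Raises :class:`DegenerateModelError` for collinear parents or a
    numerically exact fit (unbounded likelihood).
    """
    parents = tuple(sorted(set(parents)))
    if child in parents:
        raise ValueError(f"{child!r} cannot be its own parent")
    if cache is not None:
        hit = cache.get(child, parents)
        if hit is not None:
            return hit
    n = d.n
    _, sigma2 = d._solve(child, parents)
    var_child = d._gram[d.column_index(child), d.column_index(child)] / n
    if sigma2 < _ZERO_RESIDUAL_REL_TOL * var_child:
        raise DegenerateModelError(
            f"zero residual variance regressing {child!r} on {sorted(parents)}")
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = len(parents) + 2
    score = loglik - 0.5 * k * math.log(n)
    if cache is not None:
        cache.put(child, parents, score)
    return score


def graph_score(d: Dataset, g: Dag, cache: ScoreCache | None = None) -> float:
    """Sum of local scores over all nodes of ``g`` — the graph score f(G, D)."""
    unknown = [v for v in g.nodes if v not in d._index]
    if unknown:
        raise ValueError(f"graph nodes absent from dataset: {unknown}")
    total = 0.0
    for node in g.nodes:
        try:
            total += local_score(d, node, g.parents(node), cache)
        except DegenerateModelError as err:
            raise DegenerateModelError(f"node {node!r}: {err}") from err
    return total


def delta_insert(
    d: Dataset, g: Dag, x: str, y: str, cache: ScoreCache | None = None
) -> float:
    """Exact graph-score change from inserting x→y (decomposable update)."""
    if g.has_edge(x, y):
        raise ValueError(f"edge ({x!r}, {y!r}) already present")
    pa = g.parents(y)
    return local_score(d, y, (*pa, x), cache) - local_score(d, y, pa, cache)


def delta_delete(
    d: Dataset, g: Dag, x: str, y: str, cache: ScoreCache | None = None
) -> float:
    """Exact graph-score change from deleting the existing edge x→y."""
    if not g.has_edge(x, y):
        raise ValueError(f"edge ({x!r}, {y!r}) not present")
    pa = g.parents(y)
    reduced = tuple(v for v in pa if v != x)
    return local_score(d, y, reduced, cache) - local_score(d, y, pa, cache)


def regression_coefficients(
    d: Dataset, response: str, regressors: Sequence[str]
) -> np.ndarray:
    """Least-squares coefficients (intercept excluded) of ``response`` on
    ``regressors``, in the given regressor order."""
    coef, _ = d._solve(response, list(regressors))
    return coef
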