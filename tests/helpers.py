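"""Shared test utilities: an independent naive greedy oracle, exhaustive DAG
enumeration, and role-assignment shorthand.

The oracle deliberately shares no code with the package's search or scoring:
local likelihoods come from explicit least-squares design matrices
(numpy.linalg.lstsq), the graph score is recomputed in full at every
candidate move, and acyclicity is checked by depth-first search on raw edge
sets.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np

from gges import RoleAssignment, VariableSpec


def make_roles(names, outcomes=()):
    outcomes = set(outcomes)
    return RoleAssignment(
        [VariableSpec(n, "outcome" if n in outcomes else "causal") for n in names]
    )


# ---------------------------------------------------------------------------
# naive scoring and greedy search (full rescans; no caching; no shared code)

def naive_local_bic(X: np.ndarray, child: int, parents: tuple[int, ...]) -> float:
    n = X.shape[0]
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in parents])
    y = X[:, child]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return loglik - 0.5 * (len(parents) + 2) * math.log(n)


def naive_graph_score(X: np.ndarray, edges: set[tuple[int, int]]) -> float:
    p = X.shape[1]
    total = 0.0
    for child in range(p):
        parents = tuple(sorted(u for u, v in edges if v == child))
        total += naive_local_bic(X, child, parents)
    return total


def _has_cycle(p: int, edges: set[tuple[int, int]]) -> bool:
    adj = {i: [v for u, v in edges if u == i] for i in range(p)}
    state = [0] * p  # 0 unseen, 1 in stack, 2 done

    def dfs(u):
        state[u] = 1
        for v in adj[u]:
            if state[v] == 1 or (state[v] == 0 and dfs(v)):
                return True
        state[u] = 2
        return False

    return any(state[i] == 0 and dfs(i) for i in range(p))


def naive_gges(X: np.ndarray, outcome_idx: set[int], tol: float = 1e-9):
    """Forward then backward greedy search with full rescoring each step.

    Returns (edge set, final score).  Candidate order and tie handling mirror
    the documented contract: lexicographic (source, target), strict
    improvement with a 1e-9 tolerance.
    """
    p = X.shape[1]
    edges: set[tuple[int, int]] = set()
    score = naive_graph_score(X, edges)
    while True:  # forward
        best, best_score = None, score
        for x in range(p):
            if x in outcome_idx:
                continue
            for y in range(p):
                if x == y or (x, y) in edges:
                    continue
                cand = edges | {(x, y)}
                if _has_cycle(p, cand):
                    continue
                s = naive_graph_score(X, cand)
                if s > best_score + tol:
                    best, best_score = (x, y), s
        if best is None:
            break
        edges.add(best)
        score = best_score
    while True:  # backward
        best, best_score = None, score
        for x, y in sorted(edges):
            s = naive_graph_score(X, edges - {(x, y)})
            if s > best_score + tol:
                best, best_score = (x, y), s
        if best is None:
            break
        edges.discard(best)
        score = best_score
    return edges, score


# ---------------------------------------------------------------------------
# exhaustive DAG enumeration for small-graph oracle tests

def all_dags(names):
    """Every DAG on the given nodes, as lists of (parent, child) name pairs."""
    pairs = list(combinations(range(len(names)), 2))
    out = []
    for states in product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (i, j), st in zip(pairs, states):
            if st == 1:
                edges.add((i, j))
            elif st == 2:
                edges.add((j, i))
        if not _has_cycle(len(names), edges):
            out.append([(names[u], names[v]) for u, v in sorted(edges)])
    return out


def skeleton_and_vstructs(nodes, edges):
    """Class signature: (skeleton, v-structures) of an edge list."""
    eset = set(edges)
    skel = frozenset(frozenset(e) for e in eset)

    def adjacent(a, b):
        return (a, b) in eset or (b, a) in eset

    vs = set()
    for y in nodes:
        pa = sorted(u for u, v in eset if v == y)
        for a, b in combinations(pa, 2):
            if not adjacent(a, b):
                vs.add((a, y, b))
    return skel, frozenset(vs)
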