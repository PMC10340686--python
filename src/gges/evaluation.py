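"""Structural accuracy metrics and the k-fold cross-validation stability harness.

Adjacency precision/recall (AP, AR) compare skeletons — edges with direction
ignored — while arrowhead precision/recall (AHP, AHR) compare directed
endpoints: an estimated arrowhead x→y is correct only if the reference also
directs x→y.  Undirected edges of a PDAG contribute adjacencies but no
arrowheads.  A precision whose denominator is zero (no estimated edges) is
reported as ``None`` ("undefined"), never silently as 0 or 1.

No ground-truth graph exists for observational cohorts, so the
cross-validation harness evaluates each training-fold graph against the
full-data graph and reports per-edge stability: the fraction of folds whose
fitted graph contains each edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Union

import numpy as np
import pandas as pd

from .graphs import Dag, Pdag
from .scoring import Dataset
from .search import RoleAssignment, fit_gges

__all__ = [
    "MetricReport",
    "CvReport",
    "adjacency_metrics",
    "arrowhead_metrics",
    "metric_report",
    "cross_validate",
]

Graph = Union[Dag, Pdag]


@dataclass(frozen=True)
class MetricReport:
    """AP/AR/AHP/AHR with the counts they are computed from.

    ``ap``/``ahp`` are ``None`` when their denominator (estimated edges or
    estimated arrowheads) is zero.
    """

    ap: float | None
    ar: float
    ahp: float | None
    ahr: float
    adjacency_counts: tuple[int, int, int]  # (tp, fp, fn)
    arrowhead_counts: tuple[int, int, int]

    def to_dict(self) -> dict:
        return asdict(self)


def _skeleton(g: Graph) -> frozenset[frozenset[str]]:
    return g.skeleton()


def _arrowheads(g: Graph) -> frozenset[tuple[str, str]]:
    if isinstance(g, Dag):
        return frozenset(g.edges)
    return frozenset(g.directed_edges)


def _check_nodes(est: Graph, ref: Graph) -> None:
    if set(est.nodes) != set(ref.nodes):
        raise ValueError("estimated and reference graphs have different node sets")


def adjacency_metrics(est: Graph, ref: Graph) -> tuple[float | None, float, tuple[int, int, int]]:
    """Skeleton precision and recall: (AP, AR, (tp, fp, fn))."""
    _check_nodes(est, ref)
    se, sr = _skeleton(est), _skeleton(ref)
    tp = len(se & sr)
    fp = len(se - sr)
    fn = len(sr - se)
    ap = tp / (tp + fp) if (tp + fp) else None
    ar = tp / (tp + fn) if (tp + fn) else 1.0
    return ap, ar, (tp, fp, fn)


def arrowhead_metrics(est: Graph, ref: Graph) -> tuple[float | None, float, tuple[int, int, int]]:
    """Directed-endpoint precision and recall: (AHP, AHR, (tp, fp, fn)).

    An arrowhead is an ordered directed pair x→y; it counts as correct only if
    the reference directs the same pair identically.
    """
    _check_nodes(est, ref)
    ae, ar_ = _arrowheads(est), _arrowheads(ref)
    tp = len(ae & ar_)
    fp = len(ae - ar_)
    fn = len(ar_ - ae)
    ahp = tp / (tp + fp) if (tp + fp) else None
    ahr = tp / (tp + fn) if (tp + fn) else 1.0
    return ahp, ahr, (tp, fp, fn)


def metric_report(est: Graph, ref: Graph) -> MetricReport:
    ap, ar, adj = adjacency_metrics(est, ref)
    ahp, ahr, arrow = arrowhead_metrics(est, ref)
    return MetricReport(ap, ar, ahp, ahr, adj, arrow)


@dataclass
class CvReport:
    """Per-fold structural metrics plus cross-fold edge stability."""

    fold_reports: list[MetricReport]
    edge_stability: dict[tuple[str, str], float]
    k: int
    seed: int
    reference_graph: Dag | None = None

    def __post_init__(self) -> None:
        if self.k != len(self.fold_reports):
            raise ValueError("k must equal the number of fold reports")
        bad = {e: f for e, f in self.edge_stability.items() if not 0.0 <= f <= 1.0}
        if bad:
            raise ValueError(f"stability fractions outside [0, 1]: {bad}")

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "fold_reports": [r.to_dict() for r in self.fold_reports],
            "edge_stability": [
                {"source": u, "target": v, "fraction": f}
                for (u, v), f in sorted(self.edge_stability.items())
            ],
        }
        return json.dumps(payload, indent=2)

    def stability_frame(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "fraction": f}
                for (u, v), f in sorted(self.edge_stability.items())]
        return pd.DataFrame(rows, columns=["source", "target", "fraction"])


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def cross_validate(
    d: Dataset, roles: RoleAssignment, k: int = 10, seed: int = 0
) -> CvReport:
    """Seeded k-fold refitting: fold graphs vs the full-data graph.

    Each fold's training set (all rows outside the fold) is refitted with the
    grouped greedy search; the fitted graph is compared with the full-data
    graph by adjacency and arrowhead metrics, and each full-data-or-fold edge's
    presence is tallied across folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if d.n < k:
        raise ValueError(f"cannot split {d.n} rows into {k} folds")
    full = fit_gges(d, roles).graph
    folds = _fold_indices(d.n, k, seed)
    reports: list[MetricReport] = []
    tally: dict[tuple[str, str], int] = {}
    for test_idx in folds:
        mask = np.ones(d.n, dtype=bool)
        mask[test_idx] = False
        n_train = int(mask.sum())
        if n_train < 3:
            raise ValueError(f"training fold of {n_train} rows is too small to score")
        train = Dataset(d.values[mask], d.variables)
        fold_graph = fit_gges(train, roles).graph
        reports.append(metric_report(fold_graph, full))
        for e in fold_graph.edges:
            tally[e] = tally.get(e, 0) + 1
    stability = {e: c / k for e, c in tally.items()}
    for e in full.edges:
        stability.setdefault(e, 0.0)
    return CvReport(reports, stability, k=k, seed=seed, reference_graph=full)
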