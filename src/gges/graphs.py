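"""Directed and partially directed graph structures for constrained causal search.

A :class:`Dag` is a fully directed acyclic graph over named variables; a
:class:`Pdag` additionally carries undirected edges and is used to represent
(background-knowledge-restricted) Markov equivalence classes.  Node order is
part of both structures and is the universal deterministic tie-breaker: all
iteration, serialization and extension choices follow input column order.

Equivalence-class machinery (v-structures, Meek orientation rules, consistent
extensions) lives here and is shared by the search, effect-estimation and
evaluation layers.  The two-group background knowledge — outcome variables may
not cause anything — is threaded through every orientation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .search import RoleAssignment

__all__ = [
    "Dag",
    "Pdag",
    "GraphStructureError",
    "OrientationConflictError",
    "is_acyclic",
    "cpdag_of",
    "meek_closure",
    "consistent_extension",
]


class GraphStructureError(ValueError):
    """A graph violates a structural invariant (unknown node, cycle, ...)."""


class OrientationConflictError(GraphStructureError):
    """Orientation rules force both directions of the same edge."""


def _check_edges(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> None:
    known = set(nodes)
    for u, v in edges:
        if u not in known or v not in known:
            raise GraphStructureError(f"edge ({u!r}, {v!r}) references an unknown node")
        if u == v:
            raise GraphStructureError(f"self-loop on {u!r}")


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph with a stable node order.

    ``edges`` are ordered (parent, child) pairs.  Acyclicity is verified at
    construction; instances are immutable, so it holds for the lifetime of the
    object.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise GraphStructureError("duplicate node names")
        edges = frozenset((str(u), str(v)) for u, v in edges)
        _check_edges(nodes, edges)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        if not is_acyclic(self):
            raise GraphStructureError("directed cycle in graph")

    # -- queries ---------------------------------------------------------
    def parents(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise GraphStructureError(f"unknown node {node!r}")
        return tuple(u for u in self.nodes if (u, node) in self.edges)

    def children(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise GraphStructureError(f"unknown node {node!r}")
        return tuple(v for v in self.nodes if (node, v) in self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for u, v in self.edges if node in (u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def adjacent(self, u: str, v: str) -> bool:
        return (u, v) in self.edges or (v, u) in self.edges

    def has_path(self, u: str, v: str) -> bool:
        """True iff a directed path u ⇝ v exists (u == v counts as a path)."""
        return u == v or nx.has_path(self.to_networkx(), u, v)

    def with_edge(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, self.edges - {(u, v)})

    def subgraph(self, keep: Sequence[str]) -> "Dag":
        keep_set = set(keep)
        return Dag(
            tuple(n for n in self.nodes if n in keep_set),
            {(u, v) for u, v in self.edges if u in keep_set and v in keep_set},
        )

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Colliders x→y←z with x, z nonadjacent, as (x, y, z) with x < z in node order."""
        order = {n: i for i, n in enumerate(self.nodes)}
        out: set[tuple[str, str, str]] = set()
        for y in self.nodes:
            pa = self.parents(y)
            for i, x in enumerate(pa):
                for z in pa[i + 1:]:
                    if not self.adjacent(x, z):
                        a, b = sorted((x, z), key=order.__getitem__)
                        out.add((a, y, b))
        return out

    def topological_order(self) -> list[str]:
        """Deterministic topological order (ties broken by node order)."""
        g = self.to_networkx()
        return list(nx.lexicographical_topological_sort(
            g, key={n: i for i, n in enumerate(self.nodes)}.__getitem__))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def sorted_edges(self) -> list[tuple[str, str]]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return sorted(self.edges, key=lambda e: (order[e[0]], order[e[1]]))


@dataclass(frozen=True)
class Pdag:
    """Partially directed graph: directed plus undirected edges.

    Each unordered node pair appears in at most one edge set; the directed
    part is acyclic.  Undirected edges are stored as ordered-by-node-order
    pairs but compared as unordered.
    """

    nodes: tuple[str, ...]
    directed_edges: frozenset[tuple[str, str]]
    undirected_edges: frozenset[frozenset[str]]

    def __init__(
        self,
        nodes: Sequence[str],
        directed_edges: Iterable[tuple[str, str]] = (),
        undirected_edges: Iterable[Iterable[str]] = (),
    ):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise GraphStructureError("duplicate node names")
        directed = frozenset((str(u), str(v)) for u, v in directed_edges)
        undirected = frozenset(frozenset(map(str, e)) for e in undirected_edges)
        _check_edges(nodes, directed)
        for e in undirected:
            if len(e) != 2:
                raise GraphStructureError(f"undirected edge {set(e)} is not a pair")
        _check_edges(nodes, [tuple(e) for e in undirected])
        for u, v in directed:
            if frozenset((u, v)) in undirected:
                raise GraphStructureError(
                    f"pair ({u!r}, {v!r}) is both directed and undirected")
            if (v, u) in directed:
                raise GraphStructureError(f"both directions of ({u!r}, {v!r}) present")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "directed_edges", directed)
        object.__setattr__(self, "undirected_edges", undirected)
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        dg.add_edges_from(directed)
        if not nx.is_directed_acyclic_graph(dg):
            raise GraphStructureError("cycle in directed part of PDAG")

    # -- queries ---------------------------------------------------------
    def adjacent(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed_edges
            or (v, u) in self.directed_edges
            or frozenset((u, v)) in self.undirected_edges
        )

    def directed_parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u in self.nodes if (u, node) in self.directed_edges)

    def undirected_neighbors(self, node: str) -> tuple[str, ...]:
        return tuple(
            v for v in self.nodes
            if v != node and frozenset((node, v)) in self.undirected_edges
        )

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.directed_edges) | self.undirected_edges

    def is_fully_directed(self) -> bool:
        return not self.undirected_edges

    def sorted_directed(self) -> list[tuple[str, str]]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return sorted(self.directed_edges, key=lambda e: (order[e[0]], order[e[1]]))

    def sorted_undirected(self) -> list[tuple[str, str]]:
        order = {n: i for i, n in enumerate(self.nodes)}
        pairs = [tuple(sorted(e, key=order.__getitem__)) for e in self.undirected_edges]
        return sorted(pairs, key=lambda e: (order[e[0]], order[e[1]]))


def is_acyclic(g: Dag) -> bool:
    """True iff ``g`` contains no directed cycle.  Pure; never mutates."""
    return nx.is_directed_acyclic_graph(g.to_networkx())


def _role_forced(u: str, v: str, roles: "RoleAssignment") -> bool:
    """True iff the edge u→v cannot be reversed under the group constraint."""
    return roles.role_of(v) == "outcome"


def cpdag_of(g: Dag, roles: "RoleAssignment") -> Pdag:
    """Completed PDAG of ``g``'s equivalence class under the group constraint.

    Edges into outcome nodes and v-structure edges stay directed as in ``g``;
    the Meek closure then adds every further compelled orientation; all other
    edges are released as undirected.  Two DAGs with the same skeleton,
    v-structures and role-forced orientations map to the same Pdag.
    """
    missing = [n for n in g.nodes if n not in roles]
    if missing:
        raise GraphStructureError(f"roles missing for nodes {missing}")
    compelled: set[tuple[str, str]] = set()
    for x, y, z in g.v_structures():
        compelled.add((x, y))
        compelled.add((z, y))
    for u, v in g.edges:
        if _role_forced(u, v, roles):
            compelled.add((u, v))
    undirected = [e for e in g.edges if e not in compelled]
    p = Pdag(g.nodes, compelled, [frozenset(e) for e in undirected])
    return meek_closure(p, roles)


def meek_closure(p: Pdag, roles: "RoleAssignment") -> Pdag:
    """Apply Meek's orientation rules R1–R4, plus the group constraint, to fixpoint.

    The group constraint is treated as background knowledge: an undirected edge
    with exactly one outcome endpoint is oriented into the outcome node (an
    undirected edge between two outcome nodes is inconsistent, as is any rule
    firing that would direct an edge out of an outcome node).  Idempotent.

    Raises :class:`OrientationConflictError` if rules force both directions of
    an edge.
    """
    nodes = p.nodes
    directed: set[tuple[str, str]] = set(p.directed_edges)
    undirected: set[frozenset[str]] = set(p.undirected_edges)

    for u, v in directed:
        if roles.role_of(u) == "outcome":
            raise OrientationConflictError(
                f"directed edge {u!r}→{v!r} leaves an outcome variable")

    def orient(u: str, v: str) -> bool:
        """Direct u→v; returns True if anything changed."""
        pair = frozenset((u, v))
        if (u, v) in directed:
            return False
        if (v, u) in directed:
            raise OrientationConflictError(
                f"rules force both directions of edge ({u!r}, {v!r})")
        if roles.role_of(u) == "outcome":
            raise OrientationConflictError(
                f"orientation {u!r}→{v!r} would leave an outcome variable")
        undirected.discard(pair)
        directed.add((u, v))
        return True

    def adjacent(a: str, b: str) -> bool:
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    changed = True
    while changed:
        changed = False
        # Background knowledge: any undirected edge touching an outcome node.
        for pair in sorted(undirected, key=lambda e: sorted(e)):
            a, b = sorted(pair)
            ra, rb = roles.role_of(a), roles.role_of(b)
            if ra == "outcome" and rb == "outcome":
                raise OrientationConflictError(
                    f"undirected edge between outcome variables {a!r} and {b!r}")
            if rb == "outcome":
                changed |= orient(a, b)
            elif ra == "outcome":
                changed |= orient(b, a)
        for pair in sorted(undirected, key=lambda e: sorted(e)):
            a, b = tuple(pair)
            for x, y in ((a, b), (b, a)):
                # R1: z→x, x—y, z,y nonadjacent  ⇒ x→y
                if any((z, x) in directed and not adjacent(z, y)
                       for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R2: x→z→y and x—y  ⇒ x→y
                if any((x, z) in directed and (z, y) in directed
                       for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R3: x—z1, x—z2, z1→y, z2→y, z1,z2 nonadjacent  ⇒ x→y
                nbrs = [z for z in nodes if z not in (x, y)
                        and frozenset((x, z)) in undirected and (z, y) in directed]
                if any(not adjacent(z1, z2)
                       for i, z1 in enumerate(nbrs) for z2 in nbrs[i + 1:]):
                    changed |= orient(x, y)
                    break
                # R4: x—z, z→w, w→y, x—y (x adj w or x—w), z,y nonadjacent ⇒ x→y
                fired = False
                for z in nodes:
                    if z in (x, y) or frozenset((x, z)) not in undirected:
                        continue
                    for w in nodes:
                        if w in (x, y, z):
                            continue
                        if (z, w) in directed and (w, y) in directed \
                                and not adjacent(z, y) and adjacent(x, w):
                            changed |= orient(x, y)
                            fired = True
                            break
                    if fired:
                        break
                if fired:
                    break
            if changed:
                break  # re-scan from scratch after any orientation
    return Pdag(nodes, directed, undirected)


def consistent_extension(p: Pdag, roles: "RoleAssignment") -> Dag:
    """One acyclic fully directed extension of ``p`` (Dor–Tarsi algorithm).

    Preserves the directed part and the adjacency structure, creates no new
    v-structure, and respects the group constraint.  Deterministic: at every
    step the first eligible node in node order is consumed.

    Raises :class:`GraphStructureError` if no consistent extension exists.
    """
    p = meek_closure(p, roles)
    remaining = list(p.nodes)
    directed: set[tuple[str, str]] = set(p.directed_edges)
    undirected: set[frozenset[str]] = set(p.undirected_edges)
    oriented: set[tuple[str, str]] = set(directed)

    while remaining:
        # scan from the end of the node order: undirected ties then resolve as
        # earlier-node → later-node, the documented deterministic convention
        for x in reversed(remaining):
            live = set(remaining)
            out = [v for v in live if (x, v) in directed]
            if out:
                continue  # x is not a sink in the directed part
            und_nbrs = [v for v in live if frozenset((x, v)) in undirected]
            adj = set(und_nbrs) | {u for u in live if (u, x) in directed}
            # every undirected neighbor must be adjacent to all other neighbors
            ok = all(
                v == w or (v, w) in directed or (w, v) in directed
                or frozenset((v, w)) in undirected
                for v in und_nbrs for w in adj
            )
            if not ok:
                continue
            for v in und_nbrs:
                if roles.role_of(v) == "outcome":
                    raise GraphStructureError(
                        f"extension would direct {v!r}→{x!r} out of an outcome variable")
                oriented.add((v, x))
                undirected.discard(frozenset((x, v)))
            directed = {(u, v) for u, v in directed if u in live and v in live and u != x and v != x}
            undirected = {e for e in undirected if x not in e}
            remaining.remove(x)
            break
        else:
            raise GraphStructureError("PDAG admits no consistent acyclic extension")
    return Dag(p.nodes, oriented)
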