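"""File formats: edge-list CSV, DOT export, roles files, and datasets.

One strict CSV dialect everywhere: comma-separated, UTF-8, header row
required, ``.`` decimal, no index column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .graphs import Dag, GraphStructureError, Pdag
from .search import RoleAssignment

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_dot",
    "read_roles",
    "read_table",
]

Graph = Union[Dag, Pdag]


def write_edge_list(g: Graph, path) -> None:
    """Serialize a graph to CSV with columns source, target, type."""
    rows = []
    if isinstance(g, Dag):
        for u, v in g.sorted_edges():
            rows.append({"source": u, "target": v, "type": "directed"})
    else:
        for u, v in g.sorted_directed():
            rows.append({"source": u, "target": v, "type": "directed"})
        for u, v in g.sorted_undirected():
            rows.append({"source": u, "target": v, "type": "undirected"})
    frame = pd.DataFrame(rows, columns=["source", "target", "type"])
    frame.to_csv(path, index=False)


def read_edge_list(path, nodes=None) -> Graph:
    """Load an edge-list CSV; returns a Dag if fully directed, else a Pdag.

    ``nodes`` fixes the node universe and order; by default nodes are taken
    from the edges in order of first appearance.
    """
    frame = pd.read_csv(path)
    required = {"source", "target", "type"}
    if not required.issubset(frame.columns):
        raise GraphStructureError(f"edge list must have columns {sorted(required)}")
    if nodes is None:
        seen: list[str] = []
        for _, row in frame.iterrows():
            for name in (row["source"], row["target"]):
                if name not in seen:
                    seen.append(name)
        nodes = seen
    directed, undirected = [], []
    for _, row in frame.iterrows():
        kind = row["type"]
        if kind == "directed":
            directed.append((row["source"], row["target"]))
        elif kind == "undirected":
            undirected.append(frozenset((row["source"], row["target"])))
        else:
            raise GraphStructureError(f"unknown edge type {kind!r}")
    if undirected:
        return Pdag(nodes, directed, undirected)
    return Dag(nodes, directed)


def write_dot(g: Graph, path, highlight: list[str] | None = None) -> None:
    """Export a graph in DOT format for figure rendering."""
    highlight = set(highlight or [])
    lines = ["digraph causal {", "  rankdir=LR;", "  node [shape=ellipse];"]
    for n in g.nodes:
        attrs = ' [style=filled, fillcolor=lightgrey]' if n in highlight else ""
        lines.append(f'  "{n}"{attrs};')
    if isinstance(g, Dag):
        for u, v in g.sorted_edges():
            lines.append(f'  "{u}" -> "{v}";')
    else:
        for u, v in g.sorted_directed():
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in g.sorted_undirected():
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_roles(path, order) -> RoleAssignment:
    """Load a YAML/JSON name→role mapping; unlisted columns default to causal."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("roles file must map variable names to roles")
    return RoleAssignment.from_mapping(raw, order)


def read_table(path) -> pd.DataFrame:
    """Read a data CSV in the package dialect."""
    return pd.read_csv(path)
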