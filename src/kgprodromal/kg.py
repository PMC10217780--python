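"""Typed heterogeneous knowledge-graph data model, TSV I/O and transition structure.

The graph is a set of typed nodes (Disease, Symptom, Gene, Compound, ...)
joined by labelled edges.  Propagation (personalized PageRank) operates on a
column-stochastic transition matrix derived from the edge list; by default
edges are traversed in both directions and each column distributes its mass
uniformly over the node's neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NodeRecord",
    "EdgeRecord",
    "KnowledgeGraph",
    "TransitionModel",
    "GraphValidationError",
    "load_graph",
    "save_graph",
    "build_transition",
]


class GraphValidationError(ValueError):
    """Raised when node/edge tables violate the graph contract."""


@dataclass(frozen=True)
class NodeRecord:
    node_id: str
    node_type: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.node_id:
            raise GraphValidationError("node_id must be non-empty")
        if not self.node_type:
            raise GraphValidationError(f"node {self.node_id!r}: node_type must be non-empty")


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    predicate: str = "related_to"


@dataclass
class KnowledgeGraph:
    """Validated graph with a deterministic node order (sorted by node_id)."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    allow_self_loops: bool = False
    node_index: dict[str, int] = field(init=False, repr=False)
    _adjacency: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
        if dupes:
            raise GraphValidationError(f"duplicate node_id values: {dupes}")
        self.nodes = sorted(self.nodes, key=lambda n: n.node_id)
        self.node_index = {n.node_id: i for i, n in enumerate(self.nodes)}
        known = set(self.node_index)
        bad = [e for e in self.edges if e.source not in known or e.target not in known]
        if bad:
            missing = sorted({x for e in bad for x in (e.source, e.target) if x not in known})
            raise GraphValidationError(
                f"edges reference unknown node ids {missing}; offending rows: {bad[:10]}"
            )
        if not self.allow_self_loops:
            loops = [e for e in self.edges if e.source == e.target]
            if loops:
                raise GraphValidationError(f"self-loops not allowed: {loops[:10]}")
        self._adjacency = {i: set() for i in known}
        for e in self.edges:
            self._adjacency[e.source].add(e.target)
            self._adjacency[e.target].add(e.source)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def node_types(self) -> dict[str, str]:
        return {n.node_id: n.node_type for n in self.nodes}

    def neighbors(self, node_id: str) -> set[str]:
        """All nodes sharing an edge with node_id (undirected view)."""
        if node_id not in self._adjacency:
            raise KeyError(node_id)
        return set(self._adjacency[node_id])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, node_type=n.node_type, name=n.name)
        for e in self.edges:
            g.add_edge(e.source, e.target, predicate=e.predicate)
        return g


@dataclass
class TransitionModel:
    """Column-stochastic operator: column j spreads mass uniformly over j's neighbors.

    Columns with no out-neighbors under the chosen orientation are dangling;
    propagation redistributes their mass onto the restart vector.
    """

    matrix: sp.csr_matrix
    dangling_mask: np.ndarray
    orientation: str = "undirected"

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def load_graph(nodes_path: str | Path, edges_path: str | Path, allow_self_loops: bool = False) -> KnowledgeGraph:
    """Load a graph from TSV node and edge tables.

    ``nodes.tsv`` columns: node_id, node_type, name.
    ``edges.tsv`` columns: source, target, predicate.
    """
    nodes_df = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str).fillna("")
    for col in ("node_id", "node_type", "name"):
        if col not in nodes_df.columns:
            raise GraphValidationError(f"{nodes_path}: missing column {col!r}")
    for col in ("source", "target", "predicate"):
        if col not in edges_df.columns:
            raise GraphValidationError(f"{edges_path}: missing column {col!r}")
    nodes = [NodeRecord(r.node_id, r.node_type, r.name) for r in nodes_df.itertuples()]
    edges = [EdgeRecord(r.source, r.target, r.predicate) for r in edges_df.itertuples()]
    return KnowledgeGraph(nodes=nodes, edges=edges, allow_self_loops=allow_self_loops)


def save_graph(kg: KnowledgeGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    pd.DataFrame(
        [(n.node_id, n.node_type, n.name) for n in kg.nodes],
        columns=["node_id", "node_type", "name"],
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [(e.source, e.target, e.predicate) for e in kg.edges],
        columns=["source", "target", "predicate"],
    ).to_csv(edges_path, sep="\t", index=False)


def build_transition(kg: KnowledgeGraph, orientation: str = "undirected") -> TransitionModel:
    """Build the column-stochastic transition operator for propagation.

    orientation="undirected" (default) traverses every edge both ways;
    "directed" only follows source→target.
    """
    if kg.n_nodes == 0:
        raise GraphValidationError("cannot build a transition model for an empty graph")
    if orientation not in ("undirected", "directed"):
        raise ValueError(f"unknown orientation {orientation!r}")
    n = kg.n_nodes
    idx = kg.node_index
    rows: list[int] = []
    cols: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for e in kg.edges:
        s, t = idx[e.source], idx[e.target]
        pairs.add((t, s))  # mass flows source -> target: entry (target, source)
        if orientation == "undirected":
            pairs.add((s, t))
    for r, c in pairs:
        rows.append(r)
        cols.append(c)
    rows_a = np.array(rows, dtype=np.int64)
    cols_a = np.array(cols, dtype=np.int64)
    out_degree = np.bincount(cols_a, minlength=n).astype(float) if len(cols_a) else np.zeros(n)
    dangling = out_degree == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 1.0 / out_degree[cols_a] if len(cols_a) else np.array([])
    matrix = sp.csr_matrix((vals, (rows_a, cols_a)), shape=(n, n))
    return TransitionModel(matrix=matrix, dangling_mask=dangling, orientation=orientation)
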