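"""Patient-specific explanatory subnetworks around a focus node.

A prediction is explained by showing how the patient's entry concepts connect
to the focus node (e.g. the target disease) through the graph.  Relay nodes
lying on short entry→focus paths are ranked by the patient's propagated
signature value and truncated deterministically — a reproducible stand-in for
manual figure curation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .embedding import ConceptMapping
from .kg import EdgeRecord, KnowledgeGraph
from .records import PatientRecord

__all__ = ["PatientSubnetwork", "extract_subnetwork", "subnetwork_to_graphml"]


@dataclass
class PatientSubnetwork:
    focus: str
    entry_nodes: set[str]
    roles: dict[str, str]  # node_id -> entry | relay | focus
    edges: list[EdgeRecord]
    spokesig_value: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.roles)


def _bfs_distances(kg: KnowledgeGraph, sources: set[str], cutoff: int) -> dict[str, int]:
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier and d < cutoff:
        d += 1
        nxt = []
        for u in frontier:
            for v in kg.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def extract_subnetwork(kg: KnowledgeGraph, record: PatientRecord, mapping: ConceptMapping,
                       focus: str, spokesig_row: np.ndarray, node_ids: list[str],
                       max_hops: int = 2, top_k: int = 25) -> PatientSubnetwork:
    """Extract the top-k relay nodes on short paths between entry nodes and focus.

    A node qualifies as a relay candidate when dist(entry set, v) +
    dist(v, focus) ≤ max_hops; candidates are ranked by the patient's
    signature value (ties broken by node_id) and truncated to ``top_k``.
    The returned edge set is the induced subgraph on the included nodes.
    """
    if focus not in kg.node_index:
        raise KeyError(focus)
    entry = {mapping[c] for c in record.concept_ids() if c in mapping}
    if not entry:
        raise ValueError(f"patient {record.patient_id} has no entry node")
    value = dict(zip(node_ids, np.asarray(spokesig_row, dtype=float)))

    d_entry = _bfs_distances(kg, entry, max_hops)
    d_focus = _bfs_distances(kg, {focus}, max_hops)
    candidates = [
        v for v in kg.node_ids
        if v in d_entry and v in d_focus and d_entry[v] + d_focus[v] <= max_hops
        and v != focus and v not in entry
    ]
    if focus not in d_entry:
        warnings.warn(f"focus {focus} unreachable within {max_hops} hops of any entry node; "
                      "relay set is empty")
        candidates = []
    candidates.sort(key=lambda v: (-value.get(v, 0.0), v))
    relays = candidates[:top_k]

    roles = {focus: "focus"}
    for v in entry:
        roles[v] = "entry"
    for v in relays:
        roles[v] = "relay"
    included = set(roles)
    edges = [e for e in kg.edges if e.source in included and e.target in included]
    return PatientSubnetwork(
        focus=focus, entry_nodes=entry, roles=roles, edges=edges,
        spokesig_value={v: value.get(v, 0.0) for v in included})


def subnetwork_to_graphml(sub: PatientSubnetwork, kg: KnowledgeGraph,
                          path: str | Path) -> None:
    """Write the subnetwork with role/node_type/spokesig_value attributes."""
    types = kg.node_types()
    g = nx.Graph()
    for v, role in sub.roles.items():
        g.add_node(v, role=role, node_type=types[v],
                   spokesig_value=float(sub.spokesig_value.get(v, 0.0)))
    for e in sub.edges:
        g.add_edge(e.source, e.target, predicate=e.predicate)
    nx.write_graphml(g, str(path))
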