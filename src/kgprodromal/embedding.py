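"""Propagation embeddings: per-concept PSEVs and per-patient signature vectors.

A PSEV (propagated entry vector) is the stationary distribution of a
personalized PageRank walk whose restart distribution is weighted by how the
concept co-occurs with other mapped concepts across the cohort.  A patient's
signature (SPOKEsig) is the L1-normalized sum of the PSEV rows of the distinct
mapped concepts in the patient's record; each element is the propagated
relevance of one graph node for that patient.  The raw-EHR baseline is a
binary patient × mapped-concept indicator matrix with no graph enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .kg import KnowledgeGraph, TransitionModel
from .records import PatientRecord

__all__ = [
    "ConceptMapping",
    "PSEVParams",
    "PSEVMatrix",
    "SpokeSigMatrix",
    "RawEHRMatrix",
    "EmptySignatureError",
    "ConvergenceError",
    "build_restart_vector",
    "compute_psev",
    "build_psev_matrix",
    "build_spokesig",
    "build_spokesig_matrix",
    "build_raw_matrix",
    "write_matrix",
    "read_matrix",
]


class EmptySignatureError(ValueError):
    """Patient has no event that maps into the graph."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within max_iter."""


@dataclass
class ConceptMapping:
    """Partial map from EHR concept ids to graph node ids (the entry points)."""

    concept_to_node: dict[str, str]

    def __post_init__(self) -> None:
        self.concept_to_node = dict(self.concept_to_node)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concept_to_node

    def __getitem__(self, concept_id: str) -> str:
        return self.concept_to_node[concept_id]

    @property
    def concepts(self) -> list[str]:
        return sorted(self.concept_to_node)

    def validate_against(self, kg: KnowledgeGraph) -> None:
        missing = sorted(v for v in self.concept_to_node.values() if v not in kg.node_index)
        if missing:
            raise ValueError(f"mapping targets absent from graph: {missing}")

    def unmapped(self, concept_ids: set[str]) -> set[str]:
        return {c for c in concept_ids if c not in self.concept_to_node}


@dataclass(frozen=True)
class PSEVParams:
    damping: float = 0.85
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")


@dataclass
class PSEVMatrix:
    """concepts × graph-nodes embedding matrix; every row is a probability vector."""

    concepts: list[str]
    node_ids: list[str]
    values: np.ndarray
    damping: float
    tol: float

    def row(self, concept_id: str) -> np.ndarray:
        return self.values[self.concepts.index(concept_id)]


@dataclass
class SpokeSigMatrix:
    """patients × graph-nodes signature matrix; rows are probability vectors."""

    patient_ids: list[str]
    node_ids: list[str]
    values: np.ndarray

    def row(self, patient_id: str) -> np.ndarray:
        return self.values[self.patient_ids.index(patient_id)]

    def node_column(self, node_id: str) -> np.ndarray:
        return self.values[:, self.node_ids.index(node_id)]


@dataclass
class RawEHRMatrix:
    """Binary patients × mapped-concepts matrix (graph-free baseline)."""

    patient_ids: list[str]
    concepts: list[str]
    values: np.ndarray
    empty_patients: list[str] = field(default_factory=list)


def build_restart_vector(concept_id: str, cohort_records: list[PatientRecord],
                         mapping: ConceptMapping, kg: KnowledgeGraph) -> np.ndarray:
    """Cohort-weighted restart distribution for one mapped concept.

    Mass at entry node y is proportional to the number of cohort patients who
    carry ``concept_id`` and also have at least one event mapping to y.  A
    concept with no carriers falls back to unit mass on its own node.
    """
    if concept_id not in mapping:
        raise KeyError(f"concept {concept_id!r} is not mapped to any graph node")
    n = kg.n_nodes
    weights = np.zeros(n)
    for record in cohort_records:
        concepts = record.concept_ids()
        if concept_id not in concepts:
            continue
        for c in concepts:
            if c in mapping:
                weights[kg.node_index[mapping[c]]] += 1.0
    total = weights.sum()
    if total == 0:
        weights[kg.node_index[mapping[concept_id]]] = 1.0
        return weights
    return weights / total


def compute_psev(transition: TransitionModel, restart: np.ndarray,
                 damping: float = 0.85, tol: float = 1e-8,
                 max_iter: int = 1000) -> np.ndarray:
    """Personalized PageRank by power iteration.

    Fixed point of ``v ← d·(T·v + m·r) + (1−d)·r`` where m is the mass sitting
    on dangling nodes (redistributed onto the restart vector r) and d the
    damping factor.  Iterates until the L1 change drops below tol.
    """
    restart = np.asarray(restart, dtype=float)
    if restart.ndim != 1 or restart.shape[0] != transition.n_nodes:
        raise ValueError("restart vector shape does not match the graph")
    if abs(restart.sum() - 1.0) > 1e-9 or (restart < 0).any():
        raise ValueError("restart must be a probability vector")
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    T = transition.matrix
    dangling = transition.dangling_mask
    v = restart.copy()
    for _ in range(max_iter):
        dangling_mass = v[dangling].sum()
        v_new = damping * (T @ v + dangling_mass * restart) + (1.0 - damping) * restart
        residual = np.abs(v_new - v).sum()
        v = v_new
        if residual < tol:
            # guard against drift; the update conserves mass analytically
            return v / v.sum()
    raise ConvergenceError(f"no convergence in {max_iter} iterations; last residual {residual:.3e}")


def build_psev_matrix(kg: KnowledgeGraph, cohort_records: list[PatientRecord],
                      mapping: ConceptMapping, transition: TransitionModel | None = None,
                      params: PSEVParams = PSEVParams()) -> PSEVMatrix:
    """One PSEV row per mapped concept observed in the cohort.

    Rows are independent of each other and of patient order, so the matrix is
    identical regardless of computation order.
    """
    from .kg import build_transition

    mapping.validate_against(kg)
    if transition is None:
        transition = build_transition(kg)
    observed = sorted({c for r in cohort_records for c in r.concept_ids() if c in mapping})
    values = np.zeros((len(observed), kg.n_nodes))
    for i, concept in enumerate(observed):
        restart = build_restart_vector(concept, cohort_records, mapping, kg)
        try:
            values[i] = compute_psev(transition, restart, params.damping, params.tol,
                                     params.max_iter)
        except ConvergenceError as err:  # pragma: no cover - defensive context
            raise ConvergenceError(f"concept {concept!r}: {err}") from err
    return PSEVMatrix(concepts=observed, node_ids=kg.node_ids, values=values,
                      damping=params.damping, tol=params.tol)


def build_spokesig(record: PatientRecord, psev: PSEVMatrix, mapping: ConceptMapping,
                   count_weighted: bool = False) -> np.ndarray:
    """Patient signature: L1-normalized sum of the PSEV rows of the patient's concepts.

    Each distinct concept contributes once by default; ``count_weighted=True``
    weights each concept's row by its event count instead.  Unmapped concepts
    are ignored (callers can audit coverage via ``ConceptMapping.unmapped``).
    """
    row_index = {c: i for i, c in enumerate(psev.concepts)}
    if count_weighted:
        counts: dict[str, int] = {}
        for e in record.events:
            if e.concept_id in mapping and e.concept_id in row_index:
                counts[e.concept_id] = counts.get(e.concept_id, 0) + 1
        items = counts.items()
    else:
        present = {c for c in record.concept_ids() if c in mapping and c in row_index}
        items = [(c, 1) for c in present]
    if not items:
        raise EmptySignatureError(
            f"patient {record.patient_id}: no mapped concept present in the PSEV matrix")
    sig = np.zeros(len(psev.node_ids))
    for concept, weight in items:
        sig += weight * psev.values[row_index[concept]]
    return sig / sig.sum()


def build_spokesig_matrix(records: list[PatientRecord], psev: PSEVMatrix,
                          mapping: ConceptMapping,
                          count_weighted: bool = False) -> tuple[SpokeSigMatrix, list[str]]:
    """Stack signatures for all patients; returns (matrix, dropped patient ids)."""
    rows: list[np.ndarray] = []
    kept: list[str] = []
    dropped: list[str] = []
    for record in records:
        try:
            rows.append(build_spokesig(record, psev, mapping, count_weighted))
            kept.append(record.patient_id)
        except EmptySignatureError:
            dropped.append(record.patient_id)
    values = np.vstack(rows) if rows else np.zeros((0, len(psev.node_ids)))
    return SpokeSigMatrix(patient_ids=kept, node_ids=list(psev.node_ids), values=values), dropped


def build_raw_matrix(records: list[PatientRecord], mapping: ConceptMapping) -> RawEHRMatrix:
    """Binary patient × mapped-concept indicator matrix (no propagation)."""
    concepts = mapping.concepts
    col = {c: j for j, c in enumerate(concepts)}
    values = np.zeros((len(records), len(concepts)), dtype=np.int8)
    empty: list[str] = []
    for i, record in enumerate(records):
        mapped = [c for c in record.concept_ids() if c in col]
        for c in mapped:
            values[i, col[c]] = 1
        if not mapped:
            empty.append(record.patient_id)
    return RawEHRMatrix(patient_ids=[r.patient_id for r in records], concepts=concepts,
                        values=values, empty_patients=empty)


def write_matrix(matrix: PSEVMatrix | SpokeSigMatrix | RawEHRMatrix, prefix: str | Path) -> None:
    """Persist a matrix as Matrix Market plus sidecar row/column label files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = matrix.concepts if isinstance(matrix, PSEVMatrix) else matrix.patient_ids
    cols = matrix.concepts if isinstance(matrix, RawEHRMatrix) else matrix.node_ids
    # 17 significant digits round-trips float64 exactly
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix.values), precision=17)
    Path(str(prefix) + ".rows.txt").write_text("\n".join(rows) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(cols) + "\n")


def read_matrix(prefix: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Load (values, row_labels, col_labels) written by :func:`write_matrix`."""
    prefix = Path(prefix)
    values = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    rows = Path(str(prefix) + ".rows.txt").read_text().splitlines()
    cols = Path(str(prefix) + ".cols.txt").read_text().splitlines()
    return values, rows, cols
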