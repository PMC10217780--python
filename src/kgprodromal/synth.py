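"""Synthetic knowledge graphs and EHR cohorts with controllable planted signal.

The generator emulates the statistical structure the analysis assumes: a
small multi-type graph (Disease / Symptom / Gene / Compound / SideEffect)
with a designated target-disease node, a subset of EHR-mappable entry
concepts wired directly to that target ("prodromal" concepts), and a cohort
in which future cases accumulate prodromal codes at elevated rates that grow
as their index date approaches, while controls emit all codes at a common
background rate.

Signal placement: for each horizon h ∈ {1, 3, 5} years the elevated rate
applies inside the year immediately preceding t0 − 365·h.  The model trained
at horizon h therefore sees the signal epochs of horizons h, …, 5, so nearer
horizons see strictly more planted signal — the synthetic analogue of
prodromal symptoms becoming more numerous as diagnosis nears.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .embedding import ConceptMapping
from .kg import EdgeRecord, KnowledgeGraph, NodeRecord
from .records import EHREvent, PatientRecord

__all__ = [
    "SyntheticKGSpec",
    "SyntheticCohortSpec",
    "SyntheticWorld",
    "SyntheticCohort",
    "PD_DX_CODES",
    "PD_MED_CODES",
    "NEUROLEPTIC_CODES",
    "generate_kg",
    "generate_cohort",
    "generate_relayed_cohort",
]

# Reserved, unmapped concept code lists (configurable stand-ins for the PD
# diagnosis / PD medication / neuroleptic code lists used by the cohort rules).
PD_DX_CODES = frozenset({"PD_DX_1", "PD_DX_2"})
PD_MED_CODES = frozenset({"PD_MED_LEVODOPA"})
NEUROLEPTIC_CODES = frozenset({"NEURO_MED_1"})

_TYPE_PREFIX = {
    "Disease": "DIS",
    "Symptom": "SYM",
    "Gene": "GEN",
    "Compound": "CMP",
    "SideEffect": "SDE",
}
_ENTRY_DOMAIN = {"Disease": "diagnosis", "Symptom": "diagnosis", "Compound": "medication"}

_PREDICATES = {
    frozenset({"Disease", "Symptom"}): "presents",
    frozenset({"Disease", "Gene"}): "associates",
    frozenset({"Disease", "Compound"}): "treats",
    frozenset({"Disease"}): "resembles",
    frozenset({"Compound", "SideEffect"}): "causes",
    frozenset({"Gene"}): "interacts",
}


@dataclass(frozen=True)
class SyntheticKGSpec:
    n_disease: int = 15
    n_symptom: int = 25
    n_gene: int = 20
    n_compound: int = 12
    n_side_effect: int = 8
    n_entry_concepts: int = 40
    n_prodromal_neighbors: int = 8
    background_edge_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must be in [0, 1]")
        if self.n_prodromal_neighbors > self.n_entry_concepts:
            raise ValueError("n_prodromal_neighbors must not exceed n_entry_concepts")
        n_mappable = self.n_disease - 1 + self.n_symptom + self.n_compound
        if self.n_entry_concepts > n_mappable:
            raise ValueError(
                f"n_entry_concepts={self.n_entry_concepts} exceeds the "
                f"{n_mappable} mappable (Disease/Symptom/Compound) nodes")

    @property
    def type_counts(self) -> dict[str, int]:
        return {
            "Disease": self.n_disease,
            "Symptom": self.n_symptom,
            "Gene": self.n_gene,
            "Compound": self.n_compound,
            "SideEffect": self.n_side_effect,
        }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_cases: int = 200
    n_controls: int = 200
    obs_days: int = 5475                      # ~15 years of observation
    base_rate: float = 3.0                    # mean mapped events per patient-year
    signal_rate_by_horizon: tuple[tuple[int, float], ...] = ((1, 6.0), (3, 4.0), (5, 2.0))
    age_range: tuple[float, float] = (45.0, 90.0)
    frac_neuroleptic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        mult = dict(self.signal_rate_by_horizon)
        horizons = sorted(mult)
        for near, far in zip(horizons, horizons[1:]):
            if mult[near] < mult[far]:
                raise ValueError(
                    "signal multipliers must be non-increasing with horizon distance")
        if any(m < 0 for m in mult.values()):
            raise ValueError("multipliers must be non-negative")

    @property
    def multipliers(self) -> dict[int, float]:
        return dict(self.signal_rate_by_horizon)


@dataclass
class SyntheticWorld:
    """A generated graph plus everything the cohort generator needs to use it."""

    kg: KnowledgeGraph
    mapping: ConceptMapping
    target_disease: str
    entry_concepts: list[str]
    prodromal_concepts: list[str]
    spec: SyntheticKGSpec


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    labels: dict[str, int]                      # 1 = future case
    case_index_day: dict[str, int]              # planted t0 per case
    folds: dict[str, str] = field(default_factory=dict)   # relayed mode only
    train_concepts: list[str] = field(default_factory=list)
    test_concepts: list[str] = field(default_factory=list)


def _concept_for(node_id: str) -> str:
    return f"C_{node_id}"


def most_distant_disease(world: SyntheticWorld) -> str:
    """Disease node farthest from the target disease (deterministic tie-break).

    Used as the principled "unrelated disease" feature in signal-specificity
    checks: its signature value should not separate cases from controls.
    """
    import networkx as nx

    g = world.kg.to_networkx()
    dist = nx.single_source_shortest_path_length(g, world.target_disease)
    diseases = [n for n in world.kg.node_ids
                if world.kg.node_types()[n] == "Disease" and n != world.target_disease]
    return max(diseases, key=lambda n: (dist.get(n, 10**9), n))


def generate_kg(spec: SyntheticKGSpec) -> SyntheticWorld:
    """Build a connected typed graph with planted prodromal wiring.

    Edges are a deterministic spanning backbone (a path over sorted node ids),
    the planted entry→target edges, and independent background edges with
    probability ``background_edge_prob`` per remaining node pair.  Identical
    specs (seed included) yield identical graphs.
    """
    rng = np.random.default_rng(spec.seed)
    nodes: list[NodeRecord] = []
    for node_type, count in spec.type_counts.items():
        prefix = _TYPE_PREFIX[node_type]
        for i in range(1, count + 1):
            nid = f"{prefix}{i:03d}"
            nodes.append(NodeRecord(nid, node_type, f"{node_type} {i}"))
    type_of = {n.node_id: n.node_type for n in nodes}
    target_disease = "DIS001"

    mappable = sorted(n.node_id for n in nodes
                      if n.node_type in _ENTRY_DOMAIN and n.node_id != target_disease)
    entry_nodes = sorted(rng.choice(mappable, size=spec.n_entry_concepts, replace=False))
    prodromal_nodes = sorted(rng.choice(entry_nodes, size=spec.n_prodromal_neighbors,
                                        replace=False))

    def predicate(a: str, b: str) -> str:
        return _PREDICATES.get(frozenset({type_of[a], type_of[b]}), "related_to")

    edge_set: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edge_set.add((min(a, b), max(a, b)))

    ordered_ids = sorted(type_of)
    for a, b in zip(ordered_ids, ordered_ids[1:]):   # spanning backbone
        add(a, b)
    for nid in prodromal_nodes:                      # planted wiring
        add(nid, target_disease)
    if spec.background_edge_prob > 0:
        for a, b in itertools.combinations(ordered_ids, 2):
            key = (min(a, b), max(a, b))
            if key not in edge_set and rng.random() < spec.background_edge_prob:
                edge_set.add(key)

    edges = [EdgeRecord(a, b, predicate(a, b)) for a, b in sorted(edge_set)]
    kg = KnowledgeGraph(nodes=nodes, edges=edges)
    mapping = ConceptMapping({_concept_for(nid): nid for nid in entry_nodes})
    return SyntheticWorld(
        kg=kg,
        mapping=mapping,
        target_disease=target_disease,
        entry_concepts=sorted(mapping.concepts),
        prodromal_concepts=[_concept_for(n) for n in prodromal_nodes],
        spec=spec,
    )


def _poisson_events(rng: np.random.Generator, concept: str, domain: str,
                    rate_per_year: float, day_lo: int, day_hi: int) -> list[EHREvent]:
    """Poisson(rate × span) events with uniform days in [day_lo, day_hi)."""
    if day_hi <= day_lo or rate_per_year <= 0:
        return []
    span_years = (day_hi - day_lo) / 365.0
    count = rng.poisson(rate_per_year * span_years)
    days = rng.integers(day_lo, day_hi, size=count)
    return [EHREvent(event_day=int(d), concept_id=concept, domain=domain) for d in days]


def _background_events(rng: np.random.Generator, world: SyntheticWorld,
                       rate_per_concept: float, day_lo: int, day_hi: int,
                       concepts: list[str] | None = None) -> list[EHREvent]:
    events: list[EHREvent] = []
    for concept in (concepts if concepts is not None else world.entry_concepts):
        domain = _ENTRY_DOMAIN[world.kg.node_types()[world.mapping[concept]]]
        events.extend(_poisson_events(rng, concept, domain, rate_per_concept, day_lo, day_hi))
    return events


def _signal_events(rng: np.random.Generator, world: SyntheticWorld,
                   spec: SyntheticCohortSpec, t0: int, concepts: list[str],
                   on_top_of_background: bool) -> list[EHREvent]:
    """Prodromal events in the per-horizon signal epochs before t0.

    When the prodromal concepts also appear in the background process
    (standard mode) the epoch rate tops background up to base × multiplier;
    in relayed mode prodromal concepts are excluded from all backgrounds and
    the epochs carry the full base × multiplier rate.
    """
    rate_per_concept = spec.base_rate / len(world.entry_concepts)
    types = world.kg.node_types()
    events: list[EHREvent] = []
    for horizon, mult in sorted(spec.multipliers.items()):
        rate = rate_per_concept * ((mult - 1.0) if on_top_of_background else mult)
        if rate <= 0:
            continue
        hi = t0 - horizon * 365
        lo = max(0, hi - 365)
        for concept in concepts:
            domain = _ENTRY_DOMAIN[types[world.mapping[concept]]]
            events.extend(_poisson_events(rng, concept, domain, rate, lo, hi))
    return events


def generate_cohort(spec: SyntheticCohortSpec, world: SyntheticWorld) -> SyntheticCohort:
    """Simulate case and control patients against a synthetic world.

    Controls emit every entry concept at the shared background rate over the
    full observation span.  Cases do the same, receive a planted index day
    (uniform in the central 60% of the span), two PD diagnosis codes 183 days
    apart starting at t0, and extra prodromal-concept events in the horizon
    signal epochs.  The first round(frac_neuroleptic × n_cases) cases get a
    neuroleptic medication event 90 days before their first PD code.
    """
    return _generate(spec, world, relayed=False)


def generate_relayed_cohort(spec: SyntheticCohortSpec, world: SyntheticWorld,
                            train_fraction: float = 0.8) -> SyntheticCohort:
    """Cohort whose train and test cases express disjoint prodromal concepts.

    The prodromal concepts are split into two halves A (train cases) and B
    (test cases), both direct graph neighbors of the target disease.  A raw
    binary model trained on A carriers has no usable feature on B carriers,
    while graph propagation routes both onto the shared target neighborhood —
    the scenario where enrichment is necessary.
    """
    if len(world.prodromal_concepts) < 2:
        raise ValueError("relayed cohort requires at least 2 prodromal concepts")
    return _generate(spec, world, relayed=True, train_fraction=train_fraction)


def _generate(spec: SyntheticCohortSpec, world: SyntheticWorld, relayed: bool,
              train_fraction: float = 0.8) -> SyntheticCohort:
    rng = np.random.default_rng(spec.seed)
    rate_per_concept = spec.base_rate / len(world.entry_concepts)
    lo_t0 = int(0.2 * spec.obs_days)
    hi_t0 = int(0.8 * spec.obs_days)

    half = len(world.prodromal_concepts) // 2
    train_concepts = world.prodromal_concepts[:half] if relayed else list(world.prodromal_concepts)
    test_concepts = world.prodromal_concepts[half:] if relayed else list(world.prodromal_concepts)
    # relayed mode: prodromal concepts never appear in anyone's background, so
    # test-case raw vectors have zero mass on train-case concepts by construction
    background_concepts = ([c for c in world.entry_concepts
                            if c not in set(world.prodromal_concepts)]
                           if relayed else list(world.entry_concepts))

    records: list[PatientRecord] = []
    labels: dict[str, int] = {}
    case_t0: dict[str, int] = {}
    folds: dict[str, str] = {}
    n_neuro = int(round(spec.frac_neuroleptic * spec.n_cases))
    n_train_cases = int(round(train_fraction * spec.n_cases))

    for i in range(spec.n_cases):
        pid = f"case_{i + 1:05d}"
        t0 = int(rng.integers(lo_t0, hi_t0 + 1))
        fold = "train" if i < n_train_cases else "test"
        events = _background_events(rng, world, rate_per_concept, 0, spec.obs_days,
                                    concepts=background_concepts)
        events.extend(_signal_events(
            rng, world, spec, t0,
            (train_concepts if fold == "train" else test_concepts) if relayed
            else list(world.prodromal_concepts),
            on_top_of_background=not relayed))
        pd_code = sorted(PD_DX_CODES)[0]
        events.append(EHREvent(t0, pd_code, "diagnosis"))
        events.append(EHREvent(min(t0 + 183, spec.obs_days), pd_code, "diagnosis"))
        if i < n_neuro:
            events.append(EHREvent(max(0, t0 - 90), sorted(NEUROLEPTIC_CODES)[0], "medication"))
        age = rng.uniform(*spec.age_range)
        records.append(PatientRecord(
            patient_id=pid,
            birth_day=int(t0 - age * 365),
            events=events,
            last_visit_day=spec.obs_days,
        ))
        labels[pid] = 1
        case_t0[pid] = t0
        if relayed:
            folds[pid] = fold

    # Controls stop being observed 182 days after a pseudo-index drawn from the
    # same distribution as case t0, so that t0 = last_visit − 182 and the
    # windowed-history length distributions match between arms (otherwise a
    # classifier could separate the arms on follow-up length alone).
    n_train_controls = int(round(train_fraction * spec.n_controls))
    for i in range(spec.n_controls):
        pid = f"ctrl_{i + 1:05d}"
        t0 = int(rng.integers(lo_t0, hi_t0 + 1))
        last_visit = t0 + 182
        events = _background_events(rng, world, rate_per_concept, 0, last_visit,
                                    concepts=background_concepts)
        age = rng.uniform(*spec.age_range)
        records.append(PatientRecord(
            patient_id=pid,
            birth_day=int(t0 - age * 365),
            events=events,
            last_visit_day=last_visit,
        ))
        labels[pid] = 0
        if relayed:
            folds[pid] = "train" if i < n_train_controls else "test"

    return SyntheticCohort(records=records, labels=labels, case_index_day=case_t0,
                           folds=folds, train_concepts=train_concepts,
                           test_concepts=test_concepts)
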