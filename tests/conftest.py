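"""Shared fixtures: tiny handcrafted graphs, a synthetic world and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from kgprodromal import synth
from kgprodromal.cohort import CohortConfig
from kgprodromal.embedding import ConceptMapping
from kgprodromal.kg import EdgeRecord, KnowledgeGraph, NodeRecord
from kgprodromal.records import EHREvent, PatientRecord


@pytest.fixture
def path_kg() -> KnowledgeGraph:
    """Undirected path A–B–C–D–E with alternating node types."""
    nodes = [NodeRecord(nid, "Disease" if i % 2 == 0 else "Symptom", nid)
             for i, nid in enumerate("ABCDE")]
    edges = [EdgeRecord(a, b, "related_to") for a, b in zip("ABCD", "BCDE")]
    return KnowledgeGraph(nodes=nodes, edges=edges)


@pytest.fixture(scope="session")
def world() -> synth.SyntheticWorld:
    return synth.generate_kg(synth.SyntheticKGSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort(world) -> synth.SyntheticCohort:
    """Small signal cohort for unit tests (60 cases / 60 controls)."""
    return synth.generate_cohort(
        synth.SyntheticCohortSpec(n_cases=60, n_controls=60, seed=1), world)


def _patient(pid: str, events: list[tuple[int, str, str]], birth_day: int = -20000,
             last_visit: int = 3000) -> PatientRecord:
    evs = [EHREvent(day, concept, domain) for day, concept, domain in events]
    return PatientRecord(patient_id=pid, birth_day=birth_day, events=evs,
                         last_visit_day=last_visit)


@pytest.fixture(scope="session")
def rule_cohort():
    """Twelve handcrafted patients exercising every inclusion/exclusion rule.

    Returns (records, labels, config, expected) where expected maps
    patient_id -> "accepted" or the rejection reason, hand-derived from the
    rules: t0 = first PD code or earlier first PD medication; ≥2 PD codes with
    one ≥182 days after t0; neuroleptic look-back (first_code − 182,
    first_code]; age ≥ 40 at t0; control t0 = last visit − 182.
    """
    PD, MED, NEU = "PD_DX", "PD_MED", "NEU_MED"
    config = CohortConfig(pd_code_set=frozenset({PD}), pd_med_set=frozenset({MED}),
                          neuroleptic_set=frozenset({NEU}), prevalence_per_100k=None)
    dx, rx = "diagnosis", "medication"
    records = [
        # accepted, t0 = 1000 (two codes 200 days apart)
        _patient("P01", [(1000, PD, dx), (1200, PD, dx)]),
        # accepted, medication precedes code: t0 = 900
        _patient("P02", [(900, MED, rx), (1000, PD, dx), (1200, PD, dx)]),
        # rejected: a single PD code
        _patient("P03", [(1000, PD, dx)]),
        # rejected: codes only 100 days apart
        _patient("P04", [(1000, PD, dx), (1100, PD, dx)]),
        # excluded: neuroleptic 100 days before the first PD code
        _patient("P05", [(900, NEU, rx), (1000, PD, dx), (1200, PD, dx)]),
        # accepted: neuroleptic 200 days before the first code (outside window)
        _patient("P06", [(800, NEU, rx), (1000, PD, dx), (1200, PD, dx)]),
        # excluded: age 39.7 at t0 (birth −13500 → (1000+13500)/365 < 40)
        _patient("P07", [(1000, PD, dx), (1200, PD, dx)], birth_day=-13500),
        # accepted: a later PD medication does not move t0 back
        _patient("P08", [(1000, PD, dx), (1100, MED, rx), (1200, PD, dx)]),
        # control, accepted: t0 = 2000 − 182 = 1818, age ~59
        _patient("P09", [(500, "C_X", dx)], last_visit=2000),
        # control, excluded by age: birth −12000 → age (1818+12000)/365 ≈ 37.9
        _patient("P10", [(500, "C_X", dx)], birth_day=-12000, last_visit=2000),
        # excluded: med-first t0=900, but neuroleptic at 950 is within 182 days
        # of the first PD *code* (day 1000), the anchor of the look-back
        _patient("P11", [(900, MED, rx), (950, NEU, rx), (1000, PD, dx), (1200, PD, dx)]),
        # accepted: second code exactly 182 days after t0 (boundary is inclusive)
        _patient("P12", [(1000, PD, dx), (1182, PD, dx)]),
    ]
    labels = {r.patient_id: 0 if r.patient_id in ("P09", "P10") else 1 for r in records}
    expected = {
        "P01": "accepted", "P02": "accepted", "P03": "insufficient_pd_codes",
        "P04": "code_gap", "P05": "neuroleptic_window", "P06": "accepted",
        "P07": "age", "P08": "accepted", "P09": "accepted", "P10": "age",
        "P11": "neuroleptic_window", "P12": "accepted",
    }
    return records, labels, config, expected


@pytest.fixture
def two_patient_mapping() -> ConceptMapping:
    return ConceptMapping({"c": "X", "d": "Y"})
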