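"""Cohort construction: index dates, inclusion/exclusion rules, event windowing
and prevalence-matched control sampling.

Cases anchor at t0 = first PD diagnostic code, or the earlier first PD
medication when one precedes the code; at least two PD codes at least 182 days
apart are required, patients on neuroleptics within 182 days before the first
PD code are excluded (drug-induced parkinsonism look-alikes), and everyone
under 40 at index is dropped.  Controls anchor at t0 = last visit − 182 days.
Each pre-diagnostic model at horizon h years sees only events strictly before
t0 − 365·h.  Training populations are rebalanced to a disease-prevalence
case:control ratio (572 per 100,000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .records import PatientRecord

__all__ = [
    "CohortConfig",
    "IndexedPatient",
    "Rejection",
    "DAYS_PER_YEAR",
    "assign_case_index",
    "index_control",
    "apply_exclusions",
    "window_events",
    "sample_prevalence",
]

DAYS_PER_YEAR = 365
HALF_YEAR_DAYS = 182


@dataclass(frozen=True)
class CohortConfig:
    pd_code_set: frozenset[str]
    pd_med_set: frozenset[str] = frozenset()
    neuroleptic_set: frozenset[str] = frozenset()
    min_age_years: float = 40.0
    min_code_gap_days: int = HALF_YEAR_DAYS
    control_offset_days: int = HALF_YEAR_DAYS
    prevalence_per_100k: float | None = 572.0  # None → keep all controls
    horizons_years: tuple[int, ...] = (1, 3, 5)

    def __post_init__(self) -> None:
        if self.min_code_gap_days <= 0 or self.control_offset_days <= 0:
            raise ValueError("day thresholds must be positive")
        if self.prevalence_per_100k is not None and not 0 < self.prevalence_per_100k <= 100_000:
            raise ValueError("prevalence ratio numerator must be in (0, 100000]")


@dataclass(frozen=True)
class IndexedPatient:
    patient_id: str
    label: str  # "case" | "control"
    index_day: int
    age_at_index: float


@dataclass(frozen=True)
class Rejection:
    patient_id: str
    reason: str


def _age_at(record: PatientRecord, day: int) -> float:
    return (day - record.birth_day) / DAYS_PER_YEAR


def assign_case_index(record: PatientRecord, config: CohortConfig) -> IndexedPatient | Rejection:
    """Anchor a candidate case or reject it with a reason code.

    t0 is the first PD code day, replaced by the first PD-medication day when
    that is earlier.  Acceptance additionally requires ≥2 PD codes with some
    code at least ``min_code_gap_days`` after t0.
    """
    code_days = sorted(e.event_day for e in record.events if e.concept_id in config.pd_code_set)
    if len(code_days) < 2:
        return Rejection(record.patient_id, "insufficient_pd_codes")
    med_days = sorted(e.event_day for e in record.events if e.concept_id in config.pd_med_set)
    t0 = code_days[0]
    if med_days and med_days[0] < t0:
        t0 = med_days[0]
    if not any(d >= t0 + config.min_code_gap_days for d in code_days):
        return Rejection(record.patient_id, "code_gap")
    return IndexedPatient(record.patient_id, "case", t0, _age_at(record, t0))


def index_control(record: PatientRecord, config: CohortConfig) -> IndexedPatient:
    """Controls anchor ``control_offset_days`` before their last recorded visit."""
    t0 = record.last_visit_day - config.control_offset_days
    return IndexedPatient(record.patient_id, "control", t0, _age_at(record, t0))


def apply_exclusions(candidates: list[IndexedPatient], records: dict[str, PatientRecord],
                     config: CohortConfig) -> tuple[list[IndexedPatient], list[Rejection]]:
    """Apply the neuroleptic-window and age exclusions.

    The neuroleptic look-back is anchored to the first PD diagnostic code day
    (half-open window (first_code − 182, first_code]) and applies to cases
    only; the age threshold applies to both arms.  Every rejected patient
    carries exactly one primary reason.
    """
    kept: list[IndexedPatient] = []
    rejected: list[Rejection] = []
    for cand in candidates:
        record = records[cand.patient_id]
        if record.birth_day is None:
            raise ValueError(f"patient {cand.patient_id}: missing birth_day")
        if cand.label == "case" and config.neuroleptic_set:
            code_days = [e.event_day for e in record.events
                         if e.concept_id in config.pd_code_set]
            anchor = min(code_days) if code_days else cand.index_day
            neuro = [e.event_day for e in record.events
                     if e.concept_id in config.neuroleptic_set]
            if any(anchor - HALF_YEAR_DAYS < d <= anchor for d in neuro):
                rejected.append(Rejection(cand.patient_id, "neuroleptic_window"))
                continue
        if cand.age_at_index < config.min_age_years:
            rejected.append(Rejection(cand.patient_id, "age"))
            continue
        kept.append(cand)
    return kept, rejected


def window_events(record: PatientRecord, indexed: IndexedPatient,
                  horizon_years: int) -> PatientRecord:
    """Restrict a record to events strictly before t0 − 365·horizon.

    Patients left with no events keep an empty event list; modelling code
    flags and drops them downstream.
    """
    cutoff = indexed.index_day - horizon_years * DAYS_PER_YEAR
    kept = [e for e in record.events if e.event_day < cutoff]
    return replace(record, events=kept)


def sample_prevalence(cases: list[IndexedPatient], controls: list[IndexedPatient],
                      config: CohortConfig, seed: int) -> list[IndexedPatient]:
    """Subsample controls to the prevalence-matched ratio, keeping all cases.

    With prevalence p per 100k the target control count is
    floor(n_cases · 100000 / p); sampling is without replacement and
    deterministic under the seed.  ``prevalence_per_100k=None`` keeps all
    controls (1:1 and other overrides are expressed by setting the rate).
    """
    if config.prevalence_per_100k is None:
        return list(controls)
    n_required = int(np.floor(len(cases) * 100_000 / config.prevalence_per_100k))
    if len(controls) < n_required:
        raise ValueError(
            f"insufficient controls: need {n_required}, have {len(controls)}")
    rng = np.random.default_rng(seed)
    ordered = sorted(controls, key=lambda c: c.patient_id)
    chosen = rng.choice(len(ordered), size=n_required, replace=False)
    return [ordered[i] for i in sorted(chosen)]
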