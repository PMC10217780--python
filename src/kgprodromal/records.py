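"""Patient-level EHR containers shared by the cohort, embedding and scoring modules.

Dates are integer day offsets from an arbitrary epoch; no calendar arithmetic
is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["EHREvent", "PatientRecord", "write_event_tables", "read_event_tables"]

DOMAINS = ("diagnosis", "medication", "lab")


@dataclass(frozen=True, order=True)
class EHREvent:
    event_day: int
    concept_id: str
    domain: str = "diagnosis"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")


@dataclass
class PatientRecord:
    patient_id: str
    birth_day: int
    events: list[EHREvent] = field(default_factory=list)
    last_visit_day: int = 0

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        if self.events and self.last_visit_day < self.events[-1].event_day:
            raise ValueError(
                f"patient {self.patient_id}: last_visit_day {self.last_visit_day} "
                f"precedes final event day {self.events[-1].event_day}"
            )

    def concept_ids(self) -> set[str]:
        return {e.concept_id for e in self.events}

    def events_of(self, concept_ids: Iterable[str]) -> list[EHREvent]:
        wanted = set(concept_ids)
        return [e for e in self.events if e.concept_id in wanted]


def write_event_tables(records: list[PatientRecord], out_dir: str | Path,
                       labels: dict[str, int] | None = None) -> None:
    """Write events.tsv / patients.tsv (and labels.tsv when labels are given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev_rows = [
        (r.patient_id, e.concept_id, e.domain, e.event_day)
        for r in records for e in r.events
    ]
    pd.DataFrame(ev_rows, columns=["patient_id", "concept_id", "domain", "event_day"]).to_csv(
        out / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.patient_id, r.birth_day, r.last_visit_day) for r in records],
        columns=["patient_id", "birth_day", "last_visit_day"],
    ).to_csv(out / "patients.tsv", sep="\t", index=False)
    if labels is not None:
        pd.DataFrame(sorted(labels.items()), columns=["patient_id", "label"]).to_csv(
            out / "labels.tsv", sep="\t", index=False)


def read_event_tables(in_dir: str | Path) -> tuple[list[PatientRecord], dict[str, int] | None]:
    """Inverse of :func:`write_event_tables`; labels are returned when present."""
    src = Path(in_dir)
    patients = pd.read_csv(src / "patients.tsv", sep="\t", dtype={"patient_id": str})
    events = pd.read_csv(src / "events.tsv", sep="\t", dtype={"patient_id": str, "concept_id": str})
    by_patient: dict[str, list[EHREvent]] = {p: [] for p in patients.patient_id}
    for row in events.itertuples():
        by_patient[row.patient_id].append(
            EHREvent(event_day=int(row.event_day), concept_id=row.concept_id, domain=row.domain))
    records = [
        PatientRecord(
            patient_id=row.patient_id,
            birth_day=int(row.birth_day),
            events=by_patient[row.patient_id],
            last_visit_day=int(row.last_visit_day),
        )
        for row in patients.itertuples()
    ]
    labels = None
    if (src / "labels.tsv").exists():
        lab = pd.read_csv(src / "labels.tsv", sep="\t", dtype={"patient_id": str})
        labels = dict(zip(lab.patient_id, lab.label.astype(int)))
    return records, labels
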