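"""MDS prodromal-criteria baseline: likelihood-ratio scoring with an age prior.

The research criteria for prodromal Parkinson's disease combine an age-based
prior probability with a product of marker likelihood ratios through the odds
form of Bayes' rule: a marker that is present multiplies the prior odds by
LR+ ≥ 1, an absent (but assessable) marker multiplies by LR− ≤ 1, and a
marker that cannot be assessed from coded data contributes nothing (LR = 1).
The resulting posterior probability is used directly as a ranking score.

The shipped ``data/mds_markers.tsv`` / ``data/mds_age_priors.tsv`` tables are
editable defaults seeded from the published criteria values; the EHR-code to
marker map (``concept_ids`` column) is dataset-specific and left to the
caller or config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import IndexedPatient
from .records import PatientRecord

__all__ = [
    "MarkerDefinition",
    "AgePriorTable",
    "MDSMarkerProfile",
    "load_markers",
    "load_age_priors",
    "default_markers",
    "default_age_priors",
    "profile_from_events",
    "total_lr",
    "posterior_probability",
    "score_cohort",
]


@dataclass(frozen=True)
class MarkerDefinition:
    marker_id: str
    lr_present: float
    lr_absent: float
    assessable: bool = True
    concept_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.lr_present <= 0 or self.lr_absent <= 0:
            raise ValueError(f"marker {self.marker_id}: likelihood ratios must be positive")
        if not (self.lr_present >= 1 >= self.lr_absent):
            raise ValueError(
                f"marker {self.marker_id}: expected lr_present >= 1 >= lr_absent "
                f"(got {self.lr_present}, {self.lr_absent})")


@dataclass
class AgePriorTable:
    """Ordered half-open age bands [lo, hi) → prior probability of prodromal disease."""

    bands: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands)
        prev_hi = None
        prev_prior = 0.0
        for lo, hi, prior in self.bands:
            if hi <= lo:
                raise ValueError(f"empty age band [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError(f"age bands must tile without gaps or overlap at {lo}")
            if not 0 < prior < 1:
                raise ValueError(f"prior {prior} outside (0, 1)")
            if prior < prev_prior:
                raise ValueError("priors must be non-decreasing with age")
            prev_hi, prev_prior = hi, prior

    def prior_for_age(self, age: float) -> float:
        for lo, hi, prior in self.bands:
            if lo <= age < hi:
                return prior
        raise KeyError(f"age {age} not covered by the prior table")


@dataclass
class MDSMarkerProfile:
    patient_id: str
    status: dict[str, str]  # marker_id -> present | absent | unknown


def load_markers(path: str | Path) -> list[MarkerDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    defs = []
    for row in df.itertuples():
        ids = frozenset(c for c in str(row.concept_ids).split(";") if c)
        defs.append(MarkerDefinition(
            marker_id=row.marker_id,
            lr_present=float(row.lr_present),
            lr_absent=float(row.lr_absent),
            assessable=str(row.assessable) in ("1", "True", "true"),
            concept_ids=ids,
        ))
    return defs


def load_age_priors(path: str | Path) -> AgePriorTable:
    df = pd.read_csv(path, sep="\t")
    return AgePriorTable([(float(r.age_lo), float(r.age_hi), float(r.prior))
                          for r in df.itertuples()])


def default_markers() -> list[MarkerDefinition]:
    with resources.as_file(resources.files("kgprodromal.data") / "mds_markers.tsv") as p:
        return load_markers(p)


def default_age_priors() -> AgePriorTable:
    with resources.as_file(resources.files("kgprodromal.data") / "mds_age_priors.tsv") as p:
        return load_age_priors(p)


def assign_marker_concepts(defs: list[MarkerDefinition],
                           concept_map: dict[str, set[str]]) -> list[MarkerDefinition]:
    """Return defs with ``concept_ids`` replaced per ``{marker_id: concepts}``."""
    return [replace(d, concept_ids=frozenset(concept_map.get(d.marker_id, d.concept_ids)))
            for d in defs]


def profile_from_events(record: PatientRecord, defs: list[MarkerDefinition]) -> MDSMarkerProfile:
    """Presence/absence of each marker from coded events.

    present: ≥1 event in the marker's concept set; absent: assessable but no
    event; unknown: marker declared non-assessable from codes (exam- or
    imaging-based), regardless of events.
    """
    concepts = record.concept_ids()
    status: dict[str, str] = {}
    for d in defs:
        if not d.assessable:
            status[d.marker_id] = "unknown"
        elif concepts & d.concept_ids:
            status[d.marker_id] = "present"
        else:
            status[d.marker_id] = "absent"
    return MDSMarkerProfile(patient_id=record.patient_id, status=status)


def total_lr(profile: MDSMarkerProfile, defs: list[MarkerDefinition]) -> float:
    """Product of marker likelihood ratios (unknown markers contribute 1)."""
    lr = 1.0
    for d in defs:
        state = profile.status.get(d.marker_id)
        if state is None:
            raise KeyError(f"profile {profile.patient_id} missing marker {d.marker_id}")
        if state == "present":
            lr *= d.lr_present
        elif state == "absent":
            lr *= d.lr_absent
    return lr


def posterior_probability(prior: float, lr: float) -> float:
    """Bayes update in odds form: post_odds = prior_odds · LR."""
    if not 0 < prior < 1:
        raise ValueError(f"prior {prior} outside (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    odds = prior / (1.0 - prior) * lr
    return odds / (1.0 + odds)


def score_cohort(records: dict[str, PatientRecord], defs: list[MarkerDefinition],
                 priors: AgePriorTable, indexed: list[IndexedPatient],
                 require_marker: bool = False) -> dict[str, float]:
    """Posterior probability of prodromal disease per patient.

    Scores are ranking statistics for ROC analysis.  ``require_marker=True``
    restricts output to patients with at least one present marker (the
    criteria-comparison subpopulation); by default every patient is scored,
    an all-absent/unknown profile reducing to (a multiple of) the prior.
    """
    scores: dict[str, float] = {}
    for ind in indexed:
        record = records[ind.patient_id]
        try:
            prior = priors.prior_for_age(ind.age_at_index)
        except KeyError as err:
            raise KeyError(f"patient {ind.patient_id}: {err}") from err
        profile = profile_from_events(record, defs)
        if require_marker and "present" not in profile.status.values():
            continue
        scores[ind.patient_id] = posterior_probability(prior, total_lr(profile, defs))
    return scores
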