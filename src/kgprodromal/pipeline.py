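"""End-to-end experiment orchestration on synthetic worlds.

One config drives the whole comparison: generate (or load) a knowledge graph
and cohort, apply the inclusion/exclusion and windowing rules per horizon,
build propagation embeddings plus the raw-binary and MDS baselines, train
class-weighted classifiers on an 80:20 split, and report bootstrap AUC
distributions and method comparisons per horizon.

A single global seed fans out to per-stage seeds via stable name hashing, so
any stage can be re-run independently with identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as coh
from . import mds, stats, synth
from .embedding import (PSEVParams, build_psev_matrix, build_raw_matrix,
                        build_spokesig_matrix)
from .kg import build_transition

__all__ = ["ExperimentConfig", "stage_seed", "run_experiment", "write_report"]

METHODS = ("spokesig", "raw", "mds")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and stage name."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class ExperimentConfig:
    kg_spec: synth.SyntheticKGSpec = field(default_factory=synth.SyntheticKGSpec)
    cohort_spec: synth.SyntheticCohortSpec = field(default_factory=synth.SyntheticCohortSpec)
    horizons: tuple[int, ...] = (1, 3, 5)
    model: str = "forest"
    prevalence_per_100k: float | None = None   # None → use all generated controls
    min_age_years: float = 40.0
    damping: float = 0.85
    tol: float = 1e-8
    train_fraction: float = 0.8
    n_boot: int = 100
    boot_sample_size: int = 50
    relayed: bool = False
    methods: tuple[str, ...] = METHODS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kg_spec" in raw:
            raw["kg_spec"] = synth.SyntheticKGSpec(**raw["kg_spec"])
        if "cohort_spec" in raw:
            cs = dict(raw["cohort_spec"])
            if "signal_rate_by_horizon" in cs:
                cs["signal_rate_by_horizon"] = tuple(
                    (int(k), float(v)) for k, v in dict(cs["signal_rate_by_horizon"]).items())
            if "age_range" in cs:
                cs["age_range"] = tuple(cs["age_range"])
            raw["cohort_spec"] = synth.SyntheticCohortSpec(**cs)
        for key in ("horizons", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _default_marker_defs(world: synth.SyntheticWorld) -> list[mds.MarkerDefinition]:
    """Attach synthetic prodromal concepts to the leading EHR-assessable markers."""
    defs = mds.default_markers()
    assessable = [d for d in defs if d.assessable]
    concept_map = {d.marker_id: {c} for d, c in zip(assessable, world.prodromal_concepts)}
    return mds.assign_marker_concepts(defs, concept_map)


def _cohort_config(config: ExperimentConfig) -> coh.CohortConfig:
    return coh.CohortConfig(
        pd_code_set=synth.PD_DX_CODES,
        pd_med_set=synth.PD_MED_CODES,
        neuroleptic_set=synth.NEUROLEPTIC_CODES,
        min_age_years=config.min_age_years,
        prevalence_per_100k=config.prevalence_per_100k,
        horizons_years=config.horizons,
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full per-horizon comparison; returns a JSON-serializable report."""
    world = synth.generate_kg(config.kg_spec)
    cohort_spec = config.cohort_spec
    if cohort_spec.seed != stage_seed(config.seed, "cohort"):
        cohort_spec = synth.SyntheticCohortSpec(
            **{**asdict(cohort_spec), "seed": stage_seed(config.seed, "cohort")})
    gen = (synth.generate_relayed_cohort(cohort_spec, world, config.train_fraction)
           if config.relayed else synth.generate_cohort(cohort_spec, world))
    ccfg = _cohort_config(config)
    records = {r.patient_id: r for r in gen.records}

    # --- indexing and exclusions (horizon-independent) --------------------
    candidates: list[coh.IndexedPatient] = []
    rejections: list[coh.Rejection] = []
    for r in gen.records:
        if gen.labels[r.patient_id] == 1:
            res = coh.assign_case_index(r, ccfg)
            (candidates if isinstance(res, coh.IndexedPatient) else rejections).append(res)
        else:
            candidates.append(coh.index_control(r, ccfg))
    included, excluded = coh.apply_exclusions(candidates, records, ccfg)
    rejections.extend(excluded)
    cases = [p for p in included if p.label == "case"]
    controls = [p for p in included if p.label == "control"]
    controls = coh.sample_prevalence(cases, controls, ccfg, stage_seed(config.seed, "prevalence"))

    reason_counts: dict[str, int] = {}
    for rej in rejections:
        reason_counts[rej.reason] = reason_counts.get(rej.reason, 0) + 1
    accounting = {
        "input_patients": len(gen.records),
        "included_cases": len(cases),
        "included_controls_before_sampling": sum(p.label == "control" for p in included),
        "controls_after_prevalence_sampling": len(controls),
        "excluded_by_reason": dict(sorted(reason_counts.items())),
    }

    transition = build_transition(world.kg)
    params = PSEVParams(damping=config.damping, tol=config.tol)
    marker_defs = _default_marker_defs(world)
    priors = mds.default_age_priors()
    types = world.kg.node_types()

    report: dict = {
        "seed": config.seed,
        "relayed": config.relayed,
        "model": config.model,
        "cohort_accounting": accounting,
        "horizons": {},
    }

    for horizon in config.horizons:
        pop = cases + controls
        windowed = {p.patient_id: coh.window_events(records[p.patient_id], p, horizon)
                    for p in pop}
        usable = [p for p in pop if windowed[p.patient_id].events]
        n_empty = len(pop) - len(usable)
        wrecords = [windowed[p.patient_id] for p in usable]

        psev = build_psev_matrix(world.kg, wrecords, world.mapping,
                                 transition=transition, params=params)
        sig, dropped = build_spokesig_matrix(wrecords, psev, world.mapping)
        keep = [p for p in usable if p.patient_id not in set(dropped)]
        krecords = [windowed[p.patient_id] for p in keep]
        raw = build_raw_matrix(krecords, world.mapping)
        mds_scores = mds.score_cohort({r.patient_id: r for r in krecords}, marker_defs,
                                      priors, keep)
        y = np.array([1 if p.label == "case" else 0 for p in keep])
        pid = [p.patient_id for p in keep]

        if config.relayed:
            fold = np.array([gen.folds[p] for p in pid])
            train_idx = np.flatnonzero(fold == "train")
            test_idx = np.flatnonzero(fold == "test")
        else:
            train_idx, test_idx = stats.split_train_test(
                len(keep), y, stats.SplitSpec(config.train_fraction, True,
                                              stage_seed(config.seed, f"split:{horizon}")))

        weights = stats.class_weights(y[train_idx])
        hreport: dict = {
            "n_modelled": len(keep),
            "n_empty_after_windowing": n_empty + len(dropped),
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
            "methods": {},
        }

        feature_matrices = {"spokesig": (sig.values, sig.node_ids),
                            "raw": (raw.values.astype(float), raw.concepts)}
        aucs: dict[str, stats.AUCDistribution] = {}
        for method in config.methods:
            if method == "mds":
                test_scores = np.array([mds_scores[pid[i]] for i in test_idx])
            else:
                X, _ = feature_matrices[method]
                scorer = stats.train_classifier(
                    X[train_idx], y[train_idx], weights, model=config.model,
                    seed=stage_seed(config.seed, f"train:{method}:{horizon}"))
                test_scores = scorer.scores(X[test_idx])
                if method == "spokesig":
                    imp = stats.importance_percentiles(scorer.importances, sig.node_ids, types)
                    hreport["top_disease_features"] = stats.top_features_by_type(
                        imp, "Disease", 15)[["node_id", "importance", "percentile"]]\
                        .to_dict("records")
            dist = stats.bootstrap_auc(
                test_scores, y[test_idx], n_boot=config.n_boot,
                sample_size=config.boot_sample_size,
                seed=stage_seed(config.seed, f"boot:{method}:{horizon}"))
            aucs[method] = dist
            hreport["methods"][method] = {
                "auc_mean": round(dist.mean, 6),
                "auc_sd": round(dist.sd, 6),
                "ci95": [round(dist.ci95[0], 6), round(dist.ci95[1], 6)],
            }

        fm = stats.feature_mannwhitney(sig.values, y, sig.node_ids, types)
        target_row = fm[fm.node_id == world.target_disease].iloc[0]
        hreport["target_disease_feature"] = {
            "node_id": world.target_disease,
            "p_value": float(target_row.p_value),
            "direction": float(target_row.direction),
        }

        comparisons = {}
        if "spokesig" in aucs and "raw" in aucs:
            t, p = stats.compare_auc_distributions(aucs["spokesig"], aucs["raw"], "t")
            comparisons["spokesig_vs_raw_t"] = {"statistic": round(t, 6), "p_value": p}
        if "spokesig" in aucs and "mds" in aucs:
            t, p = stats.compare_auc_distributions(aucs["spokesig"], aucs["mds"], "t")
            comparisons["spokesig_vs_mds_t"] = {"statistic": round(t, 6), "p_value": p}
        hreport["comparisons"] = comparisons
        report["horizons"][str(horizon)] = hreport

    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
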