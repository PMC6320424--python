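"""End-to-end orchestration: synth → visits → exclusions → standardize →
phenotype → patients → measures → validation, with a run manifest whose
stage counts chain against the exclusion log and mapping statistics."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .codemap import (
    Crosswalk,
    era_rule_from_cutover,
    phenotype_codes,
    standardize_diagnoses,
)
from .cohort import (
    RecordTables,
    apply_patient_exclusions,
    apply_visit_exclusions,
    build_patients,
    build_visits,
    filter_orphan_diagnoses,
    summarize_cohort,
)
from .measures import HousingLookup, compute_measures
from .synthgen import (
    SynthConfig,
    generate_emr,
    make_fixture_crosswalks,
    make_housing_lookup,
    make_inflation_index,
)
from .validate import run_validation

__all__ = ["run_pipeline", "write_artifacts"]


def _config_hash(config: SynthConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: SynthConfig | None = None,
    *,
    tables: RecordTables | None = None,
    icd10_xwalk: Crosswalk | None = None,
    ccs_xwalk: Crosswalk | None = None,
    housing_lookup: HousingLookup | None = None,
    inflation_index: dict | None = None,
    run_validation_stage: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Run the full cascade and return every stage artifact in memory.

    With only a :class:`SynthConfig`, the synthetic substrate supplies the
    tables, crosswalks, housing lookup and inflation index; externally
    loaded inputs can be passed instead.
    """
    if config is None:
        config = SynthConfig()
    ledger = None
    if tables is None:
        tables, ledger = generate_emr(config)
    if icd10_xwalk is None or ccs_xwalk is None:
        fx10, fxccs = make_fixture_crosswalks()
        icd10_xwalk = icd10_xwalk or fx10
        ccs_xwalk = ccs_xwalk or fxccs
    if housing_lookup is None:
        housing_lookup = make_housing_lookup(config)
    if inflation_index is None:
        inflation_index = make_inflation_index(config.base_year)
    window = (config.study_start, config.study_end)

    visits = build_visits(tables, inflation_index)
    visits_kept, visit_log = apply_visit_exclusions(visits, window, min_age=21)
    dx = filter_orphan_diagnoses(tables.diagnosis, visits_kept["visit_id"])
    era_rule = era_rule_from_cutover(config.cutover)
    std, map_stats = standardize_diagnoses(dx, icd10_xwalk, era_rule)
    std_kept = std[~std["excluded"]].copy()
    phen, phen_stats = phenotype_codes(std_kept, ccs_xwalk)
    patients = build_patients(
        visits_kept, tables.demographic, phen, study_end=config.study_end
    )
    patients_kept, patient_log = apply_patient_exclusions(patients)
    measures = compute_measures(patients_kept, housing_lookup)
    profile = summarize_cohort(measures, age_threshold=65)
    report = run_validation(measures, alpha=alpha) if run_validation_stage else None

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": {
            "records_in": {
                name: int(len(getattr(tables, name)))
                for name in ("demographic", "movement", "billing", "pharmacy",
                             "diagnosis")
            },
            "visits_built": int(len(visits)),
            "visits_kept": int(len(visits_kept)),
            "diagnoses_after_orphan_filter": int(len(dx)),
            "diagnoses_standardized": int(len(std_kept)),
            "diagnoses_unmapped": int(std["excluded"].sum()),
            "patients_built": int(len(patients)),
            "patients_kept": int(len(patients_kept)),
        },
        "exclusions": visit_log.to_records() + patient_log.to_records(),
        "mapping_stats": map_stats.to_dict(),
        "phenotype_stats": phen_stats.to_dict(),
    }
    return {
        "tables": tables,
        "ledger": ledger,
        "visits": visits,
        "visits_kept": visits_kept,
        "visit_log": visit_log,
        "diagnoses": dx,
        "standardized": std,
        "map_stats": map_stats,
        "phenotyped": phen,
        "phen_stats": phen_stats,
        "patients": patients,
        "patients_kept": patients_kept,
        "patient_log": patient_log,
        "measures": measures,
        "profile": profile,
        "validation": report,
        "manifest": manifest,
    }


def write_artifacts(result: dict, out_dir) -> None:
    """Write the standard file artifacts of a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: RecordTables = result["tables"]
    for name in ("demographic", "movement", "billing", "pharmacy", "diagnosis"):
        getattr(tables, name).to_csv(out / f"{name}.csv", index=False)
    result["visits_kept"].to_csv(out / "visits.csv", index=False)
    meas = result["measures"].copy()
    for col in ("codes", "categories"):
        if col in meas.columns:
            meas[col] = meas[col].apply(lambda t: ";".join(map(str, t)))
    meas.to_csv(out / "patients.csv", index=False)
    with open(out / "exclusion_log.json", "w") as fh:
        json.dump(result["manifest"]["exclusions"], fh, indent=2)
    with open(out / "mapping_stats.json", "w") as fh:
        json.dump(result["map_stats"].to_dict(), fh, indent=2)
    with open(out / "phenotype_stats.json", "w") as fh:
        json.dump(result["phen_stats"].to_dict(), fh, indent=2)
    with open(out / "profile.json", "w") as fh:
        json.dump(result["profile"], fh, indent=2)
    if result["validation"] is not None:
        with open(out / "validation_report.json", "w") as fh:
            json.dump(result["validation"], fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2)
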