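"""Visit/patient aggregation, exclusion rules, and the audit log."""

import numpy as np
import pandas as pd
import pytest

from emrforge.cohort import (
    ExclusionLog,
    RecordTables,
    adjust_inflation,
    apply_patient_exclusions,
    apply_visit_exclusions,
    build_patients,
    build_visits,
    filter_orphan_diagnoses,
    summarize_cohort,
)
from emrforge.errors import ConfigError, IntegrityError, SchemaError


def _tables(movement=None, billing=None, pharmacy=None, diagnosis=None,
            demographic=None):
    demo = demographic if demographic is not None else pd.DataFrame(
        [{"patient_id": "P1", "sex": "M", "race": "chinese",
          "singaporean": True, "birth_date": "1960-04-01",
          "postal_code": "H4001"}]
    )
    empty_mv = pd.DataFrame(columns=["patient_id", "visit_id", "visit_class",
                                     "admit_date", "discharge_date"])
    empty_bill = pd.DataFrame(columns=["patient_id", "visit_id", "charge",
                                       "subsidy", "subsidized", "year"])
    empty_rx = pd.DataFrame(columns=["patient_id", "visit_id", "drug_code",
                                     "is_prescription", "is_device"])
    empty_dx = pd.DataFrame(columns=["patient_id", "visit_id", "code", "role",
                                     "visit_date"])
    return RecordTables(
        demographic=demo,
        movement=movement if movement is not None else empty_mv,
        billing=billing if billing is not None else empty_bill,
        pharmacy=pharmacy if pharmacy is not None else empty_rx,
        diagnosis=diagnosis if diagnosis is not None else empty_dx,
    )


def test_build_visits_sums_bills_per_visit():
    mv = pd.DataFrame(
        [
            {"patient_id": "P1", "visit_id": "A", "visit_class": "SOC",
             "admit_date": "2008-01-10", "discharge_date": "2008-01-10"},
            {"patient_id": "P1", "visit_id": "B", "visit_class": "SOC",
             "admit_date": "2008-02-10", "discharge_date": "2008-02-10"},
        ]
    )
    bills = pd.DataFrame(
        [
            {"patient_id": "P1", "visit_id": "A", "charge": 100.0,
             "subsidy": 0.0, "subsidized": False, "year": 2008},
            {"patient_id": "P1", "visit_id": "A", "charge": 200.0,
             "subsidy": 0.0, "subsidized": False, "year": 2008},
            {"patient_id": "P1", "visit_id": "A", "charge": 50.0,
             "subsidy": 0.0, "subsidized": False, "year": 2008},
        ]
    )
    visits = build_visits(_tables(movement=mv, billing=bills))
    assert len(visits) == 2
    assert visits.set_index("visit_id").loc["A", "charge"] == 350.0


def test_build_visits_full_join_keeps_pharmacy_only_visit():
    rx = pd.DataFrame(
        [{"patient_id": "P1", "visit_id": "X", "drug_code": "D1",
          "is_prescription": True, "is_device": False}]
    )
    visits = build_visits(_tables(pharmacy=rx))
    assert list(visits["visit_id"]) == ["X"]
    assert visits.loc[0, "pps_visit"] == 1
    assert pd.isna(visits.loc[0, "visit_class"])


def test_build_visits_conflicting_movement_duplicates_error():
    mv = pd.DataFrame(
        [
            {"patient_id": "P1", "visit_id": "A", "visit_class": "SOC",
             "admit_date": "2008-01-10", "discharge_date": "2008-01-10"},
            {"patient_id": "P1", "visit_id": "A", "visit_class": "ED",
             "admit_date": "2008-01-11", "discharge_date": "2008-01-11"},
        ]
    )
    with pytest.raises(IntegrityError):
        build_visits(_tables(movement=mv))


def test_record_tables_schema_validation():
    with pytest.raises(SchemaError):
        RecordTables(
            demographic=pd.DataFrame({"patient_id": ["P1"]}),
            movement=pd.DataFrame(), billing=pd.DataFrame(),
            pharmacy=pd.DataFrame(), diagnosis=pd.DataFrame(),
        )


@pytest.mark.parametrize(
    "amount,year,index,expected",
    [(100.0, 2015, {2015: 1.0}, 100.0), (100.0, 2005, {2005: 1.30}, 130.0)],
)
def test_adjust_inflation(amount, year, index, expected):
    assert adjust_inflation(amount, year, index) == pytest.approx(expected)


def test_adjust_inflation_domain_errors():
    with pytest.raises(ValueError):
        adjust_inflation(-1.0, 2015, {2015: 1.0})
    with pytest.raises(ConfigError):
        adjust_inflation(10.0, 1999, {2015: 1.0})


def _visit_frame(rows):
    df = pd.DataFrame(rows)
    for col in ("admit_date", "discharge_date", "birth_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


WINDOW = ("2005-01-01", "2013-12-31")


def test_visit_window_rule_targets_inpatient_only():
    visits = _visit_frame(
        [
            # inpatient straddling the window start → dropped
            {"visit_id": "A", "visit_class": "inpatient",
             "admit_date": "2004-12-30", "discharge_date": "2005-01-05",
             "age_at_visit": 50.0},
            # outpatient visit on a 2004 date → retained by this rule
            {"visit_id": "B", "visit_class": "outpatient",
             "admit_date": "2004-06-01", "discharge_date": "2004-06-01",
             "age_at_visit": 50.0},
        ]
    )
    kept, log = apply_visit_exclusions(visits, WINDOW, min_age=21)
    assert list(kept["visit_id"]) == ["B"]
    assert log.removed("inpatient_outside_study_window") == 1


def test_visit_age_rule_boundary():
    visits = _visit_frame(
        [
            {"visit_id": "A", "visit_class": "SOC", "admit_date": "2008-01-01",
             "discharge_date": "2008-01-01", "age_at_visit": 20.0},  # 20y11m
            {"visit_id": "B", "visit_class": "SOC", "admit_date": "2008-01-01",
             "discharge_date": "2008-01-01", "age_at_visit": 21.0},
        ]
    )
    kept, log = apply_visit_exclusions(visits, WINDOW, min_age=21)
    assert list(kept["visit_id"]) == ["B"]
    assert log.removed("age_below_minimum_at_visit") == 1


def test_unparseable_dates_go_to_data_quality_rule():
    visits = _visit_frame(
        [{"visit_id": "A", "visit_class": "SOC", "admit_date": None,
          "discharge_date": None, "age_at_visit": np.nan}]
    )
    kept, log = apply_visit_exclusions(visits, WINDOW, min_age=21)
    assert kept.empty
    assert log.removed("data_quality_unresolvable_dates") == 1


def test_filter_orphan_diagnoses():
    dx = pd.DataFrame({"visit_id": ["A", "A", "B", "C", "C"], "code": list("vwxyz")})
    assert len(filter_orphan_diagnoses(dx, {"A", "C"})) == 4
    assert filter_orphan_diagnoses(dx, set()).empty


def _patients_for_exclusion():
    return pd.DataFrame(
        [
            {"patient_id": "P1", "has_primary_dx": False, "birth_year": 1950,
             "sex": "F", "codes": ("4019",)},
            {"patient_id": "P2", "has_primary_dx": True, "birth_year": 1900,
             "sex": "M", "codes": ("4019",)},
            {"patient_id": "P3", "has_primary_dx": True, "birth_year": 1901,
             "sex": "M", "codes": ("4019",)},
            {"patient_id": "P4", "has_primary_dx": True, "birth_year": 1960,
             "sex": "M", "codes": ("6469",)},  # pregnancy code on a male
            {"patient_id": "P5", "has_primary_dx": True, "birth_year": 1960,
             "sex": "F", "codes": ("6469",)},
        ]
    )


def test_patient_exclusion_rules_in_order():
    kept, log = apply_patient_exclusions(_patients_for_exclusion())
    assert set(kept["patient_id"]) == {"P3", "P5"}
    assert log.removed("no_primary_diagnosis") == 1
    assert log.removed("birth_year_1900_or_earlier") == 1
    assert log.removed("sex_incompatible_diagnosis") == 1
    rules = [r["rule"] for r in log.to_records()]
    assert rules.index("no_primary_diagnosis") < rules.index(
        "birth_year_1900_or_earlier"
    ) < rules.index("sex_incompatible_diagnosis")


def test_missing_sex_with_triggered_rule_is_data_quality():
    pats = pd.DataFrame(
        [{"patient_id": "P1", "has_primary_dx": True, "birth_year": 1950,
          "sex": None, "codes": ("6469",)}]
    )
    kept, log = apply_patient_exclusions(pats)
    assert kept.empty
    assert log.removed("data_quality_missing_sex") == 1


def test_build_patients_aggregates():
    visits = _visit_frame(
        [
            {"visit_id": "A", "patient_id": "P1", "visit_class": "inpatient",
             "admit_date": "2008-01-01", "length_of_stay": 2, "charge": 10.0,
             "charge_adj": 11.0, "subsidy": 0.0, "subsidy_adj": 0.0,
             "subsidized": True, "pps_visit": 3},
            {"visit_id": "B", "patient_id": "P1", "visit_class": "SOC",
             "admit_date": "2008-02-01", "length_of_stay": 0, "charge": 5.0,
             "charge_adj": 5.5, "subsidy": 1.0, "subsidy_adj": 1.1,
             "subsidized": False, "pps_visit": 9},
            {"visit_id": "C", "patient_id": "P1", "visit_class": "inpatient",
             "admit_date": "2008-03-01", "length_of_stay": 5, "charge": 20.0,
             "charge_adj": 22.0, "subsidy": 0.0, "subsidy_adj": 0.0,
             "subsidized": True, "pps_visit": 1},
        ]
    )
    demo = pd.DataFrame(
        [{"patient_id": "P1", "sex": "M", "race": "chinese",
          "singaporean": True, "birth_date": "1960-04-01",
          "postal_code": "H4001"}]
    )
    pats = build_patients(visits, demo, study_end="2013-12-31")
    row = pats.iloc[0]
    assert row["total_los"] == 7
    assert row["n_inpatient"] == 2 and row["n_soc"] == 1
    assert row["pps"] == 9
    assert row["total_charge_adj"] == pytest.approx(38.5)
    assert row["age_at_study_end"] == 53


def test_build_patients_unknown_patient_errors():
    visits = _visit_frame(
        [{"visit_id": "A", "patient_id": "P9", "visit_class": "SOC",
          "admit_date": "2008-01-01", "length_of_stay": 0, "charge": 0.0,
          "charge_adj": 0.0, "subsidy": 0.0, "subsidy_adj": 0.0,
          "subsidized": False, "pps_visit": 0}]
    )
    demo = pd.DataFrame(
        [{"patient_id": "P1", "sex": "M", "race": "chinese",
          "singaporean": True, "birth_date": "1960-04-01",
          "postal_code": "H4001"}]
    )
    with pytest.raises(IntegrityError):
        build_patients(visits, demo)


def test_exclusion_log_chain_validation():
    log = ExclusionLog()
    log.add("r1", "visit", 10, 8)
    with pytest.raises(IntegrityError):
        log.add("r2", "visit", 9, 9)  # breaks the chain
    with pytest.raises(IntegrityError):
        log.add("r3", "visit", 8, 9)  # increases rows


def test_summarize_cohort_counts_and_median():
    pats = pd.DataFrame(
        {
            "patient_id": list("abcd"),
            "sex": ["M", "M", "F", "F"],
            "total_charge_adj": [1.0, 2.0, 3.0, 100.0],
        }
    )
    profile = summarize_cohort(pats)
    assert profile["overall"]["sex"]["M"] == {"n": 2, "pct": 50.0}
    assert profile["overall"]["numeric"]["total_charge_adj"]["median"] == 2.5


# ---------------------------------------------------------------------------
# cascade invariants on the synthetic cohort


def test_exclusions_are_idempotent(small_run, small_cfg):
    window = (small_cfg.study_start, small_cfg.study_end)
    again, log = apply_visit_exclusions(small_run["visits_kept"], window, 21)
    assert len(again) == len(small_run["visits_kept"])
    assert all(r["n_removed"] == 0 for r in log.to_records())
    pats_again, plog = apply_patient_exclusions(small_run["patients_kept"])
    assert len(pats_again) == len(small_run["patients_kept"])
    assert all(r["n_removed"] == 0 for r in plog.to_records())


def test_cascade_level_consistency(small_run):
    tables = small_run["tables"]
    n_records = sum(
        len(getattr(tables, t)) for t in ("movement", "billing", "pharmacy")
    )
    assert len(small_run["patients_kept"]) <= len(small_run["visits_kept"])
    assert len(small_run["visits_kept"]) <= n_records


def test_aggregation_conserves_charges(small_run):
    visits = small_run["visits_kept"]
    pats = small_run["patients"]
    total_visit = visits["charge_adj"].sum()
    total_patient = pats["total_charge_adj"].sum()
    assert total_patient == pytest.approx(total_visit, rel=1e-9)
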