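"""Record → visit → patient cohort construction.

The EMR stores five record-level tables: one demographic row per patient,
and movement / billing / pharmacy / diagnosis rows keyed by (patient, visit).
Analysis needs two aggregated views:

* **visit level** — records aggregated within each table by visit id, the
  aggregates fully joined across tables, then linked to demographics;
* **patient level** — visit rows aggregated by patient id (sums for
  charges and length of stay, counts by visit class, logical OR for
  disease-category flags, max for the visit polypharmacy count).

Exclusion criteria are applied between the two levels and logged rule by
rule in an :class:`ExclusionLog` so that every dropped row is attributable
to exactly one rule and the before/after counts chain exactly.

Hospital charges are adjusted for inflation (to the index's base year)
*before* patient-level aggregation, so patient totals are in constant
dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError

__all__ = [
    "RecordTables",
    "ExclusionLog",
    "adjust_inflation",
    "build_visits",
    "apply_visit_exclusions",
    "filter_orphan_diagnoses",
    "build_patients",
    "apply_patient_exclusions",
    "load_invalid_dx_rules",
    "summarize_cohort",
]

_SCHEMAS = {
    "demographic": {"patient_id", "sex", "race", "singaporean", "birth_date", "postal_code"},
    "movement": {"patient_id", "visit_id", "visit_class", "admit_date", "discharge_date"},
    "billing": {"patient_id", "visit_id", "charge", "subsidy", "subsidized", "year"},
    "pharmacy": {"patient_id", "visit_id", "drug_code", "is_prescription", "is_device"},
    "diagnosis": {"patient_id", "visit_id", "code", "role", "visit_date"},
}

VISIT_CLASSES = ("inpatient", "SOC", "ED", "outpatient")


@dataclass
class RecordTables:
    """The five record-level EMR tables, schema-validated on construction."""

    demographic: pd.DataFrame
    movement: pd.DataFrame
    billing: pd.DataFrame
    pharmacy: pd.DataFrame
    diagnosis: pd.DataFrame

    def __post_init__(self) -> None:
        problems = []
        for name, required in _SCHEMAS.items():
            df = getattr(self, name)
            missing = required - set(df.columns)
            if missing:
                problems.append(f"{name}: missing columns {sorted(missing)}")
        if problems:
            raise SchemaError("; ".join(problems))
        if self.demographic["patient_id"].duplicated().any():
            raise SchemaError("demographic table has duplicate patient_id rows")


@dataclass
class ExclusionLog:
    """Ordered, chain-consistent audit of exclusion rules."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rule: str, level: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise IntegrityError(f"rule {rule!r} increased row count")
        if self.rows and self.rows[-1]["level"] == level:
            prev_after = self.rows[-1]["n_after"]
            if prev_after != n_before:
                raise IntegrityError(
                    f"exclusion chain broken at {rule!r}: {prev_after} != {n_before}"
                )
        self.rows.append(
            {
                "rule": rule,
                "level": level,
                "n_before": int(n_before),
                "n_removed": int(n_before - n_after),
                "n_after": int(n_after),
            }
        )

    def removed(self, rule: str) -> int:
        for row in self.rows:
            if row["rule"] == rule:
                return row["n_removed"]
        raise KeyError(rule)

    def extend(self, other: "ExclusionLog") -> None:
        for row in other.rows:
            self.rows.append(dict(row))

    def to_records(self) -> list[dict]:
        return [dict(r) for r in self.rows]


def adjust_inflation(amount: float, year: int, index: Mapping[int, float]) -> float:
    """Convert a nominal amount to base-year dollars via the index table."""
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    if year not in index:
        raise ConfigError(f"year {year} absent from inflation index table")
    return amount * index[year]


def _floor_years(start: pd.Series, end: pd.Series) -> pd.Series:
    """Completed years between two date series (floor of the interval)."""
    start = pd.to_datetime(start)
    end = pd.to_datetime(end)
    years = end.dt.year - start.dt.year
    before_birthday = (end.dt.month < start.dt.month) | (
        (end.dt.month == start.dt.month) & (end.dt.day < start.dt.day)
    )
    return years - before_birthday.astype(int)


def build_visits(
    tables: RecordTables, inflation_index: Mapping[int, float] | None = None
) -> pd.DataFrame:
    """Aggregate records to one row per visit and link demographics.

    Movement is expected to hold at most one row per visit; conflicting
    duplicates raise :class:`IntegrityError`.  Billing amounts are summed
    (inflation-adjusted per bill first when an index is given), the subsidy
    flag is OR-ed, and the visit polypharmacy count ``pps_visit`` is the
    number of distinct prescription, non-device drug codes.  The aggregates
    are full-outer-joined on visit id: a visit seen in any of the three
    tables exists exactly once in the result.
    """
    mv = tables.movement.copy()
    dup = mv.duplicated(subset="visit_id", keep=False)
    if dup.any():
        conflicting = mv[dup].groupby("visit_id").nunique(dropna=False)
        if (conflicting > 1).any().any():
            raise IntegrityError(
                f"conflicting duplicate movement rows for visits "
                f"{list(conflicting.index[:5])}"
            )
        mv = mv.drop_duplicates(subset="visit_id")
    mv = mv.set_index("visit_id")

    bill = tables.billing.copy()
    if inflation_index is not None:
        bill["charge_adj"] = [
            adjust_inflation(a, y, inflation_index)
            for a, y in zip(bill["charge"], bill["year"])
        ]
        bill["subsidy_adj"] = [
            adjust_inflation(a, y, inflation_index)
            for a, y in zip(bill["subsidy"], bill["year"])
        ]
    else:
        bill["charge_adj"] = bill["charge"]
        bill["subsidy_adj"] = bill["subsidy"]
    bill_agg = bill.groupby("visit_id").agg(
        patient_id_bill=("patient_id", "first"),
        charge=("charge", "sum"),
        charge_adj=("charge_adj", "sum"),
        subsidy=("subsidy", "sum"),
        subsidy_adj=("subsidy_adj", "sum"),
        subsidized=("subsidized", "any"),
    )

    rx = tables.pharmacy
    countable = rx[rx["is_prescription"].astype(bool) & ~rx["is_device"].astype(bool)]
    pps = countable.groupby("visit_id")["drug_code"].nunique().rename("pps_visit")
    rx_patient = rx.groupby("visit_id")["patient_id"].first().rename("patient_id_rx")

    visits = mv.join([bill_agg, pps, rx_patient], how="outer")
    visits["pps_visit"] = visits["pps_visit"].fillna(0).astype(int)
    for col in ("charge", "charge_adj", "subsidy", "subsidy_adj"):
        visits[col] = pd.to_numeric(visits[col], errors="coerce").fillna(0.0)
    visits["subsidized"] = (
        visits["subsidized"].astype(object).apply(lambda v: bool(v) if pd.notna(v) else False)
    )

    # coalesce patient id across the three sources
    pid = visits.get("patient_id")
    if pid is None:
        pid = pd.Series(np.nan, index=visits.index)
    for alt in ("patient_id_bill", "patient_id_rx"):
        if alt in visits.columns:
            pid = pid.astype(object).where(pid.notna(), visits[alt])
            visits = visits.drop(columns=alt)
    visits["patient_id"] = pid

    visits = visits.reset_index().rename(columns={"index": "visit_id"})
    demo = tables.demographic.set_index("patient_id")
    visits = visits.join(demo, on="patient_id")

    visits["admit_date"] = pd.to_datetime(visits["admit_date"], errors="coerce")
    visits["discharge_date"] = pd.to_datetime(visits["discharge_date"], errors="coerce")
    visits["birth_date"] = pd.to_datetime(visits["birth_date"], errors="coerce")

    inpat = visits["visit_class"] == "inpatient"
    los = (visits["discharge_date"] - visits["admit_date"]).dt.days
    visits["length_of_stay"] = np.where(inpat, los, 0)
    if (visits.loc[inpat, "length_of_stay"] < 0).any():
        raise IntegrityError("inpatient visit with discharge before admission")

    ok = visits["birth_date"].notna() & visits["admit_date"].notna()
    age = pd.Series(np.nan, index=visits.index)
    age[ok] = _floor_years(visits.loc[ok, "birth_date"], visits.loc[ok, "admit_date"])
    visits["age_at_visit"] = age
    return visits


def apply_visit_exclusions(
    visits: pd.DataFrame,
    window: tuple,
    min_age: float,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Visit-level exclusion rules, in order, each logged.

    1. data quality — visits whose dates or birth date cannot be resolved;
    2. study window — *inpatient* visits not fully inside ``window``
       (admission before its start or discharge after its end);
    3. minimum age — visits where the patient was younger than ``min_age``
       at the visit date.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    log = ExclusionLog()
    cur = visits

    unresolvable = cur["admit_date"].isna() | cur["age_at_visit"].isna()
    n0 = len(cur)
    cur = cur[~unresolvable]
    log.add("data_quality_unresolvable_dates", "visit", n0, len(cur))

    inpat = cur["visit_class"] == "inpatient"
    out_of_window = inpat & (
        (cur["admit_date"] < start) | (cur["discharge_date"] > end)
    )
    n0 = len(cur)
    cur = cur[~out_of_window]
    log.add("inpatient_outside_study_window", "visit", n0, len(cur))

    underage = cur["age_at_visit"] < min_age
    n0 = len(cur)
    cur = cur[~underage]
    log.add("age_below_minimum_at_visit", "visit", n0, len(cur))

    return cur.copy(), log


def filter_orphan_diagnoses(
    diagnoses: pd.DataFrame, kept_visit_ids: Iterable
) -> pd.DataFrame:
    """Keep only diagnoses attached to a visit that survived exclusions."""
    kept = set(kept_visit_ids)
    return diagnoses[diagnoses["visit_id"].isin(kept)].copy()


def build_patients(
    visits: pd.DataFrame,
    demographics: pd.DataFrame,
    diagnoses: pd.DataFrame | None = None,
    *,
    study_end=None,
) -> pd.DataFrame:
    """Aggregate included visits to one row per patient.

    Charges/subsidies are summed on the already inflation-adjusted columns;
    visit classes are counted; the patient polypharmacy score is the max
    over visit scores.  When the (standardized, phenotyped) diagnosis table
    is supplied, per-patient code and category sets plus a
    primary-diagnosis presence flag are attached.
    """
    unknown = set(visits["patient_id"].dropna()) - set(demographics["patient_id"])
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} visits reference patients absent from demographics, "
            f"e.g. {sorted(unknown)[:5]}"
        )

    g = visits.groupby("patient_id")
    pat = pd.DataFrame(
        {
            "n_visits": g.size(),
            "n_inpatient": g.apply(
                lambda d: int((d["visit_class"] == "inpatient").sum()),
                include_groups=False,
            ),
            "n_soc": g.apply(
                lambda d: int((d["visit_class"] == "SOC").sum()), include_groups=False
            ),
            "n_ed": g.apply(
                lambda d: int((d["visit_class"] == "ED").sum()), include_groups=False
            ),
            "n_outpatient": g.apply(
                lambda d: int((d["visit_class"] == "outpatient").sum()),
                include_groups=False,
            ),
            "total_los": g["length_of_stay"].sum(),
            "total_charge": g["charge"].sum(),
            "total_charge_adj": g["charge_adj"].sum(),
            "total_subsidy": g["subsidy"].sum(),
            "total_subsidy_adj": g["subsidy_adj"].sum(),
            "n_visits_subsidized": g["subsidized"].sum().astype(int),
            "pps": g["pps_visit"].max().astype(int),
            "first_visit": g["admit_date"].min(),
            "last_visit": g["admit_date"].max(),
        }
    )
    span_days = (pat["last_visit"] - pat["first_visit"]).dt.days + 1
    pat["observed_years"] = span_days / 365.25

    pat = pat.join(demographics.set_index("patient_id"), how="left")
    pat["birth_date"] = pd.to_datetime(pat["birth_date"], errors="coerce")
    pat["birth_year"] = pat["birth_date"].dt.year
    if study_end is not None:
        end = pd.Timestamp(study_end)
        ok = pat["birth_date"].notna()
        age = pd.Series(np.nan, index=pat.index)
        age[ok] = _floor_years(
            pat.loc[ok, "birth_date"], pd.Series(end, index=pat.index[ok])
        )
        pat["age_at_study_end"] = age

    if diagnoses is not None:
        dg = diagnoses.groupby("patient_id")
        code_col = "code_std" if "code_std" in diagnoses.columns else "code"
        pat["codes"] = dg[code_col].agg(
            lambda s: tuple(sorted(set(s.dropna())))
        )
        if "category" in diagnoses.columns:
            pat["categories"] = dg["category"].agg(
                lambda s: tuple(sorted(set(s.dropna())))
            )
        pat["has_primary_dx"] = dg["role"].agg(lambda s: bool((s == "primary").any()))
        for col, empty in (("codes", ()), ("categories", ()), ("has_primary_dx", False)):
            if col in pat.columns:
                pat[col] = pat[col].apply(
                    lambda v: empty if (v is None or v is np.nan) else v
                )
        pat["has_primary_dx"] = pat["has_primary_dx"].fillna(False).astype(bool)

    return pat.reset_index()


def load_invalid_dx_rules(path=None) -> pd.DataFrame:
    """Sex-specific invalid-diagnosis rules (``sex,prefix`` per row).

    Default file flags pregnancy/childbirth and female-infertility ICD-9-CM
    ranges for males, and prostate-range codes for females.
    """
    if path is None:
        path = resources.files("emrforge.data") / "invalid_dx_rules.csv"
    rules = pd.read_csv(path, dtype=str)
    missing = {"sex", "prefix"} - set(rules.columns)
    if missing:
        raise SchemaError(f"invalid-dx rules file missing columns {sorted(missing)}")
    return rules


def _matches_invalid_rule(codes: tuple, sex: str, rules: pd.DataFrame) -> bool:
    prefixes = rules.loc[rules["sex"] == sex, "prefix"]
    return any(str(c).startswith(p) for c in codes for p in prefixes)


def apply_patient_exclusions(
    patients: pd.DataFrame,
    invalid_dx_rules: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Patient-level exclusion rules, in order, each logged.

    1. no primary diagnosis on record;
    2. birth year 1900 or earlier (the EMR's default-birth-year sentinel);
    3. sex-incompatible diagnoses (e.g. pregnancy codes on male patients).

    Patients whose sex is missing while a sex-specific rule would need it
    are routed to a data-quality rule rather than silently kept.
    """
    if invalid_dx_rules is None:
        invalid_dx_rules = load_invalid_dx_rules()
    log = ExclusionLog()
    cur = patients

    n0 = len(cur)
    cur = cur[cur["has_primary_dx"].astype(bool)]
    log.add("no_primary_diagnosis", "patient", n0, len(cur))

    n0 = len(cur)
    cur = cur[~(cur["birth_year"] <= 1900)]
    log.add("birth_year_1900_or_earlier", "patient", n0, len(cur))

    codes = cur["codes"] if "codes" in cur.columns else pd.Series([()] * len(cur), index=cur.index)
    sex_missing = cur["sex"].isna()
    invalid = pd.Series(False, index=cur.index)
    unresolvable = pd.Series(False, index=cur.index)
    for idx in cur.index:
        if sex_missing.at[idx]:
            # would any sex-specific rule fire for either sex?
            if any(
                _matches_invalid_rule(codes.at[idx], s, invalid_dx_rules)
                for s in invalid_dx_rules["sex"].unique()
            ):
                unresolvable.at[idx] = True
        elif _matches_invalid_rule(codes.at[idx], cur.at[idx, "sex"], invalid_dx_rules):
            invalid.at[idx] = True
    n0 = len(cur)
    cur = cur[~invalid]
    log.add("sex_incompatible_diagnosis", "patient", n0, len(cur))
    n0 = len(cur)
    cur = cur[~unresolvable.loc[cur.index]]
    log.add("data_quality_missing_sex", "patient", n0, len(cur))

    return cur.copy(), log


# ---------------------------------------------------------------------------
# cohort profile


def _count_pct(series: pd.Series) -> dict:
    n = len(series)
    out = {}
    counts = series.fillna("missing").value_counts()
    for value, count in counts.items():
        out[str(value)] = {"n": int(count), "pct": round(100.0 * count / n, 2)}
    return out


def _median_iqr(series: pd.Series) -> dict:
    s = pd.to_numeric(series, errors="coerce").dropna()
    if s.empty:
        return {"total": 0, "median": None, "q1": None, "q3": None}
    return {
        "total": float(s.sum()),
        "median": float(s.median()),
        "q1": float(s.quantile(0.25)),
        "q3": float(s.quantile(0.75)),
    }


def summarize_cohort(
    patients: pd.DataFrame, *, age_threshold: float | None = None
) -> dict:
    """Cohort profile: categorical counts/percentages, disease prevalence,
    and median/IQR of utilization and complexity measures; optionally
    stratified at an age threshold (age as at study end)."""
    if patients.empty:
        raise ValueError("cannot profile an empty cohort")

    def profile(df: pd.DataFrame) -> dict:
        out: dict = {"n_patients": int(len(df))}
        for col in ("sex", "race", "subsidy_status", "housing_group"):
            if col in df.columns:
                out[col] = _count_pct(df[col])
        if "singaporean" in df.columns:
            out["singaporean"] = _count_pct(df["singaporean"].astype("boolean"))
        if "categories" in df.columns:
            flat = df["categories"].explode().dropna()
            prev = flat.value_counts()
            out["disease_prevalence"] = {
                str(c): {"n": int(n), "pct": round(100.0 * n / len(df), 2)}
                for c, n in prev.items()
            }
        for col in (
            "total_charge_adj",
            "n_inpatient",
            "n_soc",
            "n_ed",
            "n_outpatient",
            "total_los",
            "cci",
            "pps",
        ):
            if col in df.columns:
                out.setdefault("numeric", {})[col] = _median_iqr(df[col])
        return out

    report = {"overall": profile(patients)}
    if age_threshold is not None and "age_at_study_end" in patients.columns:
        older = patients["age_at_study_end"] > age_threshold
        if older.any():
            report[f"age_over_{age_threshold:g}"] = profile(patients[older])
        if (~older).any():
            report[f"age_up_to_{age_threshold:g}"] = profile(patients[~older])
    return report
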