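"""Synthetic five-table EMR substrate with a ground-truth ledger.

Real hospital EMR extracts cannot be shipped, so every pipeline stage is
exercised against generated data whose *construction* records the truth the
pipeline must recover:

* a **latent complexity tier** (3 levels) per patient jointly drives the
  comorbidity mix of their diagnosis codes, the number of drugs dispensed,
  visit rates per class, and charge magnitudes — the minimal structure
  under which the convergent/criterion validity analyses should pass;
* diagnosis codes are drawn from fixture pools whose crosswalk route
  (direct / zero-added / truncated / unmapped) is planted by construction,
  with the nosology decided by visit date against the coding cut-over;
* billing subsidy flags and subsidy fractions depend on the patient's
  planted housing group, so housing × subsidy dependence and a monotone
  RSR gradient are built in;
* known numbers of rule violators are planted: under-21 visits,
  inpatient stays crossing the study window, default-1900 birth years,
  males with pregnancy codes, and patients with no primary diagnosis.

Everything is deterministic given the config seed.  The
:class:`GroundTruthLedger` stores planted per-patient values, per-route
conversion counts (over diagnoses attached to surviving visits), expected
exclusion counts per rule, and expected visit/patient aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import RecordTables
from .codemap import Crosswalk
from .errors import ConfigError
from .measures import HousingLookup

__all__ = [
    "SynthConfig",
    "GroundTruthLedger",
    "generate_emr",
    "make_fixture_crosswalks",
    "make_housing_lookup",
    "make_inflation_index",
    "fixture_route_table",
]

# ---------------------------------------------------------------------------
# fixture code universes
#
# ICD-10-AM-like source codes with their planted conversion route.  The
# route is forced by which keys exist in the fixture crosswalk, e.g. a
# "zero_added_1" code is absent as a key while code+"0" is present.

_ICD10_DIRECT = {
    # benign / chronic-mild conditions
    "A09": "0091", "I10": "4019", "E780": "2720", "J459": "49390",
    # mid-severity chronic disease
    "E119": "25000", "E1122": "25040", "J449": "496", "M069": "7140",
    "K259": "531", "F00": "290", "G819": "342", "K746": "5712",
    # severe / high-weight comorbidity
    "I219": "41001", "I509": "4280", "N179": "5849", "C679": "1889",
    "C349": "1629", "C800": "1990", "B24": "042", "I639": "43491",
    # sex-specific (only drawn for planted roles / female patients)
    "O269": "6469", "N979": "628",
}
_ICD10_AMBIGUOUS = {"S720": ("82000", "8208")}  # multi-target key
_ICD10_ZERO1 = {"N39": ("N390", "5990"), "I48": ("I480", "42731"),
                "K52": ("K520", "5589")}  # source → (key, target)
_ICD10_ZERO2 = {"E11": ("E1100", "25000"), "J20": ("J2000", "4660")}
_ICD10_TRUNC = {"K3580": ("K35", "5409"), "I2510": ("I251", "412"),
                "M54161": ("M541", "7242")}
_ICD10_UNMAPPED = ("Z999", "U071", "Q999", "X450")

# ICD-9-CM codes → CCS-style mutually exclusive disease categories
_CCS_DIRECT = {
    "0091": "intestinal infection", "5589": "intestinal infection",
    "4019": "essential hypertension", "4010": "essential hypertension",
    "2720": "disorders of lipid metabolism",
    "25000": "diabetes mellitus", "25040": "diabetes mellitus",
    "250": "diabetes mellitus",
    "41001": "acute myocardial infarction", "412": "acute myocardial infarction",
    "4280": "congestive heart failure",
    "496": "copd and bronchiectasis",
    "5849": "acute renal failure",
    "1889": "cancer of bladder",
    "290": "dementia",
    "342": "paralysis",
    "5712": "liver disease",
    "1629": "cancer of lung",
    "1990": "secondary malignancy",
    "042": "hiv infection",
    "49390": "asthma",
    "43491": "acute cerebrovascular disease",
    "6469": "pregnancy complication",
    "628": "female infertility",
    "7140": "rheumatoid arthritis",
    "531": "peptic ulcer",
    "185": "cancer of prostate",
    "5990": "urinary tract infection",
    "82000": "hip fracture", "8208": "hip fracture",
    "42731": "cardiac dysrhythmias",
    "4660": "upper respiratory infection", "46500": "upper respiratory infection",
    "5409": "appendicitis",
    "7242": "back problem",
}
_ICD9_ZERO1 = {"401": "4010"}     # source → key that catches it
_ICD9_ZERO2 = {"465": "46500"}
_ICD9_TRUNC = {"25001": "250", "53190": "531"}
_ICD9_UNMAPPED = ("7999", "8889")

# severity pools per era (sex-sensitive codes excluded from random draws)
_ICD10_POOLS = {
    "benign": ["A09", "I10", "E780", "J459"],
    "mid": ["E119", "E1122", "J449", "M069", "K259", "F00", "G819", "K746"],
    "severe": ["I219", "I509", "N179", "C679", "C349", "C800", "B24", "I639",
               "S720"],
}
_ICD9_POOLS = {
    "benign": ["4019", "2720", "0091", "5589", "4660", "5409", "7242", "82000"],
    "mid": ["25000", "25040", "496", "42731", "290", "5712", "531", "7140",
            "49390", "342"],
    "severe": ["41001", "4280", "5849", "1889", "1629", "1990", "042", "43491",
               "412"],
}
# planted CCS routes for non-direct ICD-9-era draws
_ICD9_ROUTE_CODES = {
    "zero_added": list(_ICD9_ZERO1) + list(_ICD9_ZERO2),
    "truncated": list(_ICD9_TRUNC),
    "unmapped": list(_ICD9_UNMAPPED),
}
_ICD10_ROUTE_CODES = {
    "zero_added": list(_ICD10_ZERO1) + list(_ICD10_ZERO2),
    "truncated": list(_ICD10_TRUNC),
    "unmapped": list(_ICD10_UNMAPPED),
}

HOUSING_GROUP_NAMES = (
    "rental/studio/1-2-room", "3-room", "4-room", "5-room/executive",
    "private", "missing",
)


def make_fixture_crosswalks() -> tuple[Crosswalk, Crosswalk]:
    """The ~60-key fixture crosswalks with planted conversion routes."""
    icd10_entries: dict[str, tuple[str, ...]] = {
        k: (v,) for k, v in _ICD10_DIRECT.items()
    }
    icd10_entries.update({k: v for k, v in _ICD10_AMBIGUOUS.items()})
    for _, (key, target) in {**_ICD10_ZERO1, **_ICD10_ZERO2, **_ICD10_TRUNC}.items():
        icd10_entries[key] = (target,)
    icd10 = Crosswalk(icd10_entries, "ICD10", "ICD9")
    ccs = Crosswalk(
        {k: (v,) for k, v in _CCS_DIRECT.items()}, "ICD9", "CCS"
    )
    return icd10, ccs


def fixture_route_table() -> pd.DataFrame:
    """Every fixture source code with its planted route and expected target
    (the by-construction oracle for the conversion engine)."""
    rows = []
    for code, tgt in _ICD10_DIRECT.items():
        rows.append(("ICD10", code, "direct", tgt, False))
    for code, tgts in _ICD10_AMBIGUOUS.items():
        rows.append(("ICD10", code, "direct", tgts[0], True))
    for code, (_, tgt) in _ICD10_ZERO1.items():
        rows.append(("ICD10", code, "zero_added_1", tgt, False))
    for code, (_, tgt) in _ICD10_ZERO2.items():
        rows.append(("ICD10", code, "zero_added_2", tgt, False))
    for code, (key, tgt) in _ICD10_TRUNC.items():
        rows.append(("ICD10", code, f"truncated({len(code) - len(key)})", tgt, False))
    for code in _ICD10_UNMAPPED:
        rows.append(("ICD10", code, "unmapped", None, False))
    for code, cat in _CCS_DIRECT.items():
        rows.append(("ICD9", code, "direct", cat, False))
    for code, key in {**_ICD9_ZERO1, **_ICD9_ZERO2}.items():
        method = "zero_added_1" if len(key) == len(code) + 1 else "zero_added_2"
        rows.append(("ICD9", code, method, _CCS_DIRECT[key], False))
    for code, key in _ICD9_TRUNC.items():
        rows.append(("ICD9", code, f"truncated({len(code) - len(key)})",
                     _CCS_DIRECT[key], False))
    for code in _ICD9_UNMAPPED:
        rows.append(("ICD9", code, "unmapped", None, False))
    return pd.DataFrame(
        rows, columns=["nosology", "code", "route", "target", "ambiguous"]
    )


# postal codes per resolved housing group; includes one mixed block (M0001,
# majority 3-room) and one exact-tie block (T0001, tie broken to 5-room).
_PUBLIC_BLOCKS = {
    "R0001": {"rental": 1.0},
    "R0002": {"1-room": 0.7, "2-room": 0.3},
    "R0003": {"studio": 1.0},
    "H3001": {"3-room": 1.0},
    "H3002": {"3-room": 1.0},
    "M0001": {"3-room": 0.6, "4-room": 0.4},
    "H4001": {"4-room": 1.0},
    "H4002": {"4-room": 1.0},
    "H5001": {"5-room": 1.0},
    "H5002": {"executive": 1.0},
    "T0001": {"4-room": 0.5, "5-room": 0.5},
}
_PRIVATE_POSTALS = ("P0001", "P0002", "P0003", "P0004")
_NONRESIDENTIAL = ("N9001", "N9002")  # on neither list → missing
_POSTALS_BY_GROUP = {
    "rental/studio/1-2-room": ["R0001", "R0002", "R0003"],
    "3-room": ["H3001", "H3002", "M0001"],
    "4-room": ["H4001", "H4002"],
    "5-room/executive": ["H5001", "H5002", "T0001"],
    "private": list(_PRIVATE_POSTALS),
    "missing": list(_NONRESIDENTIAL),
}


def make_housing_lookup(config: "SynthConfig | None" = None) -> HousingLookup:
    """Postal-code lookup with mixed and tie blocks and a private list."""
    return HousingLookup(
        {k: dict(v) for k, v in _PUBLIC_BLOCKS.items()},
        frozenset(_PRIVATE_POSTALS),
    )


def make_inflation_index(base_year: int = 2015) -> dict[int, float]:
    """Year → multiplier-to-base-year table (base year maps to 1.0)."""
    index = {y: round(1.0 + 0.025 * (base_year - y), 4) for y in range(2004, 2014)}
    index[base_year] = 1.0
    return index


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions used
    throughout the test-bed (5000 adult patients, 2005–2013 window,
    2010 coding cut-over)."""

    n_patients: int = 5000
    seed: int = 7
    study_start: str = "2005-01-01"
    study_end: str = "2013-12-31"
    cutover: str = "2010-01-01"
    base_year: int = 2015

    # latent complexity tiers
    tier_probs: tuple[float, ...] = (0.60, 0.30, 0.10)
    inpatient_mean: tuple[float, ...] = (0.25, 1.2, 3.0)
    soc_mean: tuple[float, ...] = (2.0, 5.0, 10.0)
    ed_mean: tuple[float, ...] = (0.7, 1.4, 2.5)
    outpatient_mean: tuple[float, ...] = (2.0, 4.0, 6.0)
    visit_dispersion: float = 1.5  # NB size parameter, shared across classes
    drug_mean: tuple[float, ...] = (1.5, 4.0, 8.0)  # Poisson, per visit
    severity_weights: tuple[tuple[float, ...], ...] = (
        (0.80, 0.18, 0.02), (0.45, 0.40, 0.15), (0.20, 0.35, 0.45),
    )  # per tier: P(benign / mid / severe code)
    extra_dx_mean: float = 1.2  # secondary diagnoses per visit (Poisson)

    # conversion-route mix for randomly drawn codes
    icd10_route_probs: dict = field(
        default_factory=lambda: {"direct": 0.84, "zero_added": 0.04,
                                 "truncated": 0.03, "unmapped": 0.09}
    )
    icd9_route_probs: dict = field(
        default_factory=lambda: {"direct": 0.88, "zero_added": 0.07,
                                 "truncated": 0.03, "unmapped": 0.02}
    )

    # demographics / SES
    p_male: float = 0.55
    p_singaporean: float = 0.65
    race_probs: dict = field(
        default_factory=lambda: {"chinese": 0.60, "indian": 0.13,
                                 "malay": 0.12, "others": 0.15}
    )
    housing_probs: dict = field(
        default_factory=lambda: {
            "rental/studio/1-2-room": 0.05, "3-room": 0.17, "4-room": 0.26,
            "5-room/executive": 0.22, "private": 0.12, "missing": 0.18,
        }
    )
    subsidy_p_by_housing: dict = field(
        default_factory=lambda: {
            "rental/studio/1-2-room": 0.85, "3-room": 0.75, "4-room": 0.70,
            "5-room/executive": 0.62, "private": 0.44, "missing": 0.65,
        }
    )
    subsidy_rate_by_housing: dict = field(
        default_factory=lambda: {
            "rental/studio/1-2-room": 0.62, "3-room": 0.55, "4-room": 0.50,
            "5-room/executive": 0.44, "private": 0.35, "missing": 0.50,
        }
    )  # Beta-distributed subsidized fraction of the bill, by housing

    # charges (lognormal), scaled by visit class and tier
    charge_log_mean: float = 5.5
    charge_log_sd: float = 0.8
    class_charge_factor: dict = field(
        default_factory=lambda: {"inpatient": 6.0, "SOC": 1.0, "ED": 1.5,
                                 "outpatient": 0.7}
    )
    tier_charge_factor: tuple[float, ...] = (1.0, 1.4, 2.2)

    # planted rule violators
    n_young_patients: int = 6
    underage_visits_per_patient: int = 2
    n_prewindow_inpatient: int = 8
    n_no_pd_patients: int = 10
    n_birth1900_patients: int = 7
    n_invalid_male_patients: int = 9

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be ≥ 1")
        for name in ("tier_probs",):
            if abs(sum(getattr(self, name)) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for name in ("icd10_route_probs", "icd9_route_probs", "race_probs",
                     "housing_probs"):
            d = getattr(self, name)
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ConfigError(f"{name} has probabilities outside [0,1]")
        planted = (self.n_young_patients + self.n_no_pd_patients
                   + self.n_birth1900_patients + self.n_invalid_male_patients)
        if planted + 10 > self.n_patients:
            raise ConfigError(
                "n_patients too small for the planted rule violators"
            )


@dataclass
class GroundTruthLedger:
    """Everything the generator planted, for exact downstream checks."""

    patient_tier: dict = field(default_factory=dict)
    patient_housing_group: dict = field(default_factory=dict)
    patient_subsidy_p: dict = field(default_factory=dict)
    icd10_route_counts: dict = field(default_factory=dict)  # role → route → n
    ccs_route_counts: dict = field(default_factory=dict)
    expected_exclusions: dict = field(default_factory=dict)  # rule → n removed
    n_visits_total: int = 0
    n_visits_kept: int = 0
    n_diagnoses_total: int = 0
    n_diagnoses_kept: int = 0
    excluded_visit_ids: set = field(default_factory=set)
    excluded_patient_ids: set = field(default_factory=set)
    visit_expected: pd.DataFrame | None = None  # per kept visit
    patient_expected: pd.DataFrame | None = None  # per final-cohort patient

    def to_dict(self) -> dict:
        out = {
            "icd10_route_counts": self.icd10_route_counts,
            "ccs_route_counts": self.ccs_route_counts,
            "expected_exclusions": self.expected_exclusions,
            "n_visits_total": self.n_visits_total,
            "n_visits_kept": self.n_visits_kept,
            "n_diagnoses_total": self.n_diagnoses_total,
            "n_diagnoses_kept": self.n_diagnoses_kept,
            "n_excluded_patients": len(self.excluded_patient_ids),
        }
        return out


# ---------------------------------------------------------------------------
# generation


def _floor_age(birth: date, at: date) -> int:
    return at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))


def _rand_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _neg_binomial(rng: np.random.Generator, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def generate_emr(config: SynthConfig) -> tuple[RecordTables, GroundTruthLedger]:
    """Generate the five record-level tables plus the ground-truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = date.fromisoformat(config.study_start)
    end = date.fromisoformat(config.study_end)
    cutover = date.fromisoformat(config.cutover)
    index = make_inflation_index(config.base_year)

    ledger = GroundTruthLedger()
    roles = ("primary", "secondary")
    ledger.icd10_route_counts = {
        r: {m: 0 for m in ("direct", "zero_added", "truncated", "unmapped")}
        for r in (*roles, "combined")
    }
    ledger.ccs_route_counts = {
        r: {m: 0 for m in ("direct", "zero_added", "truncated", "unmapped")}
        for r in (*roles, "combined")
    }

    # assign planted violator roles to disjoint patient indices
    idx = 0
    role_of: dict[int, str] = {}
    for role_name, count in (
        ("young", config.n_young_patients),
        ("no_pd", config.n_no_pd_patients),
        ("birth1900", config.n_birth1900_patients),
        ("invalid_male", config.n_invalid_male_patients),
    ):
        for _ in range(count):
            role_of[idx] = role_name
            idx += 1

    tiers = rng.choice(len(config.tier_probs), size=config.n_patients,
                       p=config.tier_probs)
    housing_names = list(config.housing_probs)
    housing_draws = rng.choice(
        len(housing_names), size=config.n_patients,
        p=[config.housing_probs[h] for h in housing_names],
    )
    race_names = list(config.race_probs)

    demo_rows, mv_rows, bill_rows, rx_rows, dx_rows = [], [], [], [], []
    visit_truth: list[dict] = []  # per-visit bookkeeping
    dx_truth: list[dict] = []
    prewindow_left = config.n_prewindow_inpatient
    visit_seq = 0

    def draw_code(era: str, tier: int, route_probs: dict) -> tuple[str, str]:
        """(code, route family) for one randomly drawn diagnosis."""
        routes = list(route_probs)
        route = routes[rng.choice(len(routes), p=[route_probs[r] for r in routes])]
        if route == "direct":
            pools = _ICD10_POOLS if era == "ICD10" else _ICD9_POOLS
            sev = ("benign", "mid", "severe")[
                rng.choice(3, p=config.severity_weights[tier])
            ]
            code = pools[sev][rng.integers(0, len(pools[sev]))]
        else:
            codes = (_ICD10_ROUTE_CODES if era == "ICD10" else _ICD9_ROUTE_CODES)[
                route
            ]
            code = codes[rng.integers(0, len(codes))]
        return code, route

    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        special = role_of.get(i)
        tier = int(tiers[i])
        sex = "M" if rng.random() < config.p_male else "F"
        if special == "invalid_male":
            sex = "M"
        race = race_names[rng.choice(len(race_names),
                                     p=[config.race_probs[r] for r in race_names])]
        singaporean = bool(rng.random() < config.p_singaporean)
        housing = housing_names[housing_draws[i]]
        postal = _POSTALS_BY_GROUP[housing][
            rng.integers(0, len(_POSTALS_BY_GROUP[housing]))
        ]
        if special == "birth1900":
            birth = date(1900, int(rng.integers(1, 13)), int(rng.integers(1, 28)))
        elif special == "young":
            birth = date(1990, int(rng.integers(1, 13)), int(rng.integers(1, 28)))
        else:
            birth = date(int(rng.integers(1930, 1981)),
                         int(rng.integers(1, 13)), int(rng.integers(1, 28)))
        demo_rows.append(
            {"patient_id": pid, "sex": sex, "race": race,
             "singaporean": singaporean, "birth_date": birth.isoformat(),
             "postal_code": postal}
        )
        ledger.patient_tier[pid] = tier
        ledger.patient_housing_group[pid] = housing
        p_sub = config.subsidy_p_by_housing[housing]
        ledger.patient_subsidy_p[pid] = p_sub

        # --- visit plan -----------------------------------------------------
        n_by_class = {
            "inpatient": _neg_binomial(rng, config.inpatient_mean[tier],
                                       config.visit_dispersion),
            "SOC": _neg_binomial(rng, config.soc_mean[tier],
                                 config.visit_dispersion),
            "ED": _neg_binomial(rng, config.ed_mean[tier],
                                config.visit_dispersion),
            "outpatient": _neg_binomial(rng, config.outpatient_mean[tier],
                                        config.visit_dispersion),
        }
        if sum(n_by_class.values()) == 0:
            n_by_class["outpatient"] = 1

        plan: list[dict] = []  # visit specs: class, admit, excluded_by
        if special == "young":
            adult_from = date(birth.year + 21, birth.month, birth.day)
            for _ in range(config.underage_visits_per_patient):
                admit = _rand_date(rng, start, adult_from - timedelta(days=30))
                plan.append({"class": "SOC", "admit": admit,
                             "excluded_by": "age_below_minimum_at_visit"})
            # ensure adult visits exist
            for cls in ("SOC", "outpatient"):
                plan.append({"class": cls,
                             "admit": _rand_date(rng, adult_from, end),
                             "excluded_by": None})
        else:
            for cls, n in n_by_class.items():
                for _ in range(n):
                    admit = _rand_date(rng, start, end)
                    plan.append({"class": cls, "admit": admit,
                                 "excluded_by": None})
        if special is None and prewindow_left > 0 and rng.random() < 0.5:
            admit = _rand_date(rng, start - timedelta(days=360),
                               start - timedelta(days=10))
            plan.append({"class": "inpatient", "admit": admit,
                         "excluded_by": "inpatient_outside_study_window"})
            prewindow_left -= 1

        # guarantee a kept visit to anchor the primary diagnosis
        kept_plan = [v for v in plan if v["excluded_by"] is None]
        if not kept_plan:
            v = {"class": "outpatient", "admit": _rand_date(rng, start, end),
                 "excluded_by": None}
            plan.append(v)
            kept_plan = [v]
        anchor = kept_plan[int(rng.integers(0, len(kept_plan)))]

        # --- emit visit rows ------------------------------------------------
        for v in plan:
            visit_seq += 1
            vid = f"V{visit_seq:08d}"
            v["visit_id"] = vid
            admit: date = v["admit"]
            if v["class"] == "inpatient":
                los = int(rng.geometric(1.0 / (2.0 + 2.0 * tier)))
                discharge = admit + timedelta(days=los)
                if v["excluded_by"] is None and discharge > end:
                    discharge = end
                    los = (discharge - admit).days
            else:
                los = 0
                discharge = admit
            mv_rows.append(
                {"patient_id": pid, "visit_id": vid, "visit_class": v["class"],
                 "admit_date": admit.isoformat(),
                 "discharge_date": discharge.isoformat()}
            )

            # billing: 1–3 bills, all in the admission year
            n_bills = int(rng.integers(1, 4))
            year = admit.year
            subsidized = bool(rng.random() < p_sub)
            rate = 0.0
            if subsidized:
                mean_rate = config.subsidy_rate_by_housing[housing]
                conc = 30.0
                rate = float(rng.beta(mean_rate * conc, (1 - mean_rate) * conc))
            charge_total = 0.0
            subsidy_total = 0.0
            for _ in range(n_bills):
                charge = float(
                    np.round(
                        rng.lognormal(config.charge_log_mean, config.charge_log_sd)
                        * config.class_charge_factor[v["class"]]
                        * config.tier_charge_factor[tier],
                        2,
                    )
                )
                subsidy = float(np.round(charge * rate, 2))
                bill_rows.append(
                    {"patient_id": pid, "visit_id": vid, "charge": charge,
                     "subsidy": subsidy, "subsidized": subsidized, "year": year}
                )
                charge_total += charge
                subsidy_total += subsidy

            # pharmacy
            n_drugs = int(rng.poisson(config.drug_mean[tier]))
            drugs = rng.choice(300, size=min(n_drugs, 300), replace=False)
            for d in drugs:
                rx_rows.append(
                    {"patient_id": pid, "visit_id": vid,
                     "drug_code": f"D{d + 1:04d}",
                     "is_prescription": True, "is_device": False}
                )
            if rng.random() < 0.30:
                rx_rows.append(
                    {"patient_id": pid, "visit_id": vid, "drug_code": "OTC001",
                     "is_prescription": False, "is_device": False}
                )
            if rng.random() < 0.20:
                rx_rows.append(
                    {"patient_id": pid, "visit_id": vid, "drug_code": "DEV001",
                     "is_prescription": True, "is_device": True}
                )

            # diagnoses
            era = "ICD9" if admit < cutover else "ICD10"
            route_probs = (config.icd9_route_probs if era == "ICD9"
                           else config.icd10_route_probs)
            visit_dx: list[tuple[str, str, str]] = []  # (code, role, route)
            if special == "no_pd":
                n_sec = 1 + int(rng.poisson(config.extra_dx_mean))
                for _ in range(n_sec):
                    code, route = draw_code(era, tier, route_probs)
                    visit_dx.append((code, "secondary", route))
            else:
                if v is anchor:
                    # anchor primary: guaranteed-mappable severity draw
                    pools = _ICD10_POOLS if era == "ICD10" else _ICD9_POOLS
                    sev = ("benign", "mid", "severe")[
                        rng.choice(3, p=config.severity_weights[tier])
                    ]
                    code = pools[sev][rng.integers(0, len(pools[sev]))]
                    visit_dx.append((code, "primary", "direct"))
                elif rng.random() < 0.75:
                    code, route = draw_code(era, tier, route_probs)
                    visit_dx.append((code, "primary", route))
                for _ in range(int(rng.poisson(config.extra_dx_mean))):
                    code, route = draw_code(era, tier, route_probs)
                    visit_dx.append((code, "secondary", route))
                if special == "invalid_male" and v is anchor:
                    code = "O269" if era == "ICD10" else "6469"
                    visit_dx.append((code, "secondary", "direct"))
            for code, role, route in visit_dx:
                dx_rows.append(
                    {"patient_id": pid, "visit_id": vid, "code": code,
                     "role": role, "visit_date": admit.isoformat(),
                     "nosology": era}
                )
                dx_truth.append(
                    {"patient_id": pid, "visit_id": vid, "era": era,
                     "role": role, "route": route,
                     "kept_visit": v["excluded_by"] is None}
                )

            mult = index[year]
            visit_truth.append(
                {"patient_id": pid, "visit_id": vid, "visit_class": v["class"],
                 "admit": admit, "los": los, "charge": charge_total,
                 "charge_adj": charge_total * mult,
                 "subsidy": subsidy_total, "subsidy_adj": subsidy_total * mult,
                 "subsidized": subsidized,
                 "pps_visit": len(drugs),
                 "excluded_by": v["excluded_by"], "special": special}
            )

    # ------------------------------------------------------------------ ledger
    vt = pd.DataFrame(visit_truth)
    dt = pd.DataFrame(dx_truth)
    ledger.n_visits_total = len(vt)
    kept_visits = vt[vt["excluded_by"].isna()]
    ledger.n_visits_kept = len(kept_visits)
    ledger.excluded_visit_ids = set(vt.loc[vt["excluded_by"].notna(), "visit_id"])
    ledger.n_diagnoses_total = len(dt)
    kept_dx = dt[dt["kept_visit"]]
    ledger.n_diagnoses_kept = len(kept_dx)

    for role in roles:
        sub10 = kept_dx[(kept_dx["era"] == "ICD10") & (kept_dx["role"] == role)]
        for route, n in sub10["route"].value_counts().items():
            ledger.icd10_route_counts[role][route] += int(n)
    for m in ledger.icd10_route_counts["combined"]:
        ledger.icd10_route_counts["combined"][m] = (
            ledger.icd10_route_counts["primary"][m]
            + ledger.icd10_route_counts["secondary"][m]
        )
    # CCS stage sees ICD-9-era codes (planted CCS routes) plus successfully
    # converted ICD-10-era codes (whose targets are all direct CCS keys)
    for role in roles:
        sub9 = kept_dx[(kept_dx["era"] == "ICD9") & (kept_dx["role"] == role)]
        for route, n in sub9["route"].value_counts().items():
            ledger.ccs_route_counts[role][route] += int(n)
        sub10 = kept_dx[
            (kept_dx["era"] == "ICD10") & (kept_dx["role"] == role)
            & (kept_dx["route"] != "unmapped")
        ]
        ledger.ccs_route_counts[role]["direct"] += int(len(sub10))
    for m in ledger.ccs_route_counts["combined"]:
        ledger.ccs_route_counts["combined"][m] = (
            ledger.ccs_route_counts["primary"][m]
            + ledger.ccs_route_counts["secondary"][m]
        )

    ledger.expected_exclusions = {
        "inpatient_outside_study_window": int(
            (vt["excluded_by"] == "inpatient_outside_study_window").sum()
        ),
        "age_below_minimum_at_visit": int(
            (vt["excluded_by"] == "age_below_minimum_at_visit").sum()
        ),
        "no_primary_diagnosis": config.n_no_pd_patients,
        "birth_year_1900_or_earlier": config.n_birth1900_patients,
        "sex_incompatible_diagnosis": config.n_invalid_male_patients,
    }
    excluded_specials = {"no_pd", "birth1900", "invalid_male"}
    ledger.excluded_patient_ids = set(
        vt.loc[vt["special"].isin(excluded_specials), "patient_id"]
    )

    ledger.visit_expected = (
        kept_visits[["visit_id", "patient_id", "visit_class", "los", "charge",
                     "charge_adj", "subsidy", "subsidy_adj", "subsidized",
                     "pps_visit"]]
        .set_index("visit_id")
        .sort_index()
    )
    final = kept_visits[~kept_visits["special"].isin(excluded_specials)]
    g = final.groupby("patient_id")
    ledger.patient_expected = pd.DataFrame(
        {
            "n_visits": g.size(),
            "n_inpatient": g["visit_class"].apply(lambda s: int((s == "inpatient").sum())),
            "n_soc": g["visit_class"].apply(lambda s: int((s == "SOC").sum())),
            "n_ed": g["visit_class"].apply(lambda s: int((s == "ED").sum())),
            "n_outpatient": g["visit_class"].apply(lambda s: int((s == "outpatient").sum())),
            "total_los": g["los"].sum(),
            "total_charge_adj": g["charge_adj"].sum(),
            "total_subsidy_adj": g["subsidy_adj"].sum(),
            "pps": g["pps_visit"].max(),
        }
    ).sort_index()

    tables = RecordTables(
        demographic=pd.DataFrame(demo_rows),
        movement=pd.DataFrame(mv_rows),
        billing=pd.DataFrame(bill_rows),
        pharmacy=pd.DataFrame(rx_rows),
        diagnosis=pd.DataFrame(dx_rows),
    )
    return tables, ledger
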