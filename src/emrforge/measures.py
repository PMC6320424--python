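"""Derived per-patient proxy measures.

Two disease-complexity proxies:

* **CCI** — Charlson Comorbidity Index, the weighted sum over 17
  comorbidity categories identified from ICD-9-CM codes (Deyo prefix
  adaptation, original weights 1/2/3/6).  Hierarchy pairs — diabetes with
  vs without complications, mild vs moderate/severe liver disease, any
  malignancy vs metastatic solid tumour — keep only the severe member when
  both are flagged.  Both primary and secondary diagnoses across all of a
  patient's included visits contribute.
* **PPS** — Polypharmacy Score: at visit level the number of distinct
  prescription drugs dispensed (non-prescription items and devices are
  excluded); at patient level the maximum over the patient's visits.

Two socioeconomic proxies built from the billing and address data:

* **housing type** — the patient's latest postal code resolved through a
  public-housing block lookup (a mixed block takes its majority flat type)
  or a private-housing list; unknown postals are non-residential and yield
  a missing value.  Flat types are grouped by size into 5 ordered groups.
* **subsidy** — subsidy status (all visits subsidized / none / mixed) and
  RSR, the relative subsidy received: the percentage of cumulative
  hospital charges paid by government subsidy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = [
    "ComorbidityMap",
    "HousingLookup",
    "load_comorbidity_map",
    "charlson_flags",
    "cci",
    "pps_visit",
    "pps_patient",
    "housing_type",
    "group_housing",
    "subsidy_status",
    "rsr",
    "compute_measures",
    "HOUSING_GROUPS",
]

HOUSING_GROUPS = (
    "rental/studio/1-2-room",
    "3-room",
    "4-room",
    "5-room/executive",
    "private",
)

# flat type (as stored in housing lookups) → size group
_FLAT_GROUPING = {
    "rental": "rental/studio/1-2-room",
    "studio": "rental/studio/1-2-room",
    "1-room": "rental/studio/1-2-room",
    "2-room": "rental/studio/1-2-room",
    "3-room": "3-room",
    "4-room": "4-room",
    "5-room": "5-room/executive",
    "executive": "5-room/executive",
}

# ordering used only to break proportion ties toward the larger flat type
_FLAT_SIZE_ORDER = ["rental", "studio", "1-room", "2-room", "3-room", "4-room",
                    "5-room", "executive"]


@dataclass(frozen=True)
class ComorbidityCategory:
    name: str
    prefixes: tuple[str, ...]
    weight: int
    supersedes: str | None = None


@dataclass(frozen=True)
class ComorbidityMap:
    """Ordered comorbidity categories with code prefixes and weights."""

    categories: tuple[ComorbidityCategory, ...]

    def __post_init__(self) -> None:
        names = {c.name for c in self.categories}
        for c in self.categories:
            if c.weight < 1:
                raise ConfigError(f"category {c.name}: weight must be ≥1")
            if not c.prefixes:
                raise ConfigError(f"category {c.name}: empty prefix set")
            if c.supersedes and c.supersedes not in names:
                raise ConfigError(
                    f"category {c.name} supersedes unknown category {c.supersedes!r}"
                )

    def weight(self, name: str) -> int:
        for c in self.categories:
            if c.name == name:
                return c.weight
        raise KeyError(name)


def load_comorbidity_map(path=None) -> ComorbidityMap:
    """Load a ``category,prefixes,weight,supersedes`` file (the packaged
    Deyo adaptation by default)."""
    if path is None:
        path = resources.files("emrforge.data") / "charlson_deyo.csv"
    df = pd.read_csv(path, dtype=str)
    required = {"category", "prefixes", "weight", "supersedes"}
    if missing := required - set(df.columns):
        raise SchemaError(f"comorbidity map missing columns {sorted(missing)}")
    cats = tuple(
        ComorbidityCategory(
            name=row["category"],
            prefixes=tuple(p for p in row["prefixes"].split(";") if p),
            weight=int(row["weight"]),
            supersedes=row["supersedes"] if pd.notna(row["supersedes"]) else None,
        )
        for _, row in df.iterrows()
    )
    return ComorbidityMap(cats)


def charlson_flags(codes: Iterable[str], cmap: ComorbidityMap) -> dict[str, bool]:
    """Flag each comorbidity category present in a patient's code set,
    then resolve hierarchy pairs (severe member suppresses the milder)."""
    codes = [str(c) for c in codes]
    flags = {
        cat.name: any(c.startswith(p) for c in codes for p in cat.prefixes)
        for cat in cmap.categories
    }
    for cat in cmap.categories:
        if cat.supersedes and flags[cat.name]:
            flags[cat.supersedes] = False
    return flags


def cci(flags: Mapping[str, bool], cmap: ComorbidityMap) -> int:
    """Charlson Comorbidity Index: weighted sum over true flags."""
    return int(sum(cmap.weight(name) for name, on in flags.items() if on))


def pps_visit(pharmacy_rows: pd.DataFrame) -> int:
    """Distinct prescription, non-device drug codes dispensed in one visit."""
    if pharmacy_rows.empty:
        return 0
    keep = pharmacy_rows["is_prescription"].astype(bool) & ~pharmacy_rows[
        "is_device"
    ].astype(bool)
    return int(pharmacy_rows.loc[keep, "drug_code"].nunique())


def pps_patient(visit_pps: Sequence[int]) -> int:
    """Patient polypharmacy score: the maximum visit score (0 if no visits)."""
    visit_pps = list(visit_pps)
    return int(max(visit_pps)) if visit_pps else 0


@dataclass(frozen=True)
class HousingLookup:
    """Postal-code → flat-type composition for public housing, plus the
    private-housing postal list.  The two code sets are disjoint."""

    public_blocks: Mapping[str, Mapping[str, float]]  # postal → {flat type: proportion}
    private_postals: frozenset[str]

    def __post_init__(self) -> None:
        overlap = set(self.public_blocks) & self.private_postals
        if overlap:
            raise ConfigError(
                f"postals in both public and private lists: {sorted(overlap)[:5]}"
            )
        for postal, comp in self.public_blocks.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"flat-type proportions for block {postal} sum to {total}"
                )

    @classmethod
    def from_files(cls, public_path, private_path) -> "HousingLookup":
        df = pd.read_csv(public_path, dtype={"postal": str})
        blocks: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            blocks.setdefault(row["postal"], {})[row["flat_type"]] = float(
                row["proportion"]
            )
        with open(private_path) as fh:
            private = frozenset(line.strip() for line in fh if line.strip())
        return cls(blocks, private)


def housing_type(postal: str | None, lookup: HousingLookup) -> str:
    """Resolve a postal code to a flat type, ``"private"``, or ``"missing"``.

    Mixed blocks take the flat type with the largest proportion; exact ties
    break toward the larger flat type.  Postals on neither list are
    non-residential and yield ``"missing"``.
    """
    if postal is None or (isinstance(postal, float) and pd.isna(postal)):
        return "missing"
    postal = str(postal)
    if postal in lookup.private_postals:
        return "private"
    comp = lookup.public_blocks.get(postal)
    if comp is None:
        return "missing"
    best = max(
        comp.items(), key=lambda kv: (kv[1], _FLAT_SIZE_ORDER.index(kv[0]))
    )
    return best[0]


def group_housing(flat_type: str) -> str:
    """Group flat types by size; private and missing pass through."""
    if flat_type in ("private", "missing"):
        return flat_type
    try:
        return _FLAT_GROUPING[flat_type]
    except KeyError:
        raise ConfigError(f"unknown flat type {flat_type!r}") from None


def subsidy_status(visit_subsidy_flags: Sequence[bool]) -> str:
    """Classify a patient's care as subsidized, nonsubsidized, or mixed."""
    flags = [bool(f) for f in visit_subsidy_flags]
    if not flags:
        raise ValueError("subsidy status needs at least one visit")
    if all(flags):
        return "subsidized"
    if not any(flags):
        return "nonsubsidized"
    return "mixed"


def rsr(total_subsidy: float, total_charges: float) -> float | None:
    """Relative subsidy received: percent of cumulative charges paid by
    subsidy.  Undefined (None) when the patient incurred zero charges."""
    if total_charges <= 0:
        return None
    if not 0 <= total_subsidy <= total_charges:
        raise ValueError(
            f"subsidy {total_subsidy} outside [0, charges={total_charges}]"
        )
    return 100.0 * total_subsidy / total_charges


def compute_measures(
    patients: pd.DataFrame,
    housing_lookup: HousingLookup,
    cmap: ComorbidityMap | None = None,
) -> pd.DataFrame:
    """Attach cci / pps / housing_group / subsidy_status / rsr to a
    patient-level table (as produced by :func:`emrforge.cohort.build_patients`).
    """
    if cmap is None:
        cmap = load_comorbidity_map()
    out = patients.copy()
    out["cci"] = [
        cci(charlson_flags(codes, cmap), cmap) for codes in out["codes"]
    ]
    out["housing_type"] = [
        housing_type(p, housing_lookup) for p in out["postal_code"]
    ]
    out["housing_group"] = [group_housing(t) for t in out["housing_type"]]
    out["subsidy_status"] = [
        "subsidized"
        if n_sub == n
        else ("nonsubsidized" if n_sub == 0 else "mixed")
        for n_sub, n in zip(out["n_visits_subsidized"], out["n_visits"])
    ]
    out["rsr"] = [
        rsr(s, c) for s, c in zip(out["total_subsidy_adj"], out["total_charge_adj"])
    ]
    return out
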