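"""Diagnosis-code standardization and phenotyping.

The hospital's EMR switched nosologies mid-period: visits before a cut-over
date carry ICD-9-CM diagnosis codes, later visits carry ICD-10-AM codes.
To obtain a single longitudinal coding frame, the newer codes are mapped
*backward* onto ICD-9-CM through a crosswalk table, and the resulting
ICD-9-CM pool is then collapsed ("phenotyped") onto a few hundred mutually
exclusive disease categories through a second crosswalk (CCS-style).

A code that misses the crosswalk is not discarded immediately: it first
undergoes *code modification* —

* zero addition: append one, then two, trailing ``"0"`` characters;
* truncation:   drop one trailing character at a time, down to the
  3-character heading.

The first candidate found in the crosswalk wins and the modification route
is recorded.  Codes that remain unmapped after modification are flagged for
exclusion downstream.  :class:`MappingStats` tallies the routes per
diagnosis role (primary vs secondary), on both code instances and unique
codes, mirroring the accounting a mapping-rate audit needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidCodeError, SchemaError, UndefinedRateError

__all__ = [
    "Crosswalk",
    "CodeConversion",
    "MappingStats",
    "ValiditySummary",
    "normalize_code",
    "convert_code",
    "standardize_diagnoses",
    "phenotype_codes",
    "mapping_rate",
    "validity_summary",
    "load_crosswalk",
    "era_rule_from_cutover",
]

MIN_HEADING_LEN = 3  # truncation never goes below the 3-character heading

ROLES = ("primary", "secondary")
METHOD_FAMILIES = ("direct", "zero_added", "truncated", "unmapped")


def normalize_code(raw: str) -> str:
    """Normalize a diagnosis code: strip whitespace, drop periods, upper-case.

    Idempotent.  Raises :class:`InvalidCodeError` on empty/blank input.
    """
    if raw is None:
        raise InvalidCodeError("diagnosis code is missing")
    code = str(raw).strip().replace(".", "").upper()
    if not code:
        raise InvalidCodeError(f"diagnosis code is blank: {raw!r}")
    return code


@dataclass(frozen=True)
class Crosswalk:
    """Source-code → ordered target codes mapping table.

    All keys and targets are stored normalized (dot-free, upper case).
    One-to-many rows keep file order; lookups return the full tuple and the
    caller takes the first target, flagging ambiguity.
    """

    entries: Mapping[str, tuple[str, ...]]
    source_nosology: str = "source"
    target_nosology: str = "target"

    def __post_init__(self) -> None:
        for key, targets in self.entries.items():
            if normalize_code(key) != key:
                raise SchemaError(f"crosswalk key not normalized: {key!r}")
            if not targets:
                raise SchemaError(f"crosswalk key {key!r} has no targets")
            # targets may be codes or category labels: require clean strings
            # (no periods, no surrounding whitespace), not code casing
            for t in targets:
                if not t or t != t.strip() or "." in t:
                    raise SchemaError(f"crosswalk target not normalized: {t!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def get(self, key: str) -> tuple[str, ...] | None:
        return self.entries.get(key)


def load_crosswalk(
    path, source_nosology: str = "source", target_nosology: str = "target"
) -> Crosswalk:
    """Read a delimited crosswalk file with header ``source,target``.

    Multi-target keys may appear as repeated rows (order preserved) or as a
    single row with semicolon-separated targets.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"source", "target"} - set(df.columns)
    if missing:
        raise SchemaError(f"crosswalk file {path} missing columns: {sorted(missing)}")
    entries: dict[str, tuple[str, ...]] = {}
    for src, tgt in zip(df["source"], df["target"]):
        if pd.isna(src) or pd.isna(tgt):
            raise SchemaError(f"crosswalk file {path} has a blank source/target cell")
        targets = [t for t in str(tgt).split(";") if t.strip()]
        entries[src] = entries.get(src, ()) + tuple(targets)
    return Crosswalk(entries, source_nosology, target_nosology)


@dataclass(frozen=True)
class CodeConversion:
    """Outcome of converting one source code through a crosswalk."""

    source: str
    target: str | None
    method: str  # direct | zero_added_1 | zero_added_2 | truncated(k) | unmapped
    ambiguous: bool = False
    diagnosis_role: str | None = None

    @property
    def mapped(self) -> bool:
        return self.target is not None

    @property
    def modified(self) -> bool:
        return self.mapped and self.method != "direct"

    @property
    def method_family(self) -> str:
        if self.method.startswith("zero_added"):
            return "zero_added"
        if self.method.startswith("truncated"):
            return "truncated"
        return self.method


def _candidates(code: str, prefer_truncation: bool) -> list[tuple[str, str]]:
    """Ordered (candidate key, method label) pairs for the fallback search.

    The exact code always comes first.  By default zero addition (which
    preserves more of the source's specificity) precedes truncation; the
    switch flips that precedence.
    """
    zeros = [(code + "0", "zero_added_1"), (code + "00", "zero_added_2")]
    truncs = [
        (code[:n], f"truncated({len(code) - n})")
        for n in range(len(code) - 1, MIN_HEADING_LEN - 1, -1)
    ]
    ordered = truncs + zeros if prefer_truncation else zeros + truncs
    return [(code, "direct")] + ordered


def convert_code(
    code: str,
    xwalk: Crosswalk,
    *,
    prefer_truncation: bool = False,
    diagnosis_role: str | None = None,
) -> CodeConversion:
    """Map one code through the crosswalk with the modification fallback.

    Attempts, in order: direct lookup; ``code+"0"`` then ``code+"00"``;
    truncation one trailing character at a time down to 3 characters.
    First hit wins.  A key with multiple targets yields its first target
    with ``ambiguous=True``.
    """
    norm = normalize_code(code)
    for candidate, method in _candidates(norm, prefer_truncation):
        targets = xwalk.get(candidate)
        if targets is not None:
            return CodeConversion(
                source=norm,
                target=targets[0],
                method=method,
                ambiguous=len(targets) > 1,
                diagnosis_role=diagnosis_role,
            )
    return CodeConversion(
        source=norm, target=None, method="unmapped", diagnosis_role=diagnosis_role
    )


# ---------------------------------------------------------------------------
# mapping statistics


def _zero_bucket() -> dict[str, int]:
    return {m: 0 for m in METHOD_FAMILIES} | {"total": 0, "ambiguous": 0}


@dataclass
class MappingStats:
    """Per-role conversion tallies on code instances and on unique codes.

    Invariant (checked by :meth:`validate`):
    ``direct + zero_added + truncated + unmapped == total`` for every role,
    on both instance and unique counts.
    """

    instances: dict[str, dict[str, int]] = field(
        default_factory=lambda: {r: _zero_bucket() for r in (*ROLES, "combined")}
    )
    unique: dict[str, dict[str, int]] = field(
        default_factory=lambda: {r: _zero_bucket() for r in (*ROLES, "combined")}
    )

    @classmethod
    def from_conversions(cls, conversions: Iterable[CodeConversion]) -> "MappingStats":
        stats = cls()
        seen: dict[str, set[str]] = {r: set() for r in (*ROLES, "combined")}
        for conv in conversions:
            role = conv.diagnosis_role or "secondary"
            if role not in ROLES:
                raise SchemaError(f"unknown diagnosis role: {role!r}")
            fam = conv.method_family
            for level in (role, "combined"):
                bucket = stats.instances[level]
                bucket[fam] += 1
                bucket["total"] += 1
                bucket["ambiguous"] += int(conv.ambiguous)
                if conv.source not in seen[level]:
                    seen[level].add(conv.source)
                    ubucket = stats.unique[level]
                    ubucket[fam] += 1
                    ubucket["total"] += 1
                    ubucket["ambiguous"] += int(conv.ambiguous)
        stats.validate()
        return stats

    def validate(self) -> None:
        for table in (self.instances, self.unique):
            for role, bucket in table.items():
                parts = sum(bucket[m] for m in METHOD_FAMILIES)
                if parts != bucket["total"]:
                    raise SchemaError(
                        f"mapping-stat conservation violated for {role}: "
                        f"{parts} != {bucket['total']}"
                    )

    def percentages(self, level: str = "combined", *, unique: bool = False) -> dict:
        """Per-method percentages on total and on mapped denominators."""
        bucket = (self.unique if unique else self.instances)[level]
        total = bucket["total"]
        mapped = total - bucket["unmapped"]
        out: dict[str, float | None] = {}
        for m in METHOD_FAMILIES:
            out[f"{m}_pct_of_total"] = (
                round(100.0 * bucket[m] / total, 2) if total else None
            )
        for m in ("direct", "zero_added", "truncated"):
            out[f"{m}_pct_of_mapped"] = (
                round(100.0 * bucket[m] / mapped, 2) if mapped else None
            )
        out["mapped_pct_of_total"] = (
            round(100.0 * mapped / total, 2) if total else None
        )
        return out

    def to_dict(self) -> dict:
        """JSON-ready structure: per-role counts and derived percentages."""
        out: dict = {}
        for level in (*ROLES, "combined"):
            out[level] = {
                "instances": dict(self.instances[level]),
                "unique": dict(self.unique[level]),
                "instances_pct": self.percentages(level),
                "unique_pct": self.percentages(level, unique=True),
            }
        return out


# ---------------------------------------------------------------------------
# table-level operations


def era_rule_from_cutover(
    cutover, *, date_col: str = "visit_date", nosology_col: str = "nosology",
    target_label: str = "ICD9",
) -> Callable[[pd.DataFrame], pd.Series]:
    """Predicate: which rows are already coded in the target nosology.

    A per-record nosology column wins when present; otherwise the visit
    date is compared against the coding cut-over date (earlier ⇒ already
    in the old, target nosology).
    """
    cutover = pd.Timestamp(cutover)

    def rule(df: pd.DataFrame) -> pd.Series:
        if nosology_col in df.columns and df[nosology_col].notna().all():
            return df[nosology_col].astype(str).str.upper() == target_label.upper()
        if date_col not in df.columns:
            raise SchemaError(
                f"need {nosology_col!r} or {date_col!r} to decide coding era"
            )
        dates = pd.to_datetime(df[date_col], errors="raise")
        return dates < cutover

    return rule


def standardize_diagnoses(
    diagnoses: pd.DataFrame,
    xwalk: Crosswalk,
    era_rule: Callable[[pd.DataFrame], pd.Series],
    *,
    code_col: str = "code",
    role_col: str = "role",
    prefer_truncation: bool = False,
) -> tuple[pd.DataFrame, MappingStats]:
    """Standardize every diagnosis to the target nosology.

    Rows already in the target nosology (per ``era_rule``) pass through
    untouched and do not enter the conversion statistics.  Others run
    :func:`convert_code`; rows left unmapped are flagged ``excluded``.

    Returns the table with ``code_std`` / ``map_method`` / ``modified`` /
    ``ambiguous`` / ``excluded`` columns and the per-role MappingStats of
    the converted subset.
    """
    if role_col not in diagnoses.columns:
        raise SchemaError(f"diagnosis table lacks role column {role_col!r}")
    if code_col not in diagnoses.columns:
        raise SchemaError(f"diagnosis table lacks code column {code_col!r}")
    out = diagnoses.copy()
    if out.empty:
        out["code_std"] = pd.Series(dtype=object)
        out["map_method"] = pd.Series(dtype=object)
        out["modified"] = pd.Series(dtype=bool)
        out["ambiguous"] = pd.Series(dtype=bool)
        out["excluded"] = pd.Series(dtype=bool)
        return out, MappingStats()

    bad_role = ~out[role_col].isin(ROLES)
    if bad_role.any():
        raise SchemaError(
            f"{int(bad_role.sum())} diagnosis rows have invalid/missing role"
        )

    already = era_rule(out).to_numpy()
    codes = out[code_col].map(normalize_code)

    std = codes.copy().astype(object)
    method = pd.Series("passthrough", index=out.index, dtype=object)
    ambiguous = pd.Series(False, index=out.index)
    conversions: list[CodeConversion] = []

    # memoize per (code, role): conversion is deterministic
    memo: dict[str, CodeConversion] = {}
    for idx in out.index[~already]:
        code = codes.at[idx]
        conv = memo.get(code)
        if conv is None:
            conv = convert_code(code, xwalk, prefer_truncation=prefer_truncation)
            memo[code] = conv
        conversions.append(
            CodeConversion(
                conv.source, conv.target, conv.method, conv.ambiguous,
                diagnosis_role=out.at[idx, role_col],
            )
        )
        std.at[idx] = conv.target
        method.at[idx] = conv.method
        ambiguous.at[idx] = conv.ambiguous

    out["code_std"] = std
    out["map_method"] = method
    out["modified"] = method.str.startswith(("zero_added", "truncated"))
    out["ambiguous"] = ambiguous
    out["excluded"] = method == "unmapped"
    return out, MappingStats.from_conversions(conversions)


def phenotype_codes(
    codes: pd.DataFrame,
    ccs_xwalk: Crosswalk,
    *,
    code_col: str = "code_std",
    role_col: str = "role",
    prefer_truncation: bool = False,
) -> tuple[pd.DataFrame, MappingStats]:
    """Collapse standardized codes onto mutually exclusive disease categories.

    The same modification fallback as :func:`convert_code` runs against the
    category crosswalk; every mapped code receives exactly one category.
    """
    if code_col not in codes.columns:
        raise SchemaError(f"table lacks standardized-code column {code_col!r}")
    out = codes.copy()
    if out.empty:
        out["category"] = pd.Series(dtype=object)
        out["phen_method"] = pd.Series(dtype=object)
        out["excluded"] = pd.Series(dtype=bool)
        return out, MappingStats()

    roles = (
        out[role_col]
        if role_col in out.columns
        else pd.Series("secondary", index=out.index)
    )
    memo: dict[str, CodeConversion] = {}
    conversions: list[CodeConversion] = []
    category = pd.Series(None, index=out.index, dtype=object)
    method = pd.Series("unmapped", index=out.index, dtype=object)
    for idx in out.index:
        code = out.at[idx, code_col]
        if code is None or (isinstance(code, float) and pd.isna(code)):
            continue  # upstream-unmapped rows carry no standardized code
        conv = memo.get(code)
        if conv is None:
            conv = convert_code(code, ccs_xwalk, prefer_truncation=prefer_truncation)
            memo[code] = conv
        conversions.append(
            CodeConversion(
                conv.source, conv.target, conv.method, conv.ambiguous,
                diagnosis_role=roles.at[idx],
            )
        )
        category.at[idx] = conv.target
        method.at[idx] = conv.method
    out["category"] = category
    out["phen_method"] = method
    out["excluded"] = category.isna()
    return out, MappingStats.from_conversions(conversions)


# ---------------------------------------------------------------------------
# rate arithmetic


def mapping_rate(mapped: int, total: int, *, ndigits: int = 1) -> float:
    """Percentage of codes mapped, to the reporting precision (default 0.1)."""
    if total == 0:
        raise UndefinedRateError("mapping rate undefined for total=0")
    if not 0 <= mapped <= total:
        raise ValueError(f"mapped={mapped} outside [0, {total}]")
    return round(100.0 * mapped / total, ndigits)


@dataclass(frozen=True)
class ValiditySummary:
    """Physician-audit arithmetic for modified-code samples."""

    n_sampled: int
    n_valid: int
    n_invalid: int
    validity_rate: float  # 100·valid/sampled
    sampling_fraction: float  # 100·sampled/modified-unique

    def to_dict(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "n_valid": self.n_valid,
            "n_invalid": self.n_invalid,
            "validity_rate": self.validity_rate,
            "sampling_fraction": self.sampling_fraction,
        }


def validity_summary(
    ratings: Sequence[str] | pd.Series, n_modified_unique: int
) -> ValiditySummary:
    """Summarize valid/invalid ratings over a sample of modified codes."""
    ratings = pd.Series(list(ratings), dtype=object)
    if ratings.empty:
        raise ValueError("ratings table is empty")
    bad = ~ratings.isin(["valid", "invalid"])
    if bad.any():
        raise ValueError(f"ratings must be 'valid'/'invalid'; got {ratings[bad].unique()}")
    n_sampled = len(ratings)
    if n_modified_unique < n_sampled:
        raise ValueError("n_modified_unique smaller than the rated sample")
    n_valid = int((ratings == "valid").sum())
    return ValiditySummary(
        n_sampled=n_sampled,
        n_valid=n_valid,
        n_invalid=n_sampled - n_valid,
        validity_rate=round(100.0 * n_valid / n_sampled, 1),
        sampling_fraction=round(100.0 * n_sampled / n_modified_unique, 1),
    )
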