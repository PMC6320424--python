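"""Conversion engine: normalization, fallback search, stats, rate arithmetic."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrforge.codemap import (
    Crosswalk,
    MappingStats,
    convert_code,
    era_rule_from_cutover,
    mapping_rate,
    normalize_code,
    phenotype_codes,
    standardize_diagnoses,
    validity_summary,
)
from emrforge.errors import InvalidCodeError, SchemaError, UndefinedRateError


def brute_force_convert(code: str, keys: dict) -> tuple[str | None, str]:
    """Independent oracle: enumerate the full candidate set in priority
    order (exact, +0, +00, prefixes down to length 3) and take the first
    key-set hit."""
    code = code.strip().replace(".", "").upper()
    candidates = [(code, "direct"), (code + "0", "zero_added_1"),
                  (code + "00", "zero_added_2")]
    for k in range(1, len(code) - 2):
        candidates.append((code[:-k], f"truncated({k})"))
    for cand, method in candidates:
        if cand in keys:
            return keys[cand][0], method
    return None, "unmapped"


@pytest.mark.parametrize(
    "raw,expected",
    [("e11.9", "E119"), ("410.00", "41000"), ("A09", "A09"), ("  i10 ", "I10")],
)
def test_normalize_code(raw, expected):
    assert normalize_code(raw) == expected
    assert normalize_code(normalize_code(raw)) == expected  # idempotent


@pytest.mark.parametrize("raw", ["", "   ", None, "..."])
def test_normalize_rejects_blank(raw):
    with pytest.raises(InvalidCodeError):
        normalize_code(raw)


TOY = Crosswalk(
    {"A09": ("0091",), "C610": ("185",), "K35": ("5409",), "E1100": ("25000",),
     "B99": ("1234", "5678")},
    "ICD10", "ICD9",
)


@pytest.mark.parametrize(
    "code,target,method",
    [
        ("A09", "0091", "direct"),
        ("C61", "185", "zero_added_1"),
        ("E11", "25000", "zero_added_2"),
        ("K3580", "5409", "truncated(2)"),
        ("Z999", None, "unmapped"),
    ],
)
def test_convert_code_fallback_order(code, target, method):
    conv = convert_code(code, TOY)
    assert conv.target == target
    assert conv.method == method


def test_convert_code_ambiguous_key_returns_first_target():
    conv = convert_code("B99", TOY)
    assert conv.target == "1234" and conv.ambiguous


def test_convert_code_rejects_unnormalizable():
    with pytest.raises(InvalidCodeError):
        convert_code("  ", TOY)


def test_truncation_retests_intermediate_lengths():
    # a 4-character key must catch the code before the 3-character heading
    xw = Crosswalk({"K358": ("A",), "K35": ("B",)}, "s", "t")
    conv = convert_code("K3580", xw)
    assert conv.target == "A" and conv.method == "truncated(1)"


def test_prefer_truncation_switch_flips_precedence():
    xw = Crosswalk({"K3580": ("Z",), "K358000": ("Y",), "K35": ("T",)}, "s", "t")
    # default: zero addition first → K358000 via +"00"
    assert convert_code("K35800", xw).method == "zero_added_1"
    assert convert_code("K35800", xw, prefer_truncation=True).method == "truncated(1)"


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    keys=st.dictionaries(
        st.text(alphabet="ABC0123456789", min_size=3, max_size=7),
        st.text(alphabet="0123456789", min_size=3, max_size=5),
        min_size=1, max_size=50,
    ),
    code=st.text(alphabet="ABC0123456789", min_size=3, max_size=7),
)
def test_convert_code_matches_bruteforce_oracle(keys, code):
    """On arbitrary small crosswalks, the engine agrees with candidate
    enumeration under the same priority order."""
    xw = Crosswalk({k: (v,) for k, v in keys.items()}, "s", "t")
    conv = convert_code(code, xw)
    target, method = brute_force_convert(code, {k: (v,) for k, v in keys.items()})
    assert (conv.target, conv.method) == (target, method)


def test_conversion_is_deterministic():
    codes = ["A09", "C61", "E11", "K3580", "Z999", "B99"] * 3
    runs = [
        tuple(convert_code(c, TOY) for c in codes) for _ in range(2)
    ]
    assert runs[0] == runs[1]


# ---------------------------------------------------------------------------
# table-level standardization


def _dx_table():
    rows = []
    # 4 already ICD-9-CM (pre-cutover era)
    for code in ("4019", "25000", "41001", "0091"):
        rows.append({"code": code, "role": "primary", "visit_date": "2007-05-01",
                     "nosology": "ICD9"})
    # 5 directly mappable ICD-10-era
    for code in ("A09", "A09", "C610", "C610", "A09"):
        rows.append({"code": code, "role": "secondary", "visit_date": "2011-05-01",
                     "nosology": "ICD10"})
    # 1 unmappable
    rows.append({"code": "Z999", "role": "secondary", "visit_date": "2011-06-01",
                 "nosology": "ICD10"})
    return pd.DataFrame(rows)


def test_standardize_counts_and_passthrough():
    era = era_rule_from_cutover("2010-01-01")
    out, stats = standardize_diagnoses(_dx_table(), TOY, era)
    usable = out[~out["excluded"]]
    assert len(usable) == 9
    bucket = stats.instances["combined"]
    assert bucket["total"] == 6
    assert bucket["direct"] == 5
    assert bucket["unmapped"] == 1
    # pass-through rows keep their code verbatim and stay out of the stats
    passthrough = out[out["map_method"] == "passthrough"]
    assert list(passthrough["code_std"]) == list(passthrough["code"])
    assert len(passthrough) == 4


def test_standardize_empty_table():
    era = era_rule_from_cutover("2010-01-01")
    out, stats = standardize_diagnoses(
        pd.DataFrame(columns=["code", "role", "visit_date", "nosology"]), TOY, era
    )
    assert out.empty
    assert stats.instances["combined"]["total"] == 0


def test_standardize_requires_role_column():
    with pytest.raises(SchemaError):
        standardize_diagnoses(
            pd.DataFrame({"code": ["A09"]}), TOY, era_rule_from_cutover("2010-01-01")
        )


def test_era_rule_falls_back_to_visit_date():
    era = era_rule_from_cutover("2010-01-01")
    df = pd.DataFrame({"visit_date": ["2009-12-31", "2010-01-01"]})
    assert list(era(df)) == [True, False]


def test_phenotype_examples(fixture_xwalks):
    _, ccs = fixture_xwalks
    df = pd.DataFrame(
        {"code_std": ["4019", "401", "7999"], "role": ["primary"] * 3}
    )
    out, stats = phenotype_codes(df, ccs)
    assert out.loc[0, "category"] == "essential hypertension"
    assert out.loc[0, "phen_method"] == "direct"
    assert out.loc[1, "category"] == "essential hypertension"
    assert out.loc[1, "phen_method"] == "zero_added_1"
    assert bool(out.loc[2, "excluded"])
    assert stats.instances["combined"]["total"] == 3


def test_phenotype_assigns_at_most_one_category(small_run):
    phen = small_run["phenotyped"]
    mapped = phen[~phen["excluded"]]
    # category column is scalar per row, and each distinct code always maps
    # to the same single category
    per_code = mapped.groupby("code_std")["category"].nunique()
    assert (per_code == 1).all()


def test_mapping_stats_conservation(small_run):
    for stats in (small_run["map_stats"], small_run["phen_stats"]):
        stats.validate()  # direct+zero+trunc+unmapped == total, all roles
        for level in ("primary", "secondary", "combined"):
            for pct in stats.percentages(level).values():
                if pct is not None:
                    assert 0.0 <= pct <= 100.0


# ---------------------------------------------------------------------------
# rate arithmetic


@pytest.mark.parametrize(
    "mapped,total,expected",
    [(810459, 930248, 87.1), (4598488, 4722916, 97.4), (0, 5, 0.0)],
)
def test_mapping_rate(mapped, total, expected):
    assert mapping_rate(mapped, total) == expected


def test_mapping_rate_zero_total_errors():
    with pytest.raises(UndefinedRateError):
        mapping_rate(0, 0)


@pytest.mark.parametrize(
    "n_valid,n_sampled,n_modified,rate,frac",
    [(137, 151, 653, 90.7, 23.1), (332, 361, 1747, 92.0, 20.7)],
)
def test_validity_summary(n_valid, n_sampled, n_modified, rate, frac):
    ratings = ["valid"] * n_valid + ["invalid"] * (n_sampled - n_valid)
    vs = validity_summary(ratings, n_modified)
    assert vs.validity_rate == rate
    assert vs.sampling_fraction == frac
    assert vs.n_valid + vs.n_invalid == vs.n_sampled


def test_validity_summary_boundary_and_errors():
    assert validity_summary(["valid"] * 5, 10).validity_rate == 100.0
    with pytest.raises(ValueError):
        validity_summary([], 10)
    with pytest.raises(ValueError):
        validity_summary(["valid"] * 5, 3)
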