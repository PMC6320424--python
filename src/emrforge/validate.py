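"""Statistical validation of the derived proxy measures.

Convergent validity: the two disease-complexity proxies (CCI, PPS) should
correlate with each other.  Criterion validity: both should correlate
positively with health-care utilization (inpatient / specialist-outpatient /
emergency visit counts), and the association should survive adjustment in
log-linked negative binomial count models.  For the socioeconomic proxy,
subsidy status should not be independent of housing type (Pearson
chi-square), the relative subsidy received should differ across housing
groups (Kruskal–Wallis), and both should show the expected gradient in
multinomial-logistic / linear models with private housing and nonsubsidized
care as reference categories.

Spearman confidence intervals use the Fisher z transform.  Because several
correlations are tested jointly, the intervals are Holm-adjusted by
step-down alpha allocation: with the pairs ordered by p-value, the k-th
smallest is built at confidence level 1 − α/(m−k+1) — never narrower than
the unadjusted interval.  Missing values are removed pairwise per analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import AnalysisError

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "IndependenceTest",
    "spearman_holm",
    "count_regression",
    "subsidy_regressions",
    "chisq_independence",
    "kruskal_wallis",
    "run_validation",
]


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    rho: float | None
    ci_low: float | None
    ci_high: float | None
    ci_low_unadjusted: float | None
    ci_high_unadjusted: float | None
    p_value: float | None
    n_pairs: int
    adjusted: bool
    error: str | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class RegressionResult:
    family: str  # neg-binomial | poisson | multinomial | linear
    outcome: str
    term: str
    effect: float | None  # exp(beta) for count/multinomial, beta for linear
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_used: int
    error: str | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class IndependenceTest:
    test: str
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _fisher_ci(rho: float, n: int, level: float) -> tuple[float, float]:
    if abs(rho) >= 1.0:
        return rho, rho
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    crit = sps.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def spearman_holm(
    pairs: list[tuple[str, np.ndarray, np.ndarray]], alpha: float = 0.05
) -> list[CorrelationResult]:
    """Spearman rank correlations with Holm step-down adjusted CIs.

    Each pair is (label, x, y); incomplete observations are dropped
    pairwise.  A constant vector yields a per-pair error result without
    aborting the remaining pairs.
    """
    raw: list[dict] = []
    for label, x, y in pairs:
        x = pd.to_numeric(pd.Series(np.asarray(x, dtype=float)), errors="coerce")
        y = pd.to_numeric(pd.Series(np.asarray(y, dtype=float)), errors="coerce")
        keep = x.notna() & y.notna()
        xv, yv = x[keep].to_numpy(), y[keep].to_numpy()
        n = len(xv)
        if n < 3:
            raw.append({"pair": label, "n": n, "error": "fewer than 3 complete pairs"})
            continue
        if np.all(xv == xv[0]) or np.all(yv == yv[0]):
            raw.append({"pair": label, "n": n, "error": "constant vector"})
            continue
        rho, p = sps.spearmanr(xv, yv)
        raw.append({"pair": label, "n": n, "rho": float(rho), "p": float(p)})

    valid = [r for r in raw if "error" not in r]
    m = len(valid)
    order = sorted(range(m), key=lambda i: valid[i]["p"])
    levels = {}
    for k, i in enumerate(order):  # k-th smallest p (0-based)
        levels[i] = 1.0 - alpha / (m - k)

    results: list[CorrelationResult] = []
    vi = 0
    for r in raw:
        if "error" in r:
            results.append(
                CorrelationResult(
                    pair=r["pair"], rho=None, ci_low=None, ci_high=None,
                    ci_low_unadjusted=None, ci_high_unadjusted=None,
                    p_value=None, n_pairs=r["n"], adjusted=False, error=r["error"],
                )
            )
            continue
        lo_a, hi_a = _fisher_ci(r["rho"], r["n"], levels[vi])
        lo_u, hi_u = _fisher_ci(r["rho"], r["n"], 1.0 - alpha)
        results.append(
            CorrelationResult(
                pair=r["pair"], rho=r["rho"], ci_low=lo_a, ci_high=hi_a,
                ci_low_unadjusted=lo_u, ci_high_unadjusted=hi_u,
                p_value=r["p"], n_pairs=r["n"], adjusted=True,
            )
        )
        vi += 1
    return results


def _complete_cases(*columns: pd.Series) -> pd.DataFrame:
    df = pd.concat(columns, axis=1)
    return df.dropna()


def count_regression(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    outcome_label: str = "count",
    exposure_label: str = "exposure",
) -> list[RegressionResult]:
    """Log-linked negative binomial regression of a utilization count.

    Dispersion is estimated by maximum likelihood (NB2).  If the NB fit
    fails to converge or the dispersion estimate diverges, the model falls
    back to Poisson and says so in the ``family`` field; a degenerate
    outcome yields an explicit fit-failure result, never a silent pass.
    Effects are reported as exp(β) with 95% CIs.
    """
    outcome = pd.Series(outcome).rename("__y")
    exposure = pd.Series(exposure).rename(exposure_label)
    parts = [outcome, exposure]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True) if covariates.index is not outcome.index else covariates)
    data = _complete_cases(*parts)
    n_used = len(data)

    def failure(msg: str) -> list[RegressionResult]:
        return [
            RegressionResult(
                family="neg-binomial", outcome=outcome_label, term=exposure_label,
                effect=None, ci_low=None, ci_high=None, p_value=None,
                n_used=n_used, error=msg,
            )
        ]

    if n_used == 0:
        return failure("no complete cases")
    y = data["__y"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise AnalysisError("count outcome must be non-negative integers")
    if np.all(y == y[0]):
        return failure("degenerate outcome (constant)")

    X = sm.add_constant(
        data.drop(columns="__y").astype(float), has_constant="add"
    )
    family = "neg-binomial"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, X)
            res = model.fit(disp=0, maxiter=200)
            alpha_hat = float(res.params[-1])
            if not res.mle_retvals.get("converged", False) or not np.isfinite(
                alpha_hat
            ):
                res = None
        except Exception:
            res = None
        if res is None:
            family = "poisson"
            try:
                res = sm.Poisson(y, X).fit(disp=0, maxiter=200)
            except Exception as exc:  # pragma: no cover - degenerate designs
                return failure(f"fit failure: {exc}")

    conf = np.asarray(res.conf_int())
    out = []
    for i, term in enumerate(X.columns):
        if term == "const":
            continue
        out.append(
            RegressionResult(
                family=family, outcome=outcome_label, term=term,
                effect=float(np.exp(res.params.iloc[i])),
                ci_low=float(np.exp(conf[i, 0])),
                ci_high=float(np.exp(conf[i, 1])),
                p_value=float(res.pvalues.iloc[i]),
                n_used=n_used,
            )
        )
    return out


def subsidy_regressions(
    status: pd.Series,
    rsr: pd.Series,
    housing_group: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    status_reference: str = "nonsubsidized",
    housing_reference: str = "private",
) -> list[RegressionResult]:
    """Multinomial-logistic model of subsidy status and linear model of RSR
    on housing group (reference: private housing; status reference:
    nonsubsidized), optionally adjusted for covariates such as nationality.

    Odds ratios are reported per housing group for the subsidized-vs-
    reference and mixed-vs-reference contrasts; RSR effects are additive β.
    An empty status×housing cell is reported as a warning; categories are
    never collapsed automatically.
    """
    status = pd.Series(status).astype(object)
    housing = pd.Series(housing_group).astype(object)
    tab = pd.crosstab(housing, status)
    if (tab == 0).any().any():
        empty = [
            (str(r), str(c))
            for r in tab.index for c in tab.columns if tab.loc[r, c] == 0
        ]
        warnings.warn(
            f"empty status×housing cells (not collapsed): {empty}", stacklevel=2
        )

    status_levels = [status_reference] + sorted(
        set(status.dropna()) - {status_reference}
    )
    housing_levels = [housing_reference] + sorted(
        set(housing.dropna()) - {housing_reference}
    )
    dummies = pd.get_dummies(
        pd.Categorical(housing, categories=housing_levels), drop_first=True
    ).astype(float)
    dummies.index = housing.index
    parts = [dummies]
    if covariates is not None:
        parts.append(covariates)
    Xfull = pd.concat(parts, axis=1)

    results: list[RegressionResult] = []

    # multinomial logistic for subsidy status
    y = pd.Categorical(status, categories=status_levels)
    keep = pd.Series(~pd.isna(y.codes) & (y.codes >= 0), index=status.index)
    keep &= Xfull.notna().all(axis=1)
    ycodes = pd.Series(y.codes, index=status.index)[keep]
    X = sm.add_constant(Xfull[keep].astype(float), has_constant="add")
    n_used = int(keep.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MNLogit(ycodes.to_numpy(), X).fit(disp=0, maxiter=200)
        except Exception as exc:
            fit = None
            results.append(
                RegressionResult(
                    family="multinomial", outcome="subsidy_status", term="(model)",
                    effect=None, ci_low=None, ci_high=None, p_value=None,
                    n_used=n_used, error=f"fit failure: {exc}",
                )
            )
    if fit is not None:
        # CI rows are ordered (equation, term); reshape for positional access
        conf = np.asarray(fit.conf_int()).reshape(
            len(status_levels) - 1, len(X.columns), 2
        )
        params = fit.params  # columns are equations 1..K-1
        for j, level in enumerate(status_levels[1:]):
            for t_idx, term in enumerate(X.columns):
                if term == "const":
                    continue
                beta = float(params.loc[term, j])
                lo, hi = conf[j, t_idx]
                results.append(
                    RegressionResult(
                        family="multinomial",
                        outcome=f"{level}_vs_{status_reference}",
                        term=str(term),
                        effect=float(np.exp(beta)),
                        ci_low=float(np.exp(lo)),
                        ci_high=float(np.exp(hi)),
                        p_value=float(fit.pvalues.loc[term, j]),
                        n_used=n_used,
                    )
                )

    # linear model for RSR
    rsr = pd.to_numeric(pd.Series(rsr), errors="coerce")
    keep = rsr.notna() & Xfull.notna().all(axis=1)
    Xl = sm.add_constant(Xfull[keep].astype(float), has_constant="add")
    ols = sm.OLS(rsr[keep].to_numpy(), Xl).fit()
    conf = ols.conf_int()
    for term in Xl.columns:
        if term == "const":
            continue
        results.append(
            RegressionResult(
                family="linear", outcome="rsr", term=str(term),
                effect=float(ols.params[term]),
                ci_low=float(conf.loc[term, 0]),
                ci_high=float(conf.loc[term, 1]),
                p_value=float(ols.pvalues[term]),
                n_used=int(keep.sum()),
            )
        )
    return results


def chisq_independence(table: np.ndarray | pd.DataFrame) -> IndependenceTest:
    """Pearson chi-square test of independence on an r×c contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise AnalysisError("contingency table must be 2-dimensional and non-empty")
    if (arr < 0).any():
        raise AnalysisError("contingency table has negative cells")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise AnalysisError(f"empty row(s) at index {np.where(row_sums == 0)[0].tolist()}")
    if (col_sums == 0).any():
        raise AnalysisError(
            f"empty column(s) at index {np.where(col_sums == 0)[0].tolist()}"
        )
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return IndependenceTest(
        test="pearson_chi2", statistic=float(stat), df=int(df), p_value=float(p)
    )


def kruskal_wallis(groups: list[np.ndarray]) -> IndependenceTest:
    """Kruskal–Wallis rank-sum test with average ranks and tie correction."""
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise AnalysisError(f"group {i} is empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # no separation at all: statistic is 0 by convention
        return IndependenceTest(test="kruskal_wallis", statistic=0.0, df=df, p_value=1.0)
    stat, p = sps.kruskal(*arrays)
    return IndependenceTest(
        test="kruskal_wallis", statistic=float(stat), df=df, p_value=float(p)
    )


# ---------------------------------------------------------------------------
# report assembly


def run_validation(measures: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full validity analysis on a patient-level measures table.

    Expects the columns produced by the cohort + measures stages:
    cci, pps, n_inpatient, n_soc, n_ed, sex, race, age_at_study_end,
    observed_years, housing_group, subsidy_status, rsr, singaporean.
    Returns a JSON-ready report.
    """
    report: dict = {}

    pairs = [
        ("cci_vs_pps", measures["cci"], measures["pps"]),
        ("cci_vs_inpatient", measures["cci"], measures["n_inpatient"]),
        ("cci_vs_soc", measures["cci"], measures["n_soc"]),
        ("cci_vs_ed", measures["cci"], measures["n_ed"]),
        ("pps_vs_inpatient", measures["pps"], measures["n_inpatient"]),
        ("pps_vs_soc", measures["pps"], measures["n_soc"]),
        ("pps_vs_ed", measures["pps"], measures["n_ed"]),
    ]
    report["correlations"] = [
        r.to_dict() for r in spearman_holm(pairs, alpha=alpha)
    ]

    covs = pd.DataFrame(index=measures.index)
    covs["male"] = (measures["sex"] == "M").astype(float)
    for race in sorted(set(measures["race"].dropna()))[1:]:
        covs[f"race_{race}"] = (measures["race"] == race).astype(float)
    covs["age"] = pd.to_numeric(measures["age_at_study_end"], errors="coerce")
    covs["observed_years"] = pd.to_numeric(
        measures["observed_years"], errors="coerce"
    )

    count_results = []
    for outcome in ("n_inpatient", "n_soc", "n_ed"):
        for exposure in ("cci", "pps"):
            count_results.extend(
                count_regression(
                    measures[outcome], measures[exposure], covs,
                    outcome_label=outcome, exposure_label=exposure,
                )
            )
    report["count_models"] = [r.to_dict() for r in count_results]

    ses_covs = pd.DataFrame(index=measures.index)
    ses_covs["singaporean"] = measures["singaporean"].astype(float)
    report["subsidy_models"] = [
        r.to_dict()
        for r in subsidy_regressions(
            measures["subsidy_status"], measures["rsr"],
            measures["housing_group"], ses_covs,
        )
    ]

    resolved = measures[measures["housing_group"] != "missing"]
    tab = pd.crosstab(resolved["housing_group"], resolved["subsidy_status"])
    report["housing_subsidy_chi2"] = chisq_independence(tab).to_dict()

    groups = [
        g["rsr"].dropna().to_numpy()
        for _, g in resolved.groupby("housing_group")
        if g["rsr"].notna().any()
    ]
    report["rsr_kruskal_wallis"] = kruskal_wallis(groups).to_dict()
    return report
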