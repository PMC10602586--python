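"""Logistic-regression association analyses and the descriptive table.

Each outcome is compared between APOL1 high- and low-risk genotype
groups by maximum-likelihood logistic regression (statsmodels, IRLS)
with adjustment for age at admission, sex, and the first three ancestry
principal components.  Three renal-disease strategies probe mediation:
additional adjustment for pre-existing severe renal disease, exclusion
of patients with severe renal disease, and restriction to them.
Odds ratios, 95% confidence intervals and p-values are all Wald-based,
so the printed OR/CI/p triples are mutually consistent.

The descriptive table reports n (%) by risk group with Yates
continuity-corrected chi-square tests for 2x2 comparisons, and median
(Q1–Q3) with a two-sample t-test for continuous characteristics.
p-values display with two decimals above 0.001 and in scientific
notation below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .codes import CHARLSON_CATEGORIES, INFECTION_TYPES
from .config import CRITERIA
from .errors import ValidationError

#: Outcome grid: primary, code-only shock arm, five criteria, mortality.
OUTCOMES = ("sepsis", "shock_code", *CRITERIA, "mortality")

#: Renal-disease strategies.
STRATEGIES = ("base", "adjusted", "exclude_severe_renal", "only_severe_renal")

DEFAULT_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3")

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ModelSpec:
    """One outcome/strategy logistic model."""

    outcome: str
    covariates: tuple = DEFAULT_COVARIATES
    adjust_severe_renal: bool = False
    subset: str = "all"          # all | exclude_severe_renal | only_severe_renal
    denominator: str = "cohort"  # cohort | sepsis_cases

    def validate(self) -> "ModelSpec":
        if self.subset not in ("all", "exclude_severe_renal", "only_severe_renal"):
            raise ValidationError(f"unknown subset {self.subset!r}")
        if self.subset != "all" and self.adjust_severe_renal:
            raise ValidationError(
                "subsetting on severe renal disease and adjusting for it "
                "are alternative strategies, not combined")
        if self.denominator not in ("cohort", "sepsis_cases"):
            raise ValidationError(f"unknown denominator {self.denominator!r}")
        return self


@dataclass
class AssociationResult:
    """Odds ratio with Wald CI and p for one fitted model."""

    outcome: str
    strategy: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_total: int
    n_cases: int
    n_missing: int
    converged: bool
    note: str = ""
    spec: ModelSpec | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "strategy": self.strategy,
            "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p,
            "p_display": format_p(self.p) if np.isfinite(self.p) else "",
            "n_total": self.n_total, "n_cases": self.n_cases,
            "n_missing": self.n_missing, "converged": self.converged,
            "note": self.note,
        }


def format_p(p: float) -> str:
    """Two decimals at or above 0.001, scientific notation below."""
    if p >= 0.001:
        return f"{p:.2f}"
    return f"{p:.2E}"


def _sex_indicator(series: pd.Series) -> pd.Series:
    if series.dtype == object or pd.api.types.is_string_dtype(series):
        return series.astype(str).str.upper().map({"M": 1.0, "F": 0.0})
    return series.astype(float)


def fit_logistic(rows: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one logistic model; exposure is the high-risk genotype.

    Complete-case analysis; separation or non-convergence yields a
    flagged result with diagnostics rather than silent numbers.
    """
    spec.validate()
    df = rows
    if spec.subset == "exclude_severe_renal":
        df = df[~df["severe_renal"].astype(bool)]
    elif spec.subset == "only_severe_renal":
        df = df[df["severe_renal"].astype(bool)]
    if spec.denominator == "sepsis_cases":
        df = df[df["sepsis"].astype(bool)]
    if df.empty:
        raise ValidationError(
            f"empty subset for outcome {spec.outcome!r} / {spec.subset!r}")

    X = pd.DataFrame({"exposure": df["high_risk"].astype(float)})
    for c in spec.covariates:
        X[c] = _sex_indicator(df[c]) if c == "sex" else df[c].astype(float)
    if spec.adjust_severe_renal:
        X["severe_renal"] = df["severe_renal"].astype(float)
    y = df[spec.outcome].astype(float)

    complete = X.notna().all(axis=1) & y.notna()
    n_missing = int((~complete).sum())
    X, y = X[complete], y[complete]
    n_total = len(y)
    n_cases = int(y.sum())
    strategy = _strategy_name(spec)
    if n_cases == 0 or n_cases == n_total:
        raise ValidationError(
            f"outcome {spec.outcome!r} has no cases or no non-cases "
            f"after subsetting ({n_cases}/{n_total})")

    X = sm.add_constant(X, has_constant="add")
    note = ""
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        beta = float(res.params["exposure"])
        se = float(res.bse["exposure"])
        if not converged:
            note = "IRLS did not converge"
        elif abs(beta) > 15 or se > 50:
            converged = False
            note = "possible separation: extreme exposure coefficient"
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        return AssociationResult(
            outcome=spec.outcome, strategy=strategy,
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
            n_total=n_total, n_cases=n_cases, n_missing=n_missing,
            converged=False, note=f"fit failed: {type(exc).__name__}: {exc}",
            spec=spec)

    with np.errstate(over="ignore"):  # flagged separation fits can overflow
        return AssociationResult(
            outcome=spec.outcome, strategy=strategy,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z95 * se)),
            ci_high=float(np.exp(beta + _Z95 * se)),
            p=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
            n_total=n_total, n_cases=n_cases, n_missing=n_missing,
            converged=converged, note=note, spec=spec)


def _strategy_name(spec: ModelSpec) -> str:
    if spec.adjust_severe_renal:
        return "adjusted"
    if spec.subset != "all":
        return spec.subset
    return "base"


def spec_for(outcome: str, strategy: str, **kw) -> ModelSpec:
    if strategy == "base":
        return ModelSpec(outcome=outcome, **kw)
    if strategy == "adjusted":
        return ModelSpec(outcome=outcome, adjust_severe_renal=True, **kw)
    return ModelSpec(outcome=outcome, subset=strategy, **kw)


def run_analysis_suite(rows: pd.DataFrame) -> pd.DataFrame:
    """The full outcome x strategy grid as a tidy table (8 x 4 rows).

    Cells whose model cannot be estimated (no cases after subsetting)
    are emitted with NaN estimates and an explanatory note rather than
    dropped, so the grid shape is always complete.
    """
    out = []
    for outcome in OUTCOMES:
        for strategy in STRATEGIES:
            spec = spec_for(outcome, strategy)
            try:
                res = fit_logistic(rows, spec)
            except ValidationError as exc:
                res = AssociationResult(
                    outcome=outcome, strategy=strategy, odds_ratio=np.nan,
                    ci_low=np.nan, ci_high=np.nan, p=np.nan, n_total=0,
                    n_cases=0, n_missing=0, converged=False, note=str(exc))
            out.append(res.to_dict())
    return pd.DataFrame(out)


# -- descriptive table ------------------------------------------------------

def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected chi-square statistic and p for a 2x2 table."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=True)
    return float(stat), float(p)


def _binary_row(label, x: pd.Series, high: pd.Series):
    x = x.astype(bool)
    n_hi, n_lo = int(high.sum()), int((~high).sum())
    a = int((x & high).sum())
    c = int((x & ~high).sum())
    table = [[a, n_hi - a], [c, n_lo - c]]
    note = ""
    if min(a + c, (n_hi - a) + (n_lo - c)) == 0 or min(n_hi, n_lo) == 0:
        stat, p = np.nan, np.nan
        note = "degenerate margin; test skipped"
    else:
        stat, p = yates_chi2(table)
    total = a + c
    n = n_hi + n_lo
    return {
        "characteristic": label, "kind": "categorical",
        "total": f"{total} ({100 * total / n:.1f})",
        "low_risk": f"{c} ({100 * c / n_lo:.1f})" if n_lo else "",
        "high_risk": f"{a} ({100 * a / n_hi:.1f})" if n_hi else "",
        "statistic": stat, "p": p,
        "p_display": format_p(p) if np.isfinite(p) else "",
        "note": note,
    }


def _continuous_row(label, x: pd.Series, high: pd.Series):
    def disp(v):
        return (f"{v.median():.0f} ({v.quantile(0.25):.0f}-"
                f"{v.quantile(0.75):.0f})")

    hi, lo = x[high], x[~high]
    stat, p = stats.ttest_ind(hi, lo, equal_var=True)
    return {
        "characteristic": label, "kind": "continuous",
        "total": disp(x), "low_risk": disp(lo), "high_risk": disp(hi),
        "statistic": float(stat), "p": float(p), "p_display": format_p(float(p)),
        "note": "median (Q1-Q3) displayed; two-sample t-test",
    }


def table_one(rows: pd.DataFrame) -> pd.DataFrame:
    """Descriptive characteristics by risk group, with tests.

    Categorical characteristics use Yates-corrected chi-square; age
    displays as median (Q1–Q3) with a t-test p.  Only columns present
    in ``rows`` are reported.
    """
    high = rows["high_risk"].astype(bool)
    out = []
    if "sex" in rows:
        female = _sex_indicator(rows["sex"]) == 0
        out.append(_binary_row("female", female, high))
    if "age" in rows:
        out.append(_continuous_row("age_at_admission", rows["age"].astype(float), high))
    for c in CHARLSON_CATEGORIES:
        col = f"cm_{c}"
        if col in rows:
            out.append(_binary_row(c, rows[col], high))
    if "severe_renal" in rows:
        out.append(_binary_row("severe_renal_disease", rows["severe_renal"], high))
    for t in INFECTION_TYPES:
        col = f"inf_{t}"
        if col in rows:
            out.append(_binary_row(f"infection_{t}", rows[col], high))
    return pd.DataFrame(out)
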