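"""Logistic fits, closed-form checks and the descriptive table."""

import numpy as np
import pandas as pd
import pytest

from apol1sepsis.association import (ModelSpec, fit_logistic, format_p,
                                     run_analysis_suite, table_one,
                                     yates_chi2)
from apol1sepsis.config import SimulationConfig
from apol1sepsis.errors import ValidationError
from apol1sepsis.simulate import generate_cohort_rows


def _two_by_two(a, b, c, d):
    """Cohort rows realizing a 2x2 table: (exposed case, exposed
    non-case, unexposed case, unexposed non-case)."""
    rows = ([(True, True)] * a + [(True, False)] * b
            + [(False, True)] * c + [(False, False)] * d)
    df = pd.DataFrame(rows, columns=["high_risk", "sepsis"])
    df["severe_renal"] = False
    return df


def textbook_yates(a, b, c, d):
    """Continuity-corrected chi-square from the classic formula."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


@pytest.mark.parametrize("cells", [(20, 30, 10, 40), (5, 7, 11, 13),
                                   (100, 900, 60, 940)])
def test_unadjusted_fit_recovers_cross_product_ratio(cells):
    """A covariate-free logistic fit on a 2x2 equals ad/bc, and the
    Wald CI matches log-OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)."""
    a, b, c, d = cells
    res = fit_logistic(_two_by_two(a, b, c, d),
                       ModelSpec(outcome="sepsis", covariates=()))
    expected = (a * d) / (b * c)
    assert res.odds_ratio == pytest.approx(expected, abs=1e-6 * expected)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(expected) - 1.959963984540054 * se)
    hi = np.exp(np.log(expected) + 1.959963984540054 * se)
    assert res.ci_low == pytest.approx(lo, rel=1e-4)
    assert res.ci_high == pytest.approx(hi, rel=1e-4)
    assert res.ci_low <= res.odds_ratio <= res.ci_high


def test_separation_is_flagged_not_silent():
    df = _two_by_two(30, 0, 0, 30)  # outcome == exposure exactly
    res = fit_logistic(df, ModelSpec(outcome="sepsis", covariates=()))
    assert not res.converged
    assert res.note


def test_empty_or_degenerate_subsets_raise():
    df = _two_by_two(5, 5, 5, 5)
    with pytest.raises(ValidationError):
        fit_logistic(df, ModelSpec(outcome="sepsis", covariates=(),
                                   subset="only_severe_renal"))
    allcase = df[df["sepsis"]]
    with pytest.raises(ValidationError):
        fit_logistic(allcase, ModelSpec(outcome="sepsis", covariates=()))


def test_subset_and_adjustment_cannot_combine():
    with pytest.raises(ValidationError):
        ModelSpec(outcome="sepsis", adjust_severe_renal=True,
                  subset="exclude_severe_renal").validate()


def test_attenuation_ordering_and_subset_consistency():
    """On the renal-mediated generator the base OR exceeds the
    renal-adjusted OR, which sits near 1; subset sizes partition n."""
    rows = generate_cohort_rows(SimulationConfig(n_patients=30_000, seed=3))
    base = fit_logistic(rows, ModelSpec(outcome="sepsis"))
    adj = fit_logistic(rows, ModelSpec(outcome="sepsis",
                                       adjust_severe_renal=True))
    excl = fit_logistic(rows, ModelSpec(outcome="sepsis",
                                        subset="exclude_severe_renal"))
    only = fit_logistic(rows, ModelSpec(outcome="sepsis",
                                        subset="only_severe_renal"))
    assert base.odds_ratio > adj.odds_ratio
    assert adj.ci_low < 1.0 < adj.ci_high
    assert excl.n_total + only.n_total == base.n_total


def test_analysis_suite_grid_is_complete(cohort_small):
    cohort, _ = cohort_small
    res = run_analysis_suite(cohort)
    assert len(res) == 32  # 8 outcomes x 4 strategies
    assert res[["outcome", "strategy"]].drop_duplicates().shape[0] == 32
    ok = res[res["converged"]]
    assert (ok["ci_low"] <= ok["odds_ratio"]).all()
    assert (ok["odds_ratio"] <= ok["ci_high"]).all()


def test_sepsis_case_denominator_option(cohort_small):
    cohort, _ = cohort_small
    res = fit_logistic(cohort, ModelSpec(outcome="renal",
                                         denominator="sepsis_cases"))
    assert res.n_total == int(cohort["sepsis"].sum())


def test_wald_p_and_ci_are_mutually_consistent():
    rows = generate_cohort_rows(SimulationConfig(n_patients=5_000, seed=8))
    res = fit_logistic(rows, ModelSpec(outcome="sepsis"))
    # CI excludes 1 exactly when p < 0.05, both from the same Wald statistic
    excludes_one = not (res.ci_low <= 1.0 <= res.ci_high)
    assert excludes_one == (res.p < 0.05)


# -- descriptive table ------------------------------------------------------

def test_renal_comorbidity_row_matches_textbook_chi_square():
    """Observed renal-comorbidity split 136/361 vs 409/1881 gives the
    continuity-corrected chi-square ~40.9 with p on the order 1.6e-10."""
    table = [[136, 225], [409, 1472]]
    stat, p = yates_chi2(table)
    assert stat == pytest.approx(textbook_yates(136, 225, 409, 1472),
                                 abs=1e-9)
    assert stat == pytest.approx(40.9, abs=0.05)
    assert 1e-11 < p < 1e-9


def test_identical_proportions_give_p_of_one():
    df = pd.DataFrame({
        "high_risk": [True] * 1000 + [False] * 1000,
        "cm_renal_disease": ([True] * 250 + [False] * 750) * 2,
    })
    row = table_one(df).iloc[0]
    assert row["p"] > 0.99
    assert row["p_display"] == "1.00"


def test_gender_row_rounds_to_one():
    """Female/male split 210/151 vs 1096/785 is as balanced as the
    cohort's, so the corrected p rounds to 1.00."""
    sex = (["F"] * 210 + ["M"] * 151 + ["F"] * 1096 + ["M"] * 785)
    df = pd.DataFrame({
        "high_risk": [True] * 361 + [False] * 1881,
        "sex": sex,
    })
    row = table_one(df)
    row = row[row["characteristic"] == "female"].iloc[0]
    assert row["p_display"] == "1.00"


def test_degenerate_margin_skips_test_with_note():
    df = pd.DataFrame({"high_risk": [True, False], "cm_dementia": [False, False]})
    row = table_one(df).iloc[0]
    assert np.isnan(row["p"]) and "degenerate" in row["note"]


def test_age_row_uses_median_display_and_t_test(cohort_small):
    cohort, _ = cohort_small
    t1 = table_one(cohort)
    age = t1[t1["characteristic"] == "age_at_admission"].iloc[0]
    assert "(" in age["total"] and "-" in age["total"]  # median (Q1-Q3)
    assert 0 <= age["p"] <= 1


@pytest.mark.parametrize("p,display", [
    (0.9999, "1.00"), (0.047, "0.05"), (0.001, "0.00"),
    (1.6e-10, "1.60E-10"), (0.0009, "9.00E-04"),
])
def test_p_value_display_convention(p, display):
    assert format_p(p) == display
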