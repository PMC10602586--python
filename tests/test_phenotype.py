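"""Sepsis-3 criteria, baselines, unit handling and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from apol1sepsis.phenotype import (Thresholds, call_sepsis, compute_baseline,
                                   normalize_labs, phenotype_admissions,
                                   short_term_mortality)
from apol1sepsis.errors import ValidationError
from helpers import (events_frame, labs_frame, naive_phenotype, patient,
                     patients_frame)

EMPTY_EVENTS = events_frame([])


def _call(labs, events, default_codes, start=0, discharge=5, **thr):
    return call_sepsis(0, start, discharge, normalize_labs(labs), events,
                       default_codes, Thresholds(**thr))


# -- baselines --------------------------------------------------------------

def test_baseline_is_lowest_creatinine_over_lookback_through_discharge():
    labs = normalize_labs(labs_frame([(0, -30, "creatinine", 1.0),
                                      (0, 0, "creatinine", 2.2)]))
    assert compute_baseline(labs, "creatinine", 0, 5) == 1.0


def test_baseline_may_equal_the_index_value():
    labs = normalize_labs(labs_frame([(0, 0, "creatinine", 2.0)]))
    assert compute_baseline(labs, "creatinine", 0, 5) == 2.0


def test_platelet_baseline_is_highest():
    labs = normalize_labs(labs_frame([(0, -100, "platelets", 250_000),
                                      (0, 0, "platelets", 80_000)]))
    assert compute_baseline(labs, "platelets", 0, 5) == 250_000


def test_baseline_ignores_values_outside_window():
    labs = normalize_labs(labs_frame([(0, -400, "creatinine", 0.5),
                                      (0, 0, "creatinine", 2.0)]))
    assert compute_baseline(labs, "creatinine", 0, 5) == 2.0


# -- lab criteria -----------------------------------------------------------

@pytest.mark.parametrize("baseline,win,expected", [
    (1.0, 2.0, True),    # doubling is inclusive
    (1.0, 1.99, False),
])
def test_renal_criterion_doubling(default_codes, baseline, win, expected):
    labs = labs_frame([(0, -30, "creatinine", baseline),
                       (0, 0, "creatinine", win)])
    assert _call(labs, EMPTY_EVENTS, default_codes).criteria["renal"] is expected


def test_renal_criterion_false_without_window_value(default_codes):
    labs = labs_frame([(0, -30, "creatinine", 1.0)])
    call = _call(labs, EMPTY_EVENTS, default_codes)
    assert not call.criteria["renal"]


def test_renal_criterion_not_evaluable_without_baseline(default_codes):
    call = _call(labs_frame([(0, 0, "bilirubin_total", 1.0)]), EMPTY_EVENTS,
                 default_codes)
    assert not call.criteria["renal"]
    assert "renal" in call.not_evaluable


@pytest.mark.parametrize("baseline,win,expected", [
    (0.8, 2.1, True),    # >= 2 mg/dL and >= 2x baseline
    (1.5, 2.5, False),   # above 2 mg/dL but not doubled
    (0.5, 1.9, False),   # doubled but below the absolute threshold
])
def test_hepatic_criterion(default_codes, baseline, win, expected):
    labs = labs_frame([(0, -30, "bilirubin_total", baseline),
                       (0, 0, "bilirubin_total", win)])
    assert _call(labs, EMPTY_EVENTS, default_codes).criteria["hepatic"] is expected


@pytest.mark.parametrize("baseline,win,expected", [
    (220_000, 90_000, True),
    (90_000, 40_000, False),    # baseline below 100k never qualifies
    (150_000, 99_000, False),   # decline only 34%
])
def test_hematologic_criterion(default_codes, baseline, win, expected):
    labs = labs_frame([(0, -30, "platelets", baseline),
                       (0, 0, "platelets", win)])
    got = _call(labs, EMPTY_EVENTS, default_codes).criteria["hematologic"]
    assert got is expected


def test_unit_invariance_micromolar_vs_mg_dl(default_codes):
    """Correctly tagged µmol/L inputs yield the same calls as mg/dL."""
    mg = labs_frame([(0, -30, "bilirubin_total", 0.8),
                     (0, 0, "bilirubin_total", 2.1),
                     (0, -30, "creatinine", 1.0),
                     (0, 0, "creatinine", 2.0)])
    umol = labs_frame([(0, -30, "bilirubin_total", 0.8 * 17.1, "umol/L"),
                       (0, 0, "bilirubin_total", 2.1 * 17.1, "umol/L"),
                       (0, -30, "creatinine", 1.0 * 88.4, "umol/L"),
                       (0, 0, "creatinine", 2.0 * 88.4, "umol/L")])
    a = _call(mg, EMPTY_EVENTS, default_codes)
    b = _call(umol, EMPTY_EVENTS, default_codes)
    assert a.criteria == b.criteria and a.sepsis == b.sepsis


def test_unknown_units_rejected_and_nonpositive_dropped():
    with pytest.raises(ValidationError):
        normalize_labs(labs_frame([(0, 0, "creatinine", 1.0, "furlongs")]))
    out = normalize_labs(labs_frame([(0, 0, "creatinine", -1.0),
                                     (0, 0, "creatinine", 1.0)]))
    assert len(out) == 1


# -- event criteria ---------------------------------------------------------

def test_respiratory_requires_ventilation_and_icu(default_codes):
    vent_icu = events_frame([(0, 0, "CPT", "94002"), (0, 1, "CPT", "99291")])
    vent_only = events_frame([(0, 0, "CPT", "94002")])
    icu_only = events_frame([(0, 0, "CPT", "99291")])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    assert _call(labs, vent_icu, default_codes).criteria["respiratory"]
    assert not _call(labs, vent_only, default_codes).criteria["respiratory"]
    assert not _call(labs, icu_only, default_codes).criteria["respiratory"]


def test_circulatory_norepinephrine_branch(default_codes):
    events = events_frame([(0, 0, "MED", "norepinephrine")])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    assert _call(labs, events, default_codes).criteria["circulatory"]


def test_circulatory_inotrope_vetoed_by_stress_echo(default_codes):
    events = events_frame([(0, 0, "MED", "dopamine"), (0, 0, "CPT", "93015"),
                           (0, 0, "KEYWORD", "sepsis", 2.0)])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    assert not _call(labs, events, default_codes).criteria["circulatory"]


def test_circulatory_inotrope_needs_two_keyword_mentions(default_codes):
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    # mentions sum across keywords: 1 + 1 qualifies
    events = events_frame([(0, 0, "MED", "dobutamine"),
                           (0, 0, "KEYWORD", "sepsis", 1.0),
                           (0, 1, "KEYWORD", "infection", 1.0)])
    assert _call(labs, events, default_codes).criteria["circulatory"]
    one = events_frame([(0, 0, "MED", "dobutamine"),
                        (0, 0, "KEYWORD", "sepsis", 1.0)])
    assert not _call(labs, one, default_codes).criteria["circulatory"]


def test_keyword_rule_switch_extends_to_norepinephrine(default_codes):
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    events = events_frame([(0, 0, "MED", "norepinephrine")])
    strict = _call(labs, events, default_codes,
                   keyword_rule_on_norepinephrine=True)
    assert not strict.criteria["circulatory"]


@pytest.mark.parametrize("code,system,day,expected", [
    ("R65.21", "ICD10CM", 1, True),
    ("R65.20", "ICD10CM", 0, True),
    ("995.92", "ICD9CM", 0, True),
    ("785.52", "ICD9CM", -1, True),
    ("R65.10", "ICD10CM", 0, False),   # SIRS, not shock
    ("995.92", "ICD9CM", -2, False),   # outside the window
])
def test_shock_code_flag(default_codes, code, system, day, expected):
    events = events_frame([(0, day, system, code)])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    call = _call(labs, events, default_codes)
    assert call.via_shock_code is expected
    assert call.sepsis is expected


def test_short_term_mortality_rules():
    dead = patients_frame([patient(pid=0, death=5, discharge=5)]).iloc[0]
    hospice = patients_frame([patient(pid=0, disposition="hospice")]).iloc[0]
    late = patients_frame([patient(pid=0, death=35, discharge=5)]).iloc[0]
    assert short_term_mortality(dead, 0, 5)
    assert short_term_mortality(hospice, 0, 5)
    assert not short_term_mortality(late, 0, 5)


# -- aggregation and invariants ---------------------------------------------

def test_single_criterion_is_sufficient_for_sepsis(default_codes):
    labs = labs_frame([(0, -30, "creatinine", 1.0), (0, 0, "creatinine", 2.0)])
    call = _call(labs, EMPTY_EVENTS, default_codes)
    assert call.sepsis and not call.via_shock_code
    assert call.criteria == {"circulatory": False, "respiratory": False,
                             "renal": True, "hepatic": False,
                             "hematologic": False}


def test_no_evidence_no_sepsis(default_codes):
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    call = _call(labs, EMPTY_EVENTS, default_codes)
    assert not call.sepsis and call.evidence == {}


@pytest.mark.parametrize("extra", [
    ("MED", "norepinephrine"),
    ("ICD10CM", "R65.21"),
    ("CPT", "94002"),
])
def test_monotonicity_adding_events_never_unsets_criteria(
        default_codes, population_small, extra):
    """Appending a qualifying event can only flip flags false -> true."""
    events = population_small.events
    labs = population_small.labs
    pats = population_small.patients.head(40)
    adm = pd.DataFrame({"patient_id": pats["patient_id"],
                        "start_day": pats["admission_day"],
                        "discharge_day": pats["discharge_day"]})
    before = phenotype_admissions(adm, pats, events, labs, default_codes)
    system, code = extra
    new_rows = events_frame([(int(pid), 0, system, code)
                             for pid in pats["patient_id"]])
    new_rows["event_id"] += events["event_id"].max() + 1
    after = phenotype_admissions(
        adm, pats, pd.concat([events, new_rows], ignore_index=True), labs,
        default_codes)
    flags = ["sepsis", "shock_code", "circulatory", "respiratory", "renal",
             "hepatic", "hematologic"]
    merged = before.merge(after, on="patient_id", suffixes=("_a", "_b"))
    for f in flags:
        assert not (merged[f + "_a"] & ~merged[f + "_b"]).any()


def test_evidence_cites_rows_that_satisfy_the_rule(
        default_codes, population_small, cohort_small):
    """Every true flag's evidence ids re-satisfy the rule directly."""
    cohort, _ = cohort_small
    labs = normalize_labs(population_small.labs).set_index("lab_id")
    events = population_small.events.set_index("event_id")
    sample = cohort[cohort["sepsis"]].head(120)
    lab_crit = {"renal", "hepatic", "hematologic"}
    for row in sample.itertuples(index=False):
        assert row.evidence, "true sepsis call must carry evidence"
        for part in row.evidence.split(";"):
            flag, ids = part.split(":")
            ids = [int(x) for x in ids.split(",")]
            assert ids, f"flag {flag} cited no rows"
            if flag in lab_crit:
                pid_labs = labs[labs["patient_id"] == row.patient_id]
                analyte = {"renal": "creatinine", "hepatic": "bilirubin_total",
                           "hematologic": "platelets"}[flag]
                pool = pid_labs[pid_labs["analyte"] == analyte]["value"]
                base = pool.min() if flag != "hematologic" else pool.max()
                for i in ids:
                    v = labs.loc[i, "value"]
                    if flag == "renal":
                        assert v >= 2 * base
                    elif flag == "hepatic":
                        assert v >= 2.0 and v >= 2 * base
                    else:
                        assert base >= 1e5 and v < 1e5 and v <= 0.5 * base
            else:
                cited = events.loc[ids]
                assert (cited["patient_id"] == row.patient_id).all()


def test_pipeline_matches_naive_oracle(default_codes, population_small,
                                       cohort_small):
    """Nested-loop re-evaluation agrees with the pipeline on 400 patients."""
    cohort, _ = cohort_small
    sample = cohort.head(400)
    lab_rows = {p: g.to_dict("records")
                for p, g in population_small.labs.groupby("patient_id")}
    ev_rows = {p: g.to_dict("records")
               for p, g in population_small.events.groupby("patient_id")}
    pats = population_small.patients.set_index("patient_id", drop=False)
    flags = ["sepsis", "shock_code", "circulatory", "respiratory", "renal",
             "hepatic", "hematologic", "mortality"]
    for row in sample.itertuples(index=False):
        oracle = naive_phenotype(
            pats.loc[row.patient_id].to_dict(), int(row.start_day),
            int(row.discharge_day), lab_rows.get(row.patient_id, []),
            ev_rows.get(row.patient_id, []), default_codes)
        for f in flags:
            assert oracle[f] == bool(getattr(row, f)), (row.patient_id, f)
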