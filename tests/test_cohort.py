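"""Inclusion/exclusion rules, index selection and attrition accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apol1sepsis.cohort import (assemble_cohort, qualify_admissions,
                                select_index)
from apol1sepsis.codes import CodeConfig
from apol1sepsis.errors import ConfigurationError, ValidationError
from helpers import events_frame, labs_frame, patient, patients_frame


def _base_tables(**patient_kw):
    pats = patients_frame([patient(pid=0, age=34.0, **patient_kw)])
    events = events_frame([
        (0, 0, "ICD10CM", "N39.0"),       # urinary-tract infection
        (0, 1, "MED", "vancomycin"),      # antibiotic on day +1
    ])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    return pats, events, labs


def test_base_admission_qualifies(default_codes):
    pats, events, labs = _base_tables()
    out = qualify_admissions(events, labs, pats, default_codes)
    assert out["qualifies"].all()


@pytest.mark.parametrize("mutate,expected_step", [
    ("abx_day_plus_2", "no_antibiotic"),
    ("no_infection", "no_infection_code"),
    ("age_17", "age_under_18"),
    ("covid_code", "covid_positive"),
    ("covid_flag", "covid_positive"),
    ("cardiac_surgery", "cardiac_surgery"),
    ("cardiogenic_shock", "cardiogenic_shock"),
    ("transplant", "organ_transplant"),
    ("no_labs", "no_relevant_labs"),
])
def test_exclusion_steps(default_codes, mutate, expected_step):
    pats, events, labs = _base_tables()
    if mutate == "abx_day_plus_2":
        events.loc[events["code_system"] == "MED", "day"] = 2
    elif mutate == "no_infection":
        events = events[events["code_system"] == "MED"]
    elif mutate == "age_17":
        pats.loc[0, "age"] = 17.0
    elif mutate == "covid_code":
        events = pd.concat(
            [events, events_frame([(0, 0, "ICD10CM", "U07.1")])])
    elif mutate == "covid_flag":
        pats.loc[0, "covid_positive"] = 1
    elif mutate == "cardiac_surgery":
        events = pd.concat([events, events_frame([(0, 0, "CPT", "33510")])])
    elif mutate == "cardiogenic_shock":
        events = pd.concat(
            [events, events_frame([(0, 0, "ICD10CM", "R57.0")])])
    elif mutate == "transplant":
        events = pd.concat(
            [events, events_frame([(0, 0, "ICD10CM", "Z94.0")])])
    elif mutate == "no_labs":
        labs = labs.iloc[0:0]
    out = qualify_admissions(events, labs, pats, default_codes)
    assert not out["qualifies"].any()
    assert out["fail_step"].iloc[0] == expected_step


@settings(derandomize=True, max_examples=30, deadline=None)
@given(day=st.integers(-5, 5))
def test_window_semantics_for_antibiotic_day(day):
    """Only antibiotic administration on days -1, 0 or +1 qualifies."""
    codes = CodeConfig.default()
    pats = patients_frame([patient(pid=0, age=34.0)])
    events = events_frame([(0, 0, "ICD10CM", "N39.0"),
                           (0, day, "MED", "vancomycin")])
    labs = labs_frame([(0, 0, "creatinine", 1.0)])
    out = qualify_admissions(events, labs, pats, codes)
    assert bool(out["qualifies"].iloc[0]) == (day in (-1, 0, 1))


def test_unknown_code_system_rejected(default_codes):
    pats, events, labs = _base_tables()
    events.loc[0, "code_system"] = "SNOMED"
    with pytest.raises(ValidationError):
        qualify_admissions(events, labs, pats, default_codes)


def test_empty_code_list_is_a_configuration_error(default_codes):
    raw = {k: v for k, v in default_codes.raw.items()}
    raw["antibiotics"] = []
    with pytest.raises(ConfigurationError):
        CodeConfig(raw)


def _candidates(rows):
    df = pd.DataFrame(rows, columns=["admission_id", "patient_id",
                                     "start_day", "discharge_day"])
    df["qualifies"] = True
    df["fail_step"] = ""
    df["steps_passed"] = 9
    return df


def test_index_selection_prefers_earliest_admission():
    out = select_index(_candidates([(1, 0, 100, 110), (2, 0, 40, 45)]))
    assert out["admission_id"].tolist() == [2]


def test_index_selection_tie_breaks_on_stay_then_id():
    # same start day: longer stay wins
    out = select_index(_candidates([(1, 0, 10, 12), (2, 0, 10, 20)]))
    assert out["admission_id"].tolist() == [2]
    # fully tied: lower admission id wins
    out = select_index(_candidates([(5, 0, 10, 15), (3, 0, 10, 15)]))
    assert out["admission_id"].tolist() == [3]


def test_single_admission_selects_itself():
    out = select_index(_candidates([(7, 0, 3, 9)]))
    assert out["admission_id"].tolist() == [7]


def test_attrition_conserves_counts(population_small):
    """Injected exclusions land in the right attrition rows and the
    step counts sum back to the input n."""
    pats = population_small.patients.copy()
    events = population_small.events.copy()
    labs = population_small.labs.copy()
    pats.loc[pats["patient_id"].isin([0, 1, 2]), "age"] = 15.0      # minors
    pats.loc[pats["patient_id"].isin([3, 4]), "covid_positive"] = 1
    pats.loc[pats["patient_id"] == 5, "g1_dosage"] = pd.NA          # no call
    labs = labs[~labs["patient_id"].isin([6, 7])]                   # no labs
    cohort, attrition = assemble_cohort(pats, events, labs)
    counts = attrition.set_index("step")["n_removed"]
    assert counts["age_under_18"] == 3
    assert counts["covid_positive"] == 2
    assert counts["unclassifiable_genotype"] == 1
    assert counts["no_relevant_labs"] == 2
    assert counts.sum() + len(cohort) == len(pats)
    assert attrition["n_remaining"].iloc[-1] == len(cohort)
    assert not cohort["patient_id"].isin([0, 1, 2, 3, 4, 5, 6, 7]).any()


def test_cohort_is_invariant_to_event_row_order(population_small):
    pats = population_small.patients.head(200)
    keep = population_small.events["patient_id"] < 200
    events = population_small.events[keep]
    labs = population_small.labs[population_small.labs["patient_id"] < 200]
    cohort1, _ = assemble_cohort(pats, events, labs)
    shuffled = events.sample(frac=1.0, random_state=5).reset_index(drop=True)
    cohort2, _ = assemble_cohort(pats, shuffled, labs)
    a = cohort1.sort_values("patient_id").reset_index(drop=True)
    b = cohort2.sort_values("patient_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a.drop(columns="evidence"),
                                  b.drop(columns="evidence"))


def test_noise_free_population_is_fully_eligible(cohort_small, population_small):
    cohort, attrition = cohort_small
    assert len(cohort) == len(population_small.patients)
    assert (attrition["n_removed"] == 0).all()


def test_duplicate_patient_ids_rejected(default_codes):
    pats, events, labs = _base_tables()
    dup = pd.concat([pats, pats], ignore_index=True)
    with pytest.raises(ValidationError):
        assemble_cohort(dup, events, labs, default_codes)
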