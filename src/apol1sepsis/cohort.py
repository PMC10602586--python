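"""Infection-hospitalization cohort construction.

An admission qualifies when the patient is >= 18 years old on the
admission day and has both an infection billing code and an antibiotic
administration within one day of admission (days -1, 0, +1).
Exclusions then remove admissions for cardiac surgery, cardiogenic
shock or organ transplantation, admissions with no peri-admission
creatinine, bilirubin or platelet value, and admissions with a COVID-19
positive flag or U07.1 code in the window.  Only the first qualifying
hospitalization per patient is kept (ties broken by longest stay, then
lowest admission id), and patients with an unclassifiable APOL1
genotype are dropped with a logged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariates as cov
from . import phenotype as phe
from .codes import CODE_SYSTEMS, INFECTION_TYPES, CodeConfig, load_charlson_map
from .config import CRITERIA
from .errors import ValidationError
from .genotype import classify_patients

#: Inclusion/exclusion steps, in the order they are applied.
ATTRITION_STEPS = (
    "age_under_18",
    "no_infection_code",
    "no_antibiotic",
    "cardiac_surgery",
    "cardiogenic_shock",
    "organ_transplant",
    "no_relevant_labs",
    "covid_positive",
    "unclassifiable_genotype",
)

#: All peri-admission labs absent (the weaker reading: a patient is
#: excluded only when creatinine AND bilirubin AND platelets are all
#: missing in the window).  Set to "any" to require every analyte.
LAB_EXCLUSION_MODE = "all"


@dataclass(frozen=True)
class AdmissionWindow:
    """One hospital admission; day offsets share the patient's anchor."""

    admission_id: int
    patient_id: int
    start_day: int
    discharge_day: int

    def __post_init__(self):
        if self.discharge_day < self.start_day:
            raise ValidationError("discharge before admission")

    @property
    def window(self) -> tuple[int, int, int]:
        return (self.start_day - 1, self.start_day, self.start_day + 1)


def admissions_from_patients(patients: pd.DataFrame) -> pd.DataFrame:
    """Derive the default one-admission-per-patient table."""
    return pd.DataFrame({
        "admission_id": patients["patient_id"].to_numpy(),
        "patient_id": patients["patient_id"].to_numpy(),
        "start_day": patients["admission_day"].to_numpy(),
        "discharge_day": patients["discharge_day"].to_numpy(),
    })


def age_at(patients_row_age: float, start_day) -> int:
    """Age in whole years on the admission day (floored)."""
    return int(np.floor(patients_row_age + np.asarray(start_day) / 365.25))


def _validate_events(events: pd.DataFrame) -> None:
    bad = set(events["code_system"].unique()) - set(CODE_SYSTEMS)
    if bad:
        raise ValidationError(f"unknown code systems on events: {sorted(bad)}")


def _window_any(admissions, child, prefixes=None, systems=None, codes_lower=None):
    """Per-admission indicator of any matching child row on days -1..+1."""
    sel = child
    if systems is not None:
        sel = sel[sel["code_system"].isin(systems)]
    if prefixes is not None:
        from .codes import normalize_code
        sel = sel[sel["code"].map(normalize_code).str.startswith(tuple(prefixes))]
    if codes_lower is not None:
        sel = sel[sel["code"].astype(str).str.lower().isin(codes_lower)]
    if sel.empty:
        return pd.Series(False, index=admissions.index)
    merged = admissions[["admission_id", "patient_id", "start_day"]].merge(
        sel[["patient_id", "day"]], on="patient_id", how="left")
    merged["hit"] = ((merged["day"] >= merged["start_day"] - 1)
                     & (merged["day"] <= merged["start_day"] + 1))
    hit = merged.groupby("admission_id")["hit"].any()
    return admissions["admission_id"].map(hit).fillna(False).astype(bool)


def qualify_admissions(events: pd.DataFrame, labs: pd.DataFrame,
                       patients: pd.DataFrame, codes: CodeConfig | None = None,
                       admissions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Evaluate the inclusion/exclusion rules per candidate admission.

    Returns the admissions table with ``qualifies`` and ``fail_step``
    (the first failing step, "" when qualifying) columns appended.
    """
    codes = codes or CodeConfig.default()
    _validate_events(events)
    adm = (admissions if admissions is not None
           else admissions_from_patients(patients)).reset_index(drop=True)

    age_base = adm["patient_id"].map(patients.set_index("patient_id")["age"])
    age_ok = np.floor(age_base + adm["start_day"] / 365.25) >= 18

    checks = [
        ("age_under_18", ~age_ok),
        ("no_infection_code",
         ~_window_any(adm, events, prefixes=codes.infection_codes,
                      systems=("ICD9CM", "ICD10CM"))),
        ("no_antibiotic",
         ~_window_any(adm, events, systems=("MED",),
                      codes_lower=codes.antibiotics)),
    ]
    for name, prefixes in codes.exclusion_groups.items():
        checks.append((name, _window_any(adm, events, prefixes=prefixes,
                                         systems=("ICD9CM", "ICD10CM", "CPT"))))

    lab_present = {
        analyte: _window_any_labs(adm, labs, analyte)
        for analyte in ("creatinine", "bilirubin_total", "platelets")
    }
    present = pd.concat(lab_present.values(), axis=1)
    no_labs = (~present.any(axis=1) if LAB_EXCLUSION_MODE == "all"
               else ~present.all(axis=1))
    checks.append(("no_relevant_labs", no_labs))

    covid_code = _window_any(adm, events, prefixes=codes.covid_codes,
                             systems=("ICD9CM", "ICD10CM"))
    covid_flag = adm["patient_id"].map(
        patients.set_index("patient_id")["covid_positive"]).fillna(0).astype(bool)
    checks.append(("covid_positive", covid_code | covid_flag))

    fail_step = pd.Series("", index=adm.index, dtype=object)
    steps_passed = pd.Series(len(checks), index=adm.index)
    for k, (name, failed) in enumerate(checks):
        failed = pd.Series(np.asarray(failed), index=adm.index)
        newly = failed & (fail_step == "")
        fail_step[newly] = name
        steps_passed[newly] = k
    adm = adm.copy()
    adm["qualifies"] = fail_step == ""
    adm["fail_step"] = fail_step
    adm["steps_passed"] = steps_passed
    return adm


def _window_any_labs(admissions, labs, analyte):
    sel = labs[labs["analyte"] == analyte]
    if sel.empty:
        return pd.Series(False, index=admissions.index, name=analyte)
    merged = admissions[["admission_id", "patient_id", "start_day"]].merge(
        sel[["patient_id", "day"]], on="patient_id", how="left")
    merged["hit"] = ((merged["day"] >= merged["start_day"] - 1)
                     & (merged["day"] <= merged["start_day"] + 1))
    hit = merged.groupby("admission_id")["hit"].any()
    out = admissions["admission_id"].map(hit).fillna(False).astype(bool)
    out.name = analyte
    return out


def select_index(candidates: pd.DataFrame) -> pd.DataFrame:
    """First qualifying admission per patient.

    Earliest start day wins; ties go to the longer stay, then the lower
    admission id — a fully deterministic ordering.
    """
    q = candidates[candidates["qualifies"]].copy()
    q["los"] = q["discharge_day"] - q["start_day"]
    q = q.sort_values(["patient_id", "start_day", "los", "admission_id"],
                      ascending=[True, True, False, True], kind="mergesort")
    return q.groupby("patient_id", as_index=False).head(1).drop(columns="los")


def assemble_cohort(patients: pd.DataFrame, events: pd.DataFrame,
                    labs: pd.DataFrame, codes: CodeConfig | None = None,
                    charlson_map: dict | None = None,
                    thresholds: phe.Thresholds = phe.Thresholds(),
                    admissions: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the analysis-ready cohort table and the attrition log.

    Returns ``(cohort, attrition)``; the cohort has one row per patient
    (exposure, covariates, outcomes), the attrition log counts patients
    removed at each step in order, with counts conserving the input n.
    """
    if patients["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient ids in patients table")
    codes = codes or CodeConfig.default()
    charlson_map = charlson_map or load_charlson_map()

    cand = qualify_admissions(events, labs, patients, codes, admissions)
    # Patient-level attrition: attribute each removed patient to the
    # step at which their best-progressing admission failed.
    best = cand.sort_values(["patient_id", "steps_passed"],
                            ascending=[True, False], kind="mergesort")
    best = best.groupby("patient_id", as_index=False).head(1)
    removed = best[~best["qualifies"]]
    step_counts = {s: 0 for s in ATTRITION_STEPS}
    for s, c in removed["fail_step"].value_counts().items():
        step_counts[s] = int(c)

    index = select_index(cand)
    high_risk, n_unclassifiable = classify_patients(patients)
    risk_by_pid = pd.Series(high_risk.to_numpy(), index=patients["patient_id"])
    idx_risk = index["patient_id"].map(risk_by_pid)
    step_counts["unclassifiable_genotype"] = int(idx_risk.isna().sum())
    index = index[idx_risk.notna().to_numpy()]

    calls = phe.phenotype_admissions(index, patients, events, labs, codes,
                                     thresholds)

    pids = pd.Index(index["patient_id"].to_numpy(), name="patient_id")
    start_by_pid = pd.Series(index["start_day"].to_numpy(), index=pids)
    charlson = cov.charlson_flags_table(events, start_by_pid, charlson_map)
    renal_flag = cov.severe_renal_table(events, start_by_pid)
    inf_types = cov.infection_types_table(events, start_by_pid, codes)
    pat = patients.set_index("patient_id").loc[pids]

    cohort = pd.DataFrame({
        "patient_id": pids.to_numpy(),
        "high_risk": risk_by_pid.loc[pids].astype(bool).to_numpy(),
        "age": np.floor(pat["age"].to_numpy()
                        + start_by_pid.to_numpy() / 365.25).astype(int),
        "sex": pat["sex"].astype(str).to_numpy(),
        "pc1": pat["pc1"].to_numpy(), "pc2": pat["pc2"].to_numpy(),
        "pc3": pat["pc3"].to_numpy(),
        "severe_renal": renal_flag.to_numpy(),
        "start_day": index["start_day"].to_numpy(),
        "discharge_day": index["discharge_day"].to_numpy(),
    })
    for c in charlson.columns:
        cohort[f"cm_{c}"] = charlson[c].to_numpy()
    for t in INFECTION_TYPES:
        cohort[f"inf_{t}"] = inf_types[t].to_numpy()
    if not cohort.empty:
        cohort = cohort.merge(
            calls[["patient_id", "sepsis", "shock_code", *CRITERIA,
                   "mortality", "evidence"]],
            on="patient_id", validate="one_to_one")

    n_in = len(patients)
    records, remaining = [], n_in
    records.append({"step": "input_patients", "n_removed": 0,
                    "n_remaining": remaining})
    for s in ATTRITION_STEPS:
        remaining -= step_counts[s]
        records.append({"step": s, "n_removed": step_counts[s],
                        "n_remaining": remaining})
    attrition = pd.DataFrame(records)
    assert remaining == len(cohort), "attrition counts do not conserve n"
    return cohort, attrition
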