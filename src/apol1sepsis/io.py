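"""Readers and writers for the pipeline's tabular file set.

Four UTF-8, RFC-4180 CSV files describe a population:

``patients.csv``
    One row per patient: demographics, genotype dosages, ancestry PCs,
    index admission bounds (integer day offsets; admission day 0 by
    convention), death day, discharge disposition, COVID flag.
``events.csv``
    Dated coded events: ``code_system`` in {ICD9CM, ICD10CM, CPT, MED,
    KEYWORD}; ``value`` carries mention counts for KEYWORD rows.
``labs.csv``
    Dated numeric measurements with analyte and units.
``ground_truth.csv``
    Latent per-patient truth emitted by the generator.
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import ValidationError

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "g1_dosage", "g2_dosage",
    "pc1", "pc2", "pc3", "admission_day", "discharge_day",
    "death_day", "disposition", "covid_positive",
]
EVENT_COLUMNS = ["event_id", "patient_id", "day", "code_system", "code", "value"]
LAB_COLUMNS = ["lab_id", "patient_id", "day", "analyte", "value", "units"]
GROUND_TRUTH_COLUMNS = [
    "patient_id", "true_high_risk", "true_severe_renal", "true_sepsis",
    "true_circulatory", "true_respiratory", "true_renal", "true_hepatic",
    "true_hematologic", "true_shock_code", "true_mortality",
    "true_infection_types",
]

ANALYTES = ("creatinine", "bilirubin_total", "platelets")

_PATIENT_DTYPES = {
    "patient_id": "int64", "age": "float64", "sex": "string",
    "g1_dosage": "Int64", "g2_dosage": "Int64",
    "pc1": "float64", "pc2": "float64", "pc3": "float64",
    "admission_day": "int64", "discharge_day": "int64",
    "death_day": "Int64", "disposition": "string", "covid_positive": "int64",
}
_EVENT_DTYPES = {
    "event_id": "int64", "patient_id": "int64", "day": "int64",
    "code_system": "string", "code": "string", "value": "float64",
}
_LAB_DTYPES = {
    "lab_id": "int64", "patient_id": "int64", "day": "int64",
    "analyte": "string", "value": "float64", "units": "string",
}


def _check_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_population(population, directory) -> list:
    """Write the four-file set; returns the paths written."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, df in (
        ("patients.csv", population.patients),
        ("events.csv", population.events),
        ("labs.csv", population.labs),
        ("ground_truth.csv", population.ground_truth),
    ):
        path = os.path.join(directory, name)
        _write(df, path)
        paths.append(path)
    return paths


def _read(path: str, columns, dtypes, what: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=dtypes)
    _check_columns(df, columns, what)
    return df[columns]


def read_patients(path) -> pd.DataFrame:
    return _read(path, PATIENT_COLUMNS, _PATIENT_DTYPES, "patients table")


def read_events(path) -> pd.DataFrame:
    return _read(path, EVENT_COLUMNS, _EVENT_DTYPES, "events table")


def read_labs(path) -> pd.DataFrame:
    return _read(path, LAB_COLUMNS, _LAB_DTYPES, "labs table")


def read_ground_truth(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path)
    _check_columns(df, GROUND_TRUTH_COLUMNS, "ground-truth table")
    if "true_infection_types" in df.columns:
        df["true_infection_types"] = df["true_infection_types"].fillna("")
    return df[GROUND_TRUTH_COLUMNS]


def read_population(directory):
    """Read the four-file set back into a :class:`~.simulate.Population`."""
    from .simulate import Population

    return Population(
        patients=read_patients(os.path.join(directory, "patients.csv")),
        events=read_events(os.path.join(directory, "events.csv")),
        labs=read_labs(os.path.join(directory, "labs.csv")),
        ground_truth=read_ground_truth(os.path.join(directory, "ground_truth.csv")),
    )
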