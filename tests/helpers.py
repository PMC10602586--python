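"""Table builders and a deliberately naive phenotyping oracle.

The oracle re-evaluates the sepsis rules with plain Python loops over
raw rows, independently of the pipeline's vectorized/pandas path, so
the two can be compared patient by patient.
"""

from __future__ import annotations

import pandas as pd


def patient(pid=0, age=50.0, sex="F", g1=0, g2=0, pc=(0.0, 0.0, 0.0),
            admission=0, discharge=5, death=None, disposition="home", covid=0):
    return {
        "patient_id": pid, "age": age, "sex": sex,
        "g1_dosage": g1, "g2_dosage": g2,
        "pc1": pc[0], "pc2": pc[1], "pc3": pc[2],
        "admission_day": admission, "discharge_day": discharge,
        "death_day": death, "disposition": disposition,
        "covid_positive": covid,
    }


def patients_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["g1_dosage"] = df["g1_dosage"].astype("Int64")
    df["g2_dosage"] = df["g2_dosage"].astype("Int64")
    df["death_day"] = df["death_day"].astype("Int64")
    return df


def events_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, day, code_system, code[, value]) tuples."""
    recs = []
    for i, r in enumerate(rows):
        pid, day, system, code = r[:4]
        value = r[4] if len(r) > 4 else 1.0
        recs.append({"event_id": i, "patient_id": pid, "day": day,
                     "code_system": system, "code": code, "value": value})
    return pd.DataFrame(
        recs, columns=["event_id", "patient_id", "day", "code_system",
                       "code", "value"])


def labs_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, day, analyte, value[, units]) tuples."""
    default_units = {"creatinine": "mg/dL", "bilirubin_total": "mg/dL",
                     "platelets": "/uL"}
    recs = []
    for i, r in enumerate(rows):
        pid, day, analyte, value = r[:4]
        units = r[4] if len(r) > 4 else default_units[analyte]
        recs.append({"lab_id": i, "patient_id": pid, "day": day,
                     "analyte": analyte, "value": value, "units": units})
    return pd.DataFrame(
        recs, columns=["lab_id", "patient_id", "day", "analyte", "value",
                       "units"])


# -- naive oracle -----------------------------------------------------------

def _norm(code) -> str:
    return str(code).replace(".", "").strip().upper()


def _to_internal(analyte, value, units):
    u = str(units).strip().lower()
    if analyte == "creatinine":
        return value if u == "mg/dl" else value / 88.4
    if analyte == "bilirubin_total":
        return value if u == "mg/dl" else value / 17.1
    if analyte == "platelets":
        return value * 1000.0 if u in ("10^3/ul", "10*3/ul", "k/ul") else value
    raise ValueError(analyte)


def naive_phenotype(patient_row: dict, start: int, discharge: int,
                    lab_rows: list, event_rows: list, codes) -> dict:
    """Nested-loop re-evaluation of the sepsis rules for one admission.

    ``lab_rows`` / ``event_rows`` are lists of plain dicts (raw CSV
    rows); ``codes`` supplies the configured code lists.
    """
    vals = {"creatinine": [], "bilirubin_total": [], "platelets": []}
    for r in lab_rows:
        v = _to_internal(r["analyte"], r["value"], r["units"])
        if v > 0:
            vals[r["analyte"]].append((r["day"], v))

    def baseline(analyte, rule):
        xs = [v for d, v in vals[analyte] if start - 365 <= d <= discharge]
        if not xs:
            return None
        return min(xs) if rule == "low" else max(xs)

    def window(analyte):
        return [v for d, v in vals[analyte] if start - 1 <= d <= start + 1]

    b = baseline("creatinine", "low")
    renal = b is not None and any(v >= 2.0 * b for v in window("creatinine"))
    b = baseline("bilirubin_total", "low")
    hepatic = b is not None and any(
        v >= 2.0 and v >= 2.0 * b for v in window("bilirubin_total"))
    b = baseline("platelets", "high")
    hematologic = (b is not None and b >= 100_000 and any(
        v < 100_000 and v <= 0.5 * b for v in window("platelets")))

    def dx_hit(e, prefixes, lo, hi):
        return (e["code_system"] in ("ICD9CM", "ICD10CM", "CPT")
                and lo <= e["day"] <= hi
                and any(_norm(e["code"]).startswith(p) for p in prefixes))

    def med_hit(e, names, lo, hi):
        return (e["code_system"] == "MED" and lo <= e["day"] <= hi
                and str(e["code"]).lower() in names)

    lo, hi = start - 1, start + 1
    vent = any(dx_hit(e, codes.ventilation_codes, lo, discharge)
               for e in event_rows)
    icu = any(dx_hit(e, codes.icu_codes, lo, discharge) for e in event_rows)
    respiratory = vent and icu

    mentions = sum(
        e["value"] if e["value"] == e["value"] else 1.0
        for e in event_rows
        if e["code_system"] == "KEYWORD" and lo <= e["day"] <= hi
        and str(e["code"]).lower() in codes.keywords)
    norepi = any(med_hit(e, codes.norepinephrine, lo, hi) for e in event_rows)
    inotrope = any(med_hit(e, codes.inotropes, lo, hi) for e in event_rows)
    echo = any(dx_hit(e, codes.stress_echo_codes, lo, hi) for e in event_rows)
    circulatory = norepi or (inotrope and not echo and mentions >= 2)

    shock = any(dx_hit(e, codes.shock_codes, lo, hi) for e in event_rows)

    death = patient_row["death_day"]
    has_death = death is not None and death == death and str(death) != "<NA>"
    mortality = ((has_death and start <= int(death) <= discharge)
                 or str(patient_row["disposition"]) == "hospice")

    return {
        "sepsis": shock or renal or hepatic or hematologic or respiratory
        or circulatory,
        "shock_code": shock,
        "circulatory": circulatory, "respiratory": respiratory,
        "renal": renal, "hepatic": hepatic, "hematologic": hematologic,
        "mortality": mortality,
    }
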