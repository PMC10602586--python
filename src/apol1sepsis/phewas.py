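"""Restricted PheWAS over five prespecified sepsis-related phecodes.

Phecodes aggregate ICD-9/ICD-10 diagnosis codes into clinical
phenotypes.  Per phecode: a case has two or more occurrences on
distinct days; a single mention, or any code mapping into the phecode's
related exclusion range, excludes a non-case; everyone else is a
control.  Each phecode is tested by logistic regression of case status
on the high-risk genotype with adjustment for age, sex and three PCs;
significance uses a Bonferroni threshold of 0.05 / 5 = 0.01 (strict
less-than).  A second pass repeats the analysis after excluding
patients with pre-existing severe renal disease.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .association import ModelSpec, fit_logistic
from .codes import normalize_code
from .errors import ConfigurationError, ValidationError

#: The five prespecified sepsis-related phecodes.
TARGET_PHECODES = ("038", "081", "994.1", "994.2", "994.21")

BONFERRONI_ALPHA = 0.05


class PhecodeDefinition:
    """One phecode: label, exact ICD code set, related exclusion ranges."""

    def __init__(self, phecode: str, label: str, icd9, icd10, exclude_range):
        self.phecode = str(phecode)
        self.label = label
        self.codes = frozenset(normalize_code(c) for c in (*icd9, *icd10))
        self.exclude_ranges = tuple((float(lo), float(hi))
                                    for lo, hi in exclude_range)
        self.value = float(self.phecode)


def load_definitions(path=None) -> dict[str, PhecodeDefinition]:
    """Load the phecode map (built-in miniature map by default)."""
    if path is None:
        text = resources.files("apol1sepsis.data").joinpath("phecodes.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = {}
    for code, entry in raw["phecodes"].items():
        defs[str(code)] = PhecodeDefinition(
            code, entry.get("label", ""), entry.get("icd9", ()),
            entry.get("icd10", ()), entry.get("exclude_range", ()))
    missing = set(TARGET_PHECODES) - set(defs)
    if missing:
        raise ConfigurationError(f"phecode map missing targets: {sorted(missing)}")
    return defs


def map_icd_to_phecodes(events: pd.DataFrame,
                        definitions: dict[str, PhecodeDefinition]
                        ) -> pd.DataFrame:
    """Per-patient distinct-day occurrence counts per phecode.

    A diagnosis code may roll up to several phecodes (child plus
    parent); occurrences of the same phecode on one calendar day count
    once.  Unmapped codes are ignored (their count is returned on the
    frame's ``attrs`` for logging).
    """
    dx = events[events["code_system"].isin(("ICD9CM", "ICD10CM"))]
    if dx.empty:
        out = pd.DataFrame(columns=["patient_id", "phecode", "n_days"])
        out.attrs["n_unmapped_codes"] = 0
        return out
    norm = dx["code"].map(normalize_code)
    code_to_phecodes: dict[str, list[str]] = {}
    for ph, d in definitions.items():
        for c in d.codes:
            code_to_phecodes.setdefault(c, []).append(ph)
    mapped = norm.map(code_to_phecodes)
    unmapped = mapped.isna()
    hits = pd.DataFrame({
        "patient_id": dx.loc[~unmapped, "patient_id"],
        "day": dx.loc[~unmapped, "day"],
        "phecode": mapped[~unmapped],
    }).explode("phecode")
    counts = (hits.drop_duplicates(["patient_id", "phecode", "day"])
              .groupby(["patient_id", "phecode"], as_index=False)
              .size().rename(columns={"size": "n_days"}))
    counts.attrs["n_unmapped_codes"] = int(unmapped.sum())
    return counts


def assign_case_control(counts: pd.DataFrame, patient_ids,
                        definitions: dict[str, PhecodeDefinition],
                        targets=TARGET_PHECODES) -> pd.DataFrame:
    """Per patient per target phecode: case, control or excluded.

    Case: >= 2 distinct-day occurrences (takes precedence).  Excluded:
    exactly one occurrence, or any code mapping to a phecode inside the
    target's related exclusion range.  Control: neither.
    """
    patient_ids = pd.Index(patient_ids, name="patient_id")
    wide = (counts.pivot(index="patient_id", columns="phecode", values="n_days")
            .reindex(patient_ids).fillna(0).astype(int)
            if not counts.empty else
            pd.DataFrame(0, index=patient_ids, columns=list(targets)))
    out = []
    values = {ph: definitions[ph].value for ph in definitions}
    for t in targets:
        d = definitions[t]
        n = wide[t] if t in wide.columns else pd.Series(0, index=patient_ids)
        related = pd.Series(False, index=patient_ids)
        for ph, v in values.items():
            if ph not in wide.columns:
                continue
            if any(lo <= v <= hi for lo, hi in d.exclude_ranges):
                related |= wide[ph] > 0
        status = np.where(n >= 2, "case",
                          np.where((n == 1) | related, "excluded", "control"))
        out.append(pd.DataFrame({
            "patient_id": patient_ids, "phecode": t, "status": status}))
    return pd.concat(out, ignore_index=True)


def run_restricted_phewas(patients: pd.DataFrame, assignments: pd.DataFrame,
                          definitions: dict[str, PhecodeDefinition] | None = None,
                          exclude_severe_renal: bool = False,
                          alpha: float = BONFERRONI_ALPHA) -> pd.DataFrame:
    """Fit the five genotype -> phecode logistic models.

    ``patients`` is the population-wide table (high_risk, severe_renal,
    age, sex, pc1..pc3).  The Bonferroni threshold is
    ``alpha / n_targets``; the significance comparison is strictly
    less-than, so a p exactly at the threshold is not significant.
    Phecodes with no cases (or no controls) are flagged unestimable.
    """
    definitions = definitions or load_definitions()
    targets = sorted(assignments["phecode"].unique(),
                     key=lambda c: float(c))
    threshold = alpha / len(targets)
    pop = patients
    if exclude_severe_renal:
        pop = pop[~pop["severe_renal"].astype(bool)]
    out = []
    for t in targets:
        sub = assignments[assignments["phecode"] == t]
        merged = pop.merge(sub[sub["status"] != "excluded"], on="patient_id")
        n_excluded = len(pop) - len(merged)
        merged = merged.assign(outcome=(merged["status"] == "case"))
        row = {
            "phecode": t,
            "label": definitions[t].label if t in definitions else "",
            "pass": "severe_renal_excluded" if exclude_severe_renal else "all",
            "n_cases": int(merged["outcome"].sum()),
            "n_controls": int((~merged["outcome"]).sum()),
            "n_excluded": n_excluded,
            "bonferroni_threshold": threshold,
        }
        try:
            res = fit_logistic(
                merged, ModelSpec(outcome="outcome"))
            row.update({
                "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p": res.p,
                "significant": bool(res.converged and np.isfinite(res.p)
                                    and res.p < threshold),
                "estimable": res.converged,
                "note": res.note,
            })
        except ValidationError as exc:
            row.update({
                "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "significant": False, "estimable": False,
                "note": str(exc),
            })
        out.append(row)
    return pd.DataFrame(out)


def phewas_table_from_population(patients: pd.DataFrame,
                                 events: pd.DataFrame) -> pd.DataFrame:
    """Build the population-wide PheWAS covariate table from raw tables.

    Severe-renal status uses the whole record (any listed code in the
    EHR), matching the sensitivity-analysis definition.
    """
    from .covariates import severe_renal
    from .genotype import classify_patients

    high_risk, _ = classify_patients(patients)
    groups = {pid: df for pid, df in events.groupby("patient_id")}
    empty = events.iloc[0:0]
    renal = [
        severe_renal(groups.get(int(pid), empty), start_day=None)[0]
        for pid in patients["patient_id"]
    ]
    out = patients[["patient_id", "age", "sex", "pc1", "pc2", "pc3"]].copy()
    out["high_risk"] = high_risk.to_numpy()
    out["severe_renal"] = renal
    return out[out["high_risk"].notna()].assign(
        high_risk=lambda d: d["high_risk"].astype(bool))
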