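"""Adapted EHR Sepsis-3 phenotyping and short-term mortality.

A patient in the infection cohort is called septic if they carry any of
the four septic-shock / severe-sepsis billing codes (ICD-9 995.92,
785.52; ICD-10 R65.20, R65.21) in the peri-admission window, or meet
any of five organ-dysfunction criteria evaluated against a
patient-specific lab baseline:

circulatory
    Norepinephrine use, or dobutamine/dopamine use unrelated to stress
    echocardiography with at least two mentions of
    infection/sepsis/septic keywords.
respiratory
    Ventilation codes together with ICU admission markers.
renal
    Peri-admission creatinine at least double the baseline (lowest
    value from one year before admission through discharge).
hepatic
    Total bilirubin >= 2 mg/dL (34.2 µmol/L) and at least double the
    baseline (lowest value over the same window).
hematologic
    Platelets < 100,000/µL with a >= 50% decline from a baseline
    (highest value over the window) that was itself >= 100,000/µL.

All fold-change comparisons are inclusive (>=).  Organ dysfunction is
evaluated on days {-1, 0, +1} around admission; a missing baseline
makes a lab criterion false (dysfunction cannot be asserted without a
reference) and is logged as not evaluable.  Short-term mortality is
in-hospital death or discharge to hospice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CodeConfig, normalize_code
from .config import CRITERIA
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Numeric thresholds and rule switches of the Sepsis-3 algorithm.

    Internal lab units: creatinine and bilirubin mg/dL, platelets /µL.
    """

    creatinine_fold: float = 2.0
    bilirubin_abs: float = 2.0          # mg/dL (= 34.2 umol/L)
    bilirubin_fold: float = 2.0
    platelet_abs: float = 100_000.0     # per uL
    platelet_decline: float = 0.50
    keyword_min_mentions: int = 2
    baseline_lookback_days: int = 365
    # The published rule is ambiguous about whether the keyword clause
    # applies to the norepinephrine branch; default applies it to the
    # dobutamine/dopamine branch only.
    keyword_rule_on_norepinephrine: bool = False
    # ICU requirement evaluated over the whole index stay ("stay") or
    # only the peri-admission window ("window").
    icu_window: str = "stay"

    def validate(self) -> "Thresholds":
        for name in ("creatinine_fold", "bilirubin_abs", "bilirubin_fold",
                     "platelet_abs"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 < self.platelet_decline < 1:
            raise ValidationError("platelet_decline must lie in (0, 1)")
        if self.icu_window not in ("stay", "window"):
            raise ValidationError("icu_window must be 'stay' or 'window'")
        return self


@dataclass
class SepsisCall:
    """Phenotyping result for one index admission."""

    patient_id: int
    sepsis: bool
    via_shock_code: bool
    criteria: dict                       # criterion -> bool
    evidence: dict = field(default_factory=dict)  # flag -> list of row ids
    not_evaluable: tuple = ()            # lab criteria lacking a baseline

    def __post_init__(self):
        assert self.sepsis == (self.via_shock_code or any(self.criteria.values()))


# -- unit normalization -----------------------------------------------------

_UNIT_FACTORS = {
    "creatinine": {"mg/dl": 1.0, "umol/l": 1.0 / 88.4, "µmol/l": 1.0 / 88.4},
    "bilirubin_total": {"mg/dl": 1.0, "umol/l": 1.0 / 17.1, "µmol/l": 1.0 / 17.1},
    "platelets": {"/ul": 1.0, "per_ul": 1.0, "10^3/ul": 1000.0,
                  "10*3/ul": 1000.0, "k/ul": 1000.0},
}


def normalize_labs(labs: pd.DataFrame) -> pd.DataFrame:
    """Convert lab values to internal units; drop non-positive values.

    Unknown analyte/unit combinations raise; non-positive values are
    dropped with a warning rather than an error.
    """
    out = labs.copy()
    factor = np.full(len(out), np.nan)
    analytes = out["analyte"].astype(str).str.strip()
    units = out["units"].astype(str).str.strip().str.lower()
    for analyte, table in _UNIT_FACTORS.items():
        mask = (analytes == analyte).to_numpy()
        if not mask.any():
            continue
        for unit, f in table.items():
            factor[mask & (units == unit).to_numpy()] = f
    unknown_analyte = ~analytes.isin(_UNIT_FACTORS).to_numpy()
    if unknown_analyte.any():
        bad = sorted(analytes[unknown_analyte].unique())
        raise ValidationError(f"unknown analytes: {bad}")
    if np.isnan(factor).any():
        bad = sorted(set(zip(analytes[np.isnan(factor)],
                             labs["units"][np.isnan(factor)])))
        raise ValidationError(f"unknown units for analytes: {bad}")
    out["value"] = out["value"].to_numpy() * factor
    nonpos = ~(out["value"] > 0)
    if nonpos.any():
        logger.warning("dropping %d non-positive lab values", int(nonpos.sum()))
        out = out[~nonpos]
    return out


# -- baselines and lab criteria ---------------------------------------------

_BASELINE_RULE = {"creatinine": "lowest", "bilirubin_total": "lowest",
                  "platelets": "highest"}


def compute_baseline(labs_norm: pd.DataFrame, analyte: str, start_day: int,
                     discharge_day: int, thresholds: Thresholds = Thresholds()):
    """Baseline lab value over [admission - lookback, discharge].

    Lowest creatinine/bilirubin, highest platelets; ``None`` if the
    window holds no value.  ``labs_norm`` must already be unit-normalized.
    """
    sel = labs_norm[
        (labs_norm["analyte"] == analyte)
        & (labs_norm["day"] >= start_day - thresholds.baseline_lookback_days)
        & (labs_norm["day"] <= discharge_day)
    ]
    if sel.empty:
        return None
    values = sel["value"]
    return float(values.min() if _BASELINE_RULE[analyte] == "lowest"
                 else values.max())


def _window_labs(labs_norm, analyte, start_day):
    return labs_norm[(labs_norm["analyte"] == analyte)
                     & (labs_norm["day"] >= start_day - 1)
                     & (labs_norm["day"] <= start_day + 1)]


def renal_criterion(labs_norm, start_day, baseline, thresholds=Thresholds()):
    """Creatinine doubling (or greater) over baseline; inclusive fold."""
    if baseline is None:
        return False, []
    win = _window_labs(labs_norm, "creatinine", start_day)
    hits = win[win["value"] >= thresholds.creatinine_fold * baseline]
    return not hits.empty, hits["lab_id"].tolist()


def hepatic_criterion(labs_norm, start_day, baseline, thresholds=Thresholds()):
    """Bilirubin >= 2 mg/dL absolute AND >= double the baseline."""
    if baseline is None:
        return False, []
    win = _window_labs(labs_norm, "bilirubin_total", start_day)
    hits = win[(win["value"] >= thresholds.bilirubin_abs)
               & (win["value"] >= thresholds.bilirubin_fold * baseline)]
    return not hits.empty, hits["lab_id"].tolist()


def hematologic_criterion(labs_norm, start_day, baseline, thresholds=Thresholds()):
    """Platelets < 100,000/µL with >= 50% decline from a baseline >= 100,000."""
    if baseline is None or baseline < thresholds.platelet_abs:
        return False, []
    win = _window_labs(labs_norm, "platelets", start_day)
    hits = win[(win["value"] < thresholds.platelet_abs)
               & (win["value"] <= (1 - thresholds.platelet_decline) * baseline)]
    return not hits.empty, hits["lab_id"].tolist()


# -- event criteria ---------------------------------------------------------

def _dx_or_proc(events):
    return events[events["code_system"].isin(("ICD9CM", "ICD10CM", "CPT"))]


def _code_hits(events, prefixes, day_lo, day_hi):
    sel = _dx_or_proc(events)
    sel = sel[(sel["day"] >= day_lo) & (sel["day"] <= day_hi)]
    if sel.empty:
        return sel
    norm = (sel["_code_norm"] if "_code_norm" in sel.columns
            else sel["code"].map(normalize_code))
    return sel[norm.str.startswith(tuple(prefixes))]


def _med_hits(events, names, day_lo, day_hi):
    sel = events[(events["code_system"] == "MED")
                 & (events["day"] >= day_lo) & (events["day"] <= day_hi)]
    if sel.empty:
        return sel
    lower = (sel["_code_lower"] if "_code_lower" in sel.columns
             else sel["code"].astype(str).str.lower())
    return sel[lower.isin(names)]


def keyword_mentions(events, codes: CodeConfig, start_day: int) -> float:
    """Total infection/sepsis/septic mention count over days -1..+1."""
    sel = events[(events["code_system"] == "KEYWORD")
                 & (events["day"] >= start_day - 1)
                 & (events["day"] <= start_day + 1)]
    lower = (sel["_code_lower"] if "_code_lower" in sel.columns
             else sel["code"].astype(str).str.lower())
    sel = sel[lower.isin(codes.keywords)]
    return float(sel["value"].fillna(1.0).sum())


def respiratory_criterion(events, start_day, discharge_day, codes,
                          thresholds=Thresholds()):
    """Ventilation codes AND an ICU-admission marker (conjunction)."""
    if thresholds.icu_window == "window":
        lo, hi = start_day - 1, start_day + 1
    else:
        lo, hi = start_day - 1, discharge_day
    vent = _code_hits(events, codes.ventilation_codes, lo, hi)
    icu = _code_hits(events, codes.icu_codes, lo, hi)
    ok = (not vent.empty) and (not icu.empty)
    return ok, (vent["event_id"].tolist() + icu["event_id"].tolist()) if ok else []


def circulatory_criterion(events, start_day, codes, thresholds=Thresholds()):
    """Vasopressor rule: norepinephrine, or an inotrope unrelated to
    stress echocardiography with >= 2 keyword mentions."""
    lo, hi = start_day - 1, start_day + 1
    mentions = keyword_mentions(events, codes, start_day)
    norepi = _med_hits(events, codes.norepinephrine, lo, hi)
    if not norepi.empty:
        if (not thresholds.keyword_rule_on_norepinephrine
                or mentions >= thresholds.keyword_min_mentions):
            return True, norepi["event_id"].tolist()
    ino = _med_hits(events, codes.inotropes, lo, hi)
    if ino.empty:
        return False, []
    echo = _code_hits(events, codes.stress_echo_codes, lo, hi)
    if echo.empty and mentions >= thresholds.keyword_min_mentions:
        return True, ino["event_id"].tolist()
    return False, []


def shock_code_flag(events, start_day, codes):
    """Any of the four septic-shock/severe-sepsis codes on days -1..+1."""
    hits = _code_hits(events, codes.shock_codes, start_day - 1, start_day + 1)
    return not hits.empty, hits["event_id"].tolist()


def short_term_mortality(patient_row, start_day, discharge_day) -> bool:
    """In-hospital death (death day within the stay) or hospice discharge."""
    death = patient_row["death_day"]
    died_in_house = (pd.notna(death)
                     and start_day <= int(death) <= int(discharge_day))
    return bool(died_in_house or str(patient_row["disposition"]) == "hospice")


# -- aggregation ------------------------------------------------------------

_LAB_CRITERIA = {
    "renal": ("creatinine", renal_criterion),
    "hepatic": ("bilirubin_total", hepatic_criterion),
    "hematologic": ("platelets", hematologic_criterion),
}


def call_sepsis(patient_id, start_day, discharge_day, labs_norm, events,
                codes: CodeConfig, thresholds: Thresholds = Thresholds()) -> SepsisCall:
    """Evaluate the full rule set for one index admission.

    ``labs_norm`` and ``events`` are that patient's rows only;
    ``labs_norm`` must be unit-normalized.
    """
    thresholds.validate()
    evidence: dict[str, list] = {}
    criteria: dict[str, bool] = {}
    not_evaluable = []

    for crit, (analyte, fn) in _LAB_CRITERIA.items():
        baseline = compute_baseline(labs_norm, analyte, start_day,
                                    discharge_day, thresholds)
        if baseline is None:
            not_evaluable.append(crit)
        flag, ids = fn(labs_norm, start_day, baseline, thresholds)
        criteria[crit] = flag
        if flag:
            evidence[crit] = ids

    flag, ids = respiratory_criterion(events, start_day, discharge_day,
                                      codes, thresholds)
    criteria["respiratory"] = flag
    if flag:
        evidence["respiratory"] = ids
    flag, ids = circulatory_criterion(events, start_day, codes, thresholds)
    criteria["circulatory"] = flag
    if flag:
        evidence["circulatory"] = ids
    shock, ids = shock_code_flag(events, start_day, codes)
    if shock:
        evidence["shock_code"] = ids

    criteria = {k: criteria[k] for k in CRITERIA}  # canonical order
    return SepsisCall(
        patient_id=patient_id,
        sepsis=shock or any(criteria.values()),
        via_shock_code=shock,
        criteria=criteria,
        evidence=evidence,
        not_evaluable=tuple(not_evaluable),
    )


def phenotype_one(patient_row, start_day, discharge_day, labs, events,
                  codes: CodeConfig | None = None,
                  thresholds: Thresholds = Thresholds()):
    """Per-admission reference path: sepsis call plus mortality.

    ``labs`` and ``events`` are the patient's raw rows; labs are
    normalized here.  The table-level :func:`phenotype_admissions` is
    the fast path and must agree with this row by row.
    """
    codes = codes or CodeConfig.default()
    call = call_sepsis(int(patient_row["patient_id"]), start_day, discharge_day,
                       normalize_labs(labs), events, codes, thresholds)
    mort = short_term_mortality(patient_row, start_day, discharge_day)
    return call, mort


def _ids_by_patient(frame, mask, id_col, pids):
    """patient -> sorted list of ids where mask holds (empty list default)."""
    hits = frame.loc[mask]
    agg = hits.groupby("patient_id")[id_col].agg(sorted)
    return {pid: agg.get(pid, []) for pid in pids}


def phenotype_admissions(index_admissions: pd.DataFrame, patients: pd.DataFrame,
                         events: pd.DataFrame, labs: pd.DataFrame,
                         codes: CodeConfig | None = None,
                         thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Run the phenotyper over a table of index admissions (vectorized).

    ``index_admissions`` needs ``patient_id``, ``start_day``,
    ``discharge_day`` (one row per patient).  Returns one row per
    patient with the sepsis call, per-criterion flags, short-term
    mortality and semicolon-joined evidence ids.  Row-for-row
    equivalent to :func:`call_sepsis` on each admission.
    """
    codes = codes or CodeConfig.default()
    thresholds.validate()
    adm = index_admissions.reset_index(drop=True)
    pids = adm["patient_id"].to_numpy()
    start = pd.Series(adm["start_day"].to_numpy(), index=pids)
    discharge = pd.Series(adm["discharge_day"].to_numpy(), index=pids)

    labs_norm = normalize_labs(labs)
    L = labs_norm[labs_norm["patient_id"].isin(start.index)].copy()
    L["_start"] = L["patient_id"].map(start)
    L["_discharge"] = L["patient_id"].map(discharge)
    in_base = ((L["day"] >= L["_start"] - thresholds.baseline_lookback_days)
               & (L["day"] <= L["_discharge"]))
    in_win = (L["day"] >= L["_start"] - 1) & (L["day"] <= L["_start"] + 1)

    def baseline_of(analyte):
        sel = L[(L["analyte"] == analyte) & in_base]
        agg = sel.groupby("patient_id")["value"]
        base = (agg.min() if _BASELINE_RULE[analyte] == "lowest" else agg.max())
        return L["patient_id"].map(base), base.reindex(start.index)

    crit_flags: dict[str, pd.Series] = {}
    crit_ids: dict[str, dict] = {}
    not_evaluable: dict[str, pd.Series] = {}

    rowbase, base_c = baseline_of("creatinine")
    mask = ((L["analyte"] == "creatinine") & in_win
            & (L["value"] >= thresholds.creatinine_fold * rowbase))
    crit_ids["renal"] = _ids_by_patient(L, mask, "lab_id", pids)
    not_evaluable["renal"] = base_c.isna()

    rowbase, base_b = baseline_of("bilirubin_total")
    mask = ((L["analyte"] == "bilirubin_total") & in_win
            & (L["value"] >= thresholds.bilirubin_abs)
            & (L["value"] >= thresholds.bilirubin_fold * rowbase))
    crit_ids["hepatic"] = _ids_by_patient(L, mask, "lab_id", pids)
    not_evaluable["hepatic"] = base_b.isna()

    rowbase, base_p = baseline_of("platelets")
    mask = ((L["analyte"] == "platelets") & in_win
            & (rowbase >= thresholds.platelet_abs)
            & (L["value"] < thresholds.platelet_abs)
            & (L["value"] <= (1 - thresholds.platelet_decline) * rowbase))
    crit_ids["hematologic"] = _ids_by_patient(L, mask, "lab_id", pids)
    not_evaluable["hematologic"] = base_p.isna()

    E = events[events["patient_id"].isin(start.index)].copy()
    E["_norm"] = E["code"].map(normalize_code)
    E["_lower"] = E["code"].astype(str).str.lower()
    E["_start"] = E["patient_id"].map(start)
    E["_discharge"] = E["patient_id"].map(discharge)
    e_win = (E["day"] >= E["_start"] - 1) & (E["day"] <= E["_start"] + 1)
    if thresholds.icu_window == "window":
        e_stay = e_win
    else:
        e_stay = (E["day"] >= E["_start"] - 1) & (E["day"] <= E["_discharge"])
    is_dx = E["code_system"].isin(("ICD9CM", "ICD10CM", "CPT"))
    is_med = E["code_system"] == "MED"

    def any_of(mask):
        hit = E.loc[mask].groupby("patient_id").size() > 0
        return hit.reindex(start.index, fill_value=False).astype(bool)

    vent_mask = is_dx & e_stay & E["_norm"].str.startswith(tuple(codes.ventilation_codes))
    icu_mask = is_dx & e_stay & E["_norm"].str.startswith(tuple(codes.icu_codes))
    resp = any_of(vent_mask) & any_of(icu_mask)
    resp_ids = _ids_by_patient(E, vent_mask | icu_mask, "event_id", pids)
    crit_ids["respiratory"] = resp_ids

    kw_mask = ((E["code_system"] == "KEYWORD") & e_win
               & E["_lower"].isin(codes.keywords))
    mentions = (E.loc[kw_mask].assign(v=E.loc[kw_mask, "value"].fillna(1.0))
                .groupby("patient_id")["v"].sum()
                .reindex(start.index, fill_value=0.0))
    norepi_mask = is_med & e_win & E["_lower"].isin(codes.norepinephrine)
    ino_mask = is_med & e_win & E["_lower"].isin(codes.inotropes)
    echo = any_of(is_dx & e_win
                  & E["_norm"].str.startswith(tuple(codes.stress_echo_codes)))
    enough_kw = mentions >= thresholds.keyword_min_mentions
    branch_a = any_of(norepi_mask)
    if thresholds.keyword_rule_on_norepinephrine:
        branch_a &= enough_kw
    branch_b = any_of(ino_mask) & ~echo & enough_kw
    circ = branch_a | branch_b
    norepi_ids = _ids_by_patient(E, norepi_mask, "event_id", pids)
    ino_ids = _ids_by_patient(E, ino_mask, "event_id", pids)
    crit_ids["circulatory"] = {
        pid: (norepi_ids[pid] if branch_a.loc[pid] else ino_ids[pid])
        for pid in pids}

    shock_mask = is_dx & e_win & E["_norm"].str.startswith(tuple(codes.shock_codes))
    shock = any_of(shock_mask)
    shock_ids = _ids_by_patient(E, shock_mask, "event_id", pids)

    crit_flags["renal"] = pd.Series(
        [len(crit_ids["renal"][p]) > 0 for p in pids], index=start.index)
    crit_flags["hepatic"] = pd.Series(
        [len(crit_ids["hepatic"][p]) > 0 for p in pids], index=start.index)
    crit_flags["hematologic"] = pd.Series(
        [len(crit_ids["hematologic"][p]) > 0 for p in pids], index=start.index)
    crit_flags["respiratory"] = resp
    crit_flags["circulatory"] = circ

    pat = patients.set_index("patient_id").loc[start.index]
    death = pat["death_day"]
    mortality = ((death.notna()
                  & (death >= start) & (death <= discharge))
                 | (pat["disposition"].astype(str) == "hospice")).astype(bool)

    sepsis = shock.copy()
    for c in CRITERIA:
        sepsis |= crit_flags[c]

    def evidence_str(pid):
        parts = []
        for flag in sorted((*CRITERIA, "shock_code")):
            if flag == "shock_code":
                ids = shock_ids[pid] if shock.loc[pid] else []
            else:
                ids = crit_ids[flag][pid] if crit_flags[flag].loc[pid] else []
            if ids:
                parts.append(f"{flag}:{','.join(str(i) for i in ids)}")
        return ";".join(parts)

    out = pd.DataFrame({
        "patient_id": pids,
        "sepsis": sepsis.to_numpy(),
        "shock_code": shock.to_numpy(),
    })
    for c in CRITERIA:
        out[c] = crit_flags[c].to_numpy()
    out["mortality"] = mortality.to_numpy()
    out["evidence"] = [evidence_str(p) for p in pids]
    out["not_evaluable"] = [
        ";".join(c for c in ("renal", "hepatic", "hematologic")
                 if not_evaluable[c].loc[p])
        for p in pids]
    cols = ["patient_id", "sepsis", "shock_code", *CRITERIA,
            "mortality", "evidence", "not_evaluable"]
    return out[cols]
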