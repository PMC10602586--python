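"""Comorbidity, severe-renal-disease and infection-type covariates.

Charlson/Deyo comorbidity flags use diagnosis codes from the year
before the index admission (days [-365, -1] relative to admission) with
prefix matching.  The severe-renal flag uses an exact 15-code list of
Stage 4/5 CKD / ESRD diagnosis and procedure codes over the whole prior
record up to and including the admission day (chronic states carry no
lookback limit).  Infection types are a multi-label assignment from
peri-admission infection billing codes.
"""

from __future__ import annotations

import pandas as pd

from .codes import (CHARLSON_CATEGORIES, INFECTION_TYPES, CodeConfig,
                    load_charlson_map, normalize_code)
from .errors import ConfigurationError

#: Stage 4/5 chronic kidney disease / ESRD code list (exact match after
#: dot normalization; editing this set is a config change, prefix
#: matching is deliberately off).
SEVERE_RENAL_CODES = (
    "N18.4", "N18.5", "N18.6", "N18.9",
    "585.4", "585.5", "585.6", "585.9", "586",
    "Z99.2", "Z49.0", "Z49.31", "39.95", "V45.11", "V56.0",
)
_SEVERE_RENAL_NORM = frozenset(normalize_code(c) for c in SEVERE_RENAL_CODES)

_DX = ("ICD9CM", "ICD10CM")


def _dx_events(events: pd.DataFrame) -> pd.DataFrame:
    return events[events["code_system"].isin(_DX)]


def charlson_flags(events: pd.DataFrame, start_day: int,
                   code_map: dict | None = None) -> dict[str, bool]:
    """Seventeen comorbidity flags from the lookback year.

    Events on or after the admission day never contribute.
    """
    code_map = code_map if code_map is not None else load_charlson_map()
    missing = [c for c in CHARLSON_CATEGORIES if c not in code_map]
    if missing:
        raise ConfigurationError(f"comorbidity map missing categories: {missing}")
    sel = _dx_events(events)
    sel = sel[(sel["day"] >= start_day - 365) & (sel["day"] <= start_day - 1)]
    if sel.empty:
        return {c: False for c in CHARLSON_CATEGORIES}
    norm = sel["code"].map(normalize_code)
    return {
        c: bool(norm.str.startswith(tuple(code_map[c])).any())
        for c in CHARLSON_CATEGORIES
    }


def severe_renal(events: pd.DataFrame, start_day: int | None = 0,
                 code_list=SEVERE_RENAL_CODES) -> tuple[bool, str | None]:
    """Severe-renal flag and the first triggering code.

    ``start_day=None`` searches the whole record (the population-wide
    PheWAS usage); otherwise events up to and including ``start_day``
    are searched.
    """
    sel = _dx_events(events)
    if start_day is not None:
        sel = sel[sel["day"] <= start_day]
    if sel.empty:
        return False, None
    norm_set = frozenset(normalize_code(c) for c in code_list)
    hits = sel[sel["code"].map(normalize_code).isin(norm_set)]
    if hits.empty:
        return False, None
    first = hits.sort_values("day", kind="stable").iloc[0]
    return True, str(first["code"])


# -- vectorized whole-cohort versions ---------------------------------------
# Same rules as the per-patient functions above, computed in a few
# table-wide passes; assemble_cohort uses these for speed.

def _dx_with_start(events: pd.DataFrame, start_by_pid: pd.Series) -> pd.DataFrame:
    ev = _dx_events(events)
    ev = ev[ev["patient_id"].isin(start_by_pid.index)].copy()
    ev["_start"] = ev["patient_id"].map(start_by_pid)
    ev["_norm"] = ev["code"].map(normalize_code)
    return ev


def _any_by_patient(ev, mask, pids) -> pd.Series:
    if not mask.any():
        return pd.Series(False, index=pids)
    hit = ev.loc[mask].groupby("patient_id").size() > 0
    return hit.reindex(pids, fill_value=False).astype(bool)


def charlson_flags_table(events: pd.DataFrame, start_by_pid: pd.Series,
                         code_map: dict | None = None) -> pd.DataFrame:
    """17 comorbidity flags for every indexed patient at once."""
    code_map = code_map if code_map is not None else load_charlson_map()
    missing = [c for c in CHARLSON_CATEGORIES if c not in code_map]
    if missing:
        raise ConfigurationError(f"comorbidity map missing categories: {missing}")
    ev = _dx_with_start(events, start_by_pid)
    in_window = (ev["day"] >= ev["_start"] - 365) & (ev["day"] <= ev["_start"] - 1)
    pids = start_by_pid.index
    return pd.DataFrame({
        c: _any_by_patient(ev, in_window & ev["_norm"].str.startswith(
            tuple(code_map[c])), pids)
        for c in CHARLSON_CATEGORIES
    }, index=pids)


def severe_renal_table(events: pd.DataFrame, start_by_pid: pd.Series,
                       code_list=SEVERE_RENAL_CODES) -> pd.Series:
    ev = _dx_with_start(events, start_by_pid)
    norm_set = frozenset(normalize_code(c) for c in code_list)
    mask = (ev["day"] <= ev["_start"]) & ev["_norm"].isin(norm_set)
    return _any_by_patient(ev, mask, start_by_pid.index)


def infection_types_table(events: pd.DataFrame, start_by_pid: pd.Series,
                          codes: CodeConfig | None = None) -> pd.DataFrame:
    codes = codes or CodeConfig.default()
    ev = _dx_with_start(events, start_by_pid)
    in_window = (ev["day"] >= ev["_start"] - 1) & (ev["day"] <= ev["_start"] + 1)
    pids = start_by_pid.index
    return pd.DataFrame({
        t: _any_by_patient(ev, in_window & ev["_norm"].str.startswith(
            tuple(codes.infection_by_type[t])), pids)
        for t in INFECTION_TYPES
    }, index=pids)


def infection_types(events: pd.DataFrame, start_day: int,
                    codes: CodeConfig | None = None) -> set[str]:
    """Multi-label infection-type assignment from window-day codes."""
    codes = codes or CodeConfig.default()
    sel = _dx_events(events)
    sel = sel[(sel["day"] >= start_day - 1) & (sel["day"] <= start_day + 1)]
    if sel.empty:
        return set()
    norm = sel["code"].map(normalize_code)
    return {
        t for t in INFECTION_TYPES
        if norm.str.startswith(tuple(codes.infection_by_type[t])).any()
    }
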