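"""Loading and matching of clinical code lists.

Diagnosis and procedure codes are normalized by stripping dots and
upper-casing before any comparison.  Code lists carry prefix semantics
(a listed family code matches all of its children) except where a rule
explicitly requires exact codes — the severe-renal list and the phecode
map, which do their own exact matching.  Medication lists match by
lower-cased exact name.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import yaml

from .errors import ConfigurationError

#: Code systems accepted on event rows.
CODE_SYSTEMS = ("ICD9CM", "ICD10CM", "CPT", "MED", "KEYWORD")

#: Systems that carry diagnosis/procedure codes.
DX_SYSTEMS = ("ICD9CM", "ICD10CM")


def normalize_code(code) -> str:
    """Strip dots and upper-case a diagnosis/procedure code."""
    return str(code).replace(".", "").strip().upper()


def normalize_codes(codes: Iterable) -> tuple[str, ...]:
    return tuple(normalize_code(c) for c in codes)


def _flatten(group: dict) -> tuple[str, ...]:
    """Flatten a {system: [codes]} mapping into normalized prefixes."""
    out: list[str] = []
    for system, lst in group.items():
        if system == "MED":
            continue
        out.extend(normalize_code(c) for c in lst)
    return tuple(out)


class CodeConfig:
    """Parsed code-list configuration for cohort and phenotyping rules.

    Parameters
    ----------
    raw
        Mapping with the layout of ``data/codes.yaml``.
    """

    REQUIRED = (
        "infection_types", "antibiotics", "admission_exclusions", "covid",
        "shock_codes", "ventilation", "icu", "vasopressors",
        "stress_echo_cpt", "keywords",
    )

    def __init__(self, raw: dict):
        missing = [k for k in self.REQUIRED if k not in raw]
        if missing:
            raise ConfigurationError(f"code config missing sections: {missing}")
        self.raw = raw
        self.infection_by_type = {
            t: _flatten(group) for t, group in raw["infection_types"].items()
        }
        for t, lst in self.infection_by_type.items():
            if not lst:
                raise ConfigurationError(f"empty infection code list for type {t!r}")
        self.infection_codes = tuple(
            c for lst in self.infection_by_type.values() for c in lst
        )
        self.antibiotics = frozenset(str(a).lower() for a in raw["antibiotics"])
        if not self.antibiotics:
            raise ConfigurationError("empty antibiotic list")
        self.exclusion_groups = {
            name: _flatten(group)
            for name, group in raw["admission_exclusions"].items()
        }
        self.covid_codes = _flatten(raw["covid"])
        self.shock_codes = _flatten(raw["shock_codes"])
        self.ventilation_codes = _flatten(raw["ventilation"])
        self.icu_codes = _flatten(raw["icu"])
        self.stress_echo_codes = normalize_codes(raw["stress_echo_cpt"])
        self.keywords = frozenset(str(k).lower() for k in raw["keywords"])
        vaso = raw["vasopressors"]
        self.norepinephrine = frozenset(str(m).lower() for m in vaso["norepinephrine"])
        self.inotropes = frozenset(str(m).lower() for m in vaso["inotrope"])

    @classmethod
    def from_yaml(cls, path) -> "CodeConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CodeConfig":
        text = resources.files("apol1sepsis.data").joinpath("codes.yaml").read_text()
        return cls(yaml.safe_load(text))


def load_charlson_map(path=None) -> dict[str, tuple[str, ...]]:
    """Load the 17-category comorbidity map as normalized prefix lists."""
    if path is None:
        text = resources.files("apol1sepsis.data").joinpath("charlson.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out = {name: _flatten(group) for name, group in raw.items()}
    for name, lst in out.items():
        if not lst:
            raise ConfigurationError(f"empty code list for comorbidity {name!r}")
    return out


#: Canonical order of the 17 comorbidity categories.
CHARLSON_CATEGORIES = (
    "congestive_heart_failure", "chronic_pulmonary_disease",
    "cerebrovascular_disease", "dementia", "diabetes_with_complication",
    "diabetes_without_complication", "hemiplegia_paraplegia", "aids_hiv",
    "malignancy", "myocardial_infarction", "mild_liver_disease",
    "moderate_severe_liver_disease", "peptic_ulcer_disease",
    "peripheral_vascular_disease", "renal_disease", "rheumatic_disease",
    "metastatic_solid_tumor",
)

#: Canonical order of the 10 infection-type categories.
INFECTION_TYPES = (
    "circulatory", "digestive", "genitourinary", "intestinal",
    "musculoskeletal", "neurologic", "other_bacterial", "respiratory",
    "skin", "other",
)
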