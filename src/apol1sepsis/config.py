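"""Simulation configuration.

The defaults encode the study conditions of a cohort of Black adults
hospitalized with infection: combined APOL1 risk-haplotype frequency
0.40 (so the recessive high-risk fraction is 0.40² = 16%), severe
pre-existing renal disease enriched in the high-risk group (35% vs 18%,
giving ~20.5% overall), a sepsis risk acting through severe renal
disease with odds ratio 3.0 and no direct genotype effect, a baseline
sepsis probability of 0.20 (≈25% marginal sepsis), organ-dysfunction
mix and short-term mortality matching the observed proportions among
sepsis cases, and comorbidity / infection-type rates matching the
cohort's descriptive table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

#: The five organ-dysfunction criteria, in canonical order.
CRITERIA = ("circulatory", "respiratory", "renal", "hepatic", "hematologic")

#: Criteria plus the septic-shock billing-code arm.
SEPSIS_FLAGS = CRITERIA + ("shock_code",)

DEFAULT_ORGAN_MIX = {
    # P(flag | sepsis case); multiple flags per case allowed.
    "circulatory": 0.161,
    "respiratory": 0.241,
    "renal": 0.536,
    "hepatic": 0.147,
    "hematologic": 0.181,
    "shock_code": 0.289,
}

DEFAULT_COMORBIDITY_RATES = {
    "congestive_heart_failure": 0.139,
    "chronic_pulmonary_disease": 0.169,
    "cerebrovascular_disease": 0.099,
    "dementia": 0.017,
    "diabetes_with_complication": 0.109,
    "diabetes_without_complication": 0.076,
    "hemiplegia_paraplegia": 0.021,
    "aids_hiv": 0.020,
    "malignancy": 0.166,
    "myocardial_infarction": 0.099,
    "mild_liver_disease": 0.017,
    "moderate_severe_liver_disease": 0.022,
    "peptic_ulcer_disease": 0.010,
    "peripheral_vascular_disease": 0.063,
    "renal_disease": 0.243,
    "rheumatic_disease": 0.033,
    "metastatic_solid_tumor": 0.088,
}

DEFAULT_INFECTION_TYPE_RATES = {
    "circulatory": 0.016,
    "digestive": 0.110,
    "genitourinary": 0.343,
    "intestinal": 0.027,
    "musculoskeletal": 0.049,
    "neurologic": 0.019,
    "other_bacterial": 0.393,
    "respiratory": 0.318,
    "skin": 0.145,
    "other": 0.144,
}


def _is_prob(x) -> bool:
    return 0.0 <= float(x) <= 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-EHR generator.

    Attributes
    ----------
    n_patients
        Number of patients to draw (one index admission each).
    freq_g1, freq_g2
        Risk-haplotype frequencies; G1, G2 and the reference haplotype
        are treated as three mutually exclusive haplotypes, so
        ``freq_g1 + freq_g2 <= 1``.
    p_severe_renal_given_highrisk, p_severe_renal_given_lowrisk
        Probability of pre-existing severe renal disease by risk group.
    or_sepsis_renal
        Odds ratio of sepsis for severe renal disease.
    or_sepsis_genotype_direct
        Direct (non-renal-mediated) genotype odds ratio; 1.0 means the
        genotype acts on sepsis only through renal disease.
    baseline_sepsis_prob
        Sepsis probability for low-risk patients without severe renal
        disease.
    organ_mix
        Per-criterion probabilities (plus the shock-code arm) among
        sepsis cases; criteria are drawn independently and at least one
        is forced so every sepsis case is detectable.
    mortality_given_sepsis
        Probability of in-hospital death or hospice discharge for a
        sepsis case.
    seed
        Master seed; identical configs produce byte-identical output.
    """

    n_patients: int = 2242
    freq_g1: float = 0.27
    freq_g2: float = 0.13
    p_severe_renal_given_highrisk: float = 0.35
    p_severe_renal_given_lowrisk: float = 0.18
    or_sepsis_renal: float = 3.0
    or_sepsis_genotype_direct: float = 1.0
    baseline_sepsis_prob: float = 0.20
    organ_mix: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_MIX))
    comorbidity_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_RATES))
    infection_type_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_INFECTION_TYPE_RATES))
    mortality_given_sepsis: float = 0.149
    seed: int = 0

    # Demographic / plumbing knobs (not part of the causal model).
    female_fraction: float = 0.583
    age_mean: float = 48.0
    age_sd: float = 17.0
    age_min: float = 18.0
    age_max: float = 92.0
    pc_confounding: float = 0.0   # shift of PC1 for high-risk carriers
    mean_extra_los: float = 3.0   # length of stay = 3 + Poisson(mean_extra_los)
    p_late_death: float = 0.03    # death >30 days after discharge (not short-term)
    p_sirs_given_sepsis: float = 0.4
    p_prosthetic_infection_given_renal: float = 0.10
    p_prosthetic_infection_base: float = 0.015
    p_single_sepsis_mention: float = 0.02

    def validate(self) -> "SimulationConfig":
        if int(self.n_patients) != self.n_patients or self.n_patients < 0:
            raise ConfigurationError("n_patients must be a non-negative integer")
        for name in ("freq_g1", "freq_g2"):
            if not _is_prob(getattr(self, name)):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.freq_g1 + self.freq_g2 > 1.0:
            raise ConfigurationError(
                "freq_g1 + freq_g2 must be <= 1 (three exclusive haplotypes)")
        prob_fields = (
            "p_severe_renal_given_highrisk", "p_severe_renal_given_lowrisk",
            "baseline_sepsis_prob", "mortality_given_sepsis",
            "female_fraction", "p_late_death", "p_sirs_given_sepsis",
            "p_prosthetic_infection_given_renal", "p_prosthetic_infection_base",
            "p_single_sepsis_mention",
        )
        for name in prob_fields:
            if not _is_prob(getattr(self, name)):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("or_sepsis_renal", "or_sepsis_genotype_direct"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if set(self.organ_mix) != set(SEPSIS_FLAGS):
            raise ConfigurationError(
                f"organ_mix must have exactly the keys {sorted(SEPSIS_FLAGS)}")
        for k, v in self.organ_mix.items():
            if not _is_prob(v):
                raise ConfigurationError(f"organ_mix[{k!r}] must lie in [0, 1]")
        if sum(self.organ_mix.values()) <= 0:
            raise ConfigurationError("organ_mix must have positive total mass")
        if set(self.comorbidity_rates) != set(DEFAULT_COMORBIDITY_RATES):
            raise ConfigurationError("comorbidity_rates must cover the 17 categories")
        if set(self.infection_type_rates) != set(DEFAULT_INFECTION_TYPE_RATES):
            raise ConfigurationError("infection_type_rates must cover the 10 types")
        for d in (self.comorbidity_rates, self.infection_type_rates):
            for k, v in d.items():
                if not _is_prob(v):
                    raise ConfigurationError(f"rate {k!r} must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)
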