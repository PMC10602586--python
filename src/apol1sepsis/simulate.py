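"""Synthetic longitudinal-EHR generator with known latent ground truth.

The generator draws a latent layer first — genotype haplotypes, severe
pre-existing renal disease, sepsis status from a logistic model, the
set of organ-dysfunction flags for each sepsis case, and short-term
mortality — and then emits coded events and labs that *deterministically*
satisfy the phenotyping rule for every latent flag that is set and
deterministically fail it for every flag that is not.  Running the
cohort and phenotyping stages on noise-free generated data therefore
reproduces the ground truth exactly, which is the fidelity property the
test suite checks.

The latent layer is also exposed directly (:func:`generate_cohort_rows`)
for Monte-Carlo calibration studies that need many replicates: it is the
same statistical model with the event-emission/re-extraction round trip
(separately proven to be the identity) skipped.

Dates are integer day offsets from the admission day (day 0); lab units
are mg/dL for creatinine and total bilirubin and 10³/µL for platelets,
with a units column carried so the pipeline's normalizer is exercised.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io as pio
from .codes import CHARLSON_CATEGORIES, INFECTION_TYPES
from .config import SEPSIS_FLAGS, SimulationConfig

__all__ = [
    "Population", "draw_genotypes", "generate_cohort_rows",
    "generate_population", "write_fixture", "simulate_phewas_population",
]


class Population(NamedTuple):
    """In-memory synthetic population: the four pipeline tables."""

    patients: pd.DataFrame
    events: pd.DataFrame
    labs: pd.DataFrame
    ground_truth: pd.DataFrame


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_genotypes(config: SimulationConfig, rng_state) -> tuple[np.ndarray, np.ndarray]:
    """Draw (g1_dosage, g2_dosage) per patient under Hardy–Weinberg.

    G1, G2 and the reference allele are three mutually exclusive
    haplotypes with frequencies (freq_g1, freq_g2, 1 - freq_g1 - freq_g2);
    two haplotypes are drawn per patient, so the expected high-risk
    fraction (two or more risk alleles) is (freq_g1 + freq_g2)².
    """
    config.validate()
    rng = _rng(rng_state)
    n = int(config.n_patients)
    u = rng.random((n, 2))
    g1 = (u < config.freq_g1).sum(axis=1)
    g2 = ((u >= config.freq_g1) & (u < config.freq_g1 + config.freq_g2)).sum(axis=1)
    return g1.astype(int), g2.astype(int)


def _draw_latent(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent layer shared by both generator entry points."""
    n = int(config.n_patients)
    g1, g2 = draw_genotypes(config, rng)
    high = (g1 == 2) | (g2 == 2) | ((g1 >= 1) & (g2 >= 1))

    p_renal = np.where(high, config.p_severe_renal_given_highrisk,
                       config.p_severe_renal_given_lowrisk)
    renal = rng.random(n) < p_renal

    # logit(P(sepsis)) = logit(baseline) + ln(OR_renal)*renal + ln(OR_direct)*high
    base = config.baseline_sepsis_prob
    logit = (np.log(base / (1 - base))
             + np.log(config.or_sepsis_renal) * renal
             + np.log(config.or_sepsis_genotype_direct) * high)
    sepsis = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # Organ-dysfunction flags: independent Bernoulli draws among sepsis
    # cases; force one flag (categorical on the normalized mix) when a
    # case draws none, so sepsis <=> nonempty flag set.
    mix = np.array([config.organ_mix[k] for k in SEPSIS_FLAGS], dtype=float)
    flags = (rng.random((n, len(SEPSIS_FLAGS))) < mix) & sepsis[:, None]
    none = sepsis & ~flags.any(axis=1)
    if none.any():
        forced = rng.choice(len(SEPSIS_FLAGS), size=int(none.sum()),
                            p=mix / mix.sum())
        flags[np.flatnonzero(none), forced] = True

    mortality = sepsis & (rng.random(n) < config.mortality_given_sepsis)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n),
                  config.age_min, config.age_max)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    pcs = rng.standard_normal((n, 3))
    pcs[:, 0] += config.pc_confounding * high

    comorb = {
        c: rng.random(n) < config.comorbidity_rates[c] for c in CHARLSON_CATEGORIES
    }
    inf_rates = np.array([config.infection_type_rates[t] for t in INFECTION_TYPES])
    inf = rng.random((n, len(INFECTION_TYPES))) < inf_rates
    no_type = ~inf.any(axis=1)
    if no_type.any():
        forced = rng.choice(len(INFECTION_TYPES), size=int(no_type.sum()),
                            p=inf_rates / inf_rates.sum())
        inf[np.flatnonzero(no_type), forced] = True

    discharge = 3 + rng.poisson(config.mean_extra_los, n)

    out = pd.DataFrame({
        "patient_id": np.arange(n, dtype=int),
        "g1_dosage": g1, "g2_dosage": g2, "high_risk": high,
        "severe_renal": renal, "sepsis": sepsis,
        "mortality": mortality,
        "age": age, "sex": sex,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "discharge_day": discharge.astype(int),
    })
    for j, k in enumerate(SEPSIS_FLAGS):
        out[k] = flags[:, j]
    for c in CHARLSON_CATEGORIES:
        out[f"cm_{c}"] = comorb[c]
    for j, t in enumerate(INFECTION_TYPES):
        out[f"inf_{t}"] = inf[:, j]
    return out


def generate_cohort_rows(config: SimulationConfig, rng_state=None) -> pd.DataFrame:
    """Draw analysis-ready cohort rows directly from the latent model.

    Columns match the cohort table built by the full pipeline (exposure
    ``high_risk``, covariates, outcome flags), suitable for feeding the
    association module in replicated simulation studies.
    """
    config.validate()
    rng = _rng(config.seed if rng_state is None else rng_state)
    return _draw_latent(config, rng)


# --------------------------------------------------------------------------
# Event/lab emission.  Values are drawn with safety margins so that the
# phenotyping thresholds are met (or missed) with strict inequalities
# that survive CSV round-tripping.

_INFECTION_EMIT = {  # first (system, code) per infection type, matching codes.yaml
    "circulatory": ("ICD10CM", "I33.0"),
    "digestive": ("ICD10CM", "K81.0"),
    "genitourinary": ("ICD10CM", "N39.0"),
    "intestinal": ("ICD10CM", "A04.9"),
    "musculoskeletal": ("ICD10CM", "M86.9"),
    "neurologic": ("ICD10CM", "G00.9"),
    "other_bacterial": ("ICD10CM", "A49.9"),
    "respiratory": ("ICD10CM", "J18.9"),
    "skin": ("ICD10CM", "L03.90"),
    "other": ("ICD10CM", "T81.4"),
}

_CHARLSON_EMIT = {
    "congestive_heart_failure": ("ICD10CM", "I50.9"),
    "chronic_pulmonary_disease": ("ICD10CM", "J44.9"),
    "cerebrovascular_disease": ("ICD10CM", "I63.9"),
    "dementia": ("ICD10CM", "F03.90"),
    "diabetes_with_complication": ("ICD10CM", "E11.21"),
    "diabetes_without_complication": ("ICD10CM", "E11.9"),
    "hemiplegia_paraplegia": ("ICD10CM", "G81.9"),
    "aids_hiv": ("ICD10CM", "B20"),
    "malignancy": ("ICD10CM", "C34.90"),
    "myocardial_infarction": ("ICD10CM", "I21.9"),
    "mild_liver_disease": ("ICD10CM", "K73.9"),
    "moderate_severe_liver_disease": ("ICD10CM", "I85.00"),
    "peptic_ulcer_disease": ("ICD10CM", "K25.9"),
    "peripheral_vascular_disease": ("ICD10CM", "I73.9"),
    "renal_disease": ("ICD10CM", "N18.3"),
    "rheumatic_disease": ("ICD10CM", "M32.9"),
    "metastatic_solid_tumor": ("ICD10CM", "C78.00"),
}

_SEVERE_RENAL_EMIT = [
    ("ICD10CM", "N18.6"), ("ICD10CM", "N18.5"), ("ICD10CM", "Z99.2"),
    ("ICD9CM", "585.6"), ("ICD10CM", "Z49.31"), ("ICD9CM", "V45.11"),
]

_ANTIBIOTIC_EMIT = ["vancomycin", "cefepime", "ceftriaxone",
                    "piperacillin-tazobactam", "levofloxacin", "meropenem"]


def generate_population(config: SimulationConfig) -> Population:
    """Generate patients, events and labs with a ground-truth sidecar."""
    config.validate()
    rng = _rng(config.seed)
    lat = _draw_latent(config, rng)
    n = len(lat)

    events: list[tuple] = []
    labs: list[tuple] = []

    # --- vectorized pre-draws (fixed order => byte-identical reruns) ---
    abx_idx = rng.integers(0, len(_ANTIBIOTIC_EMIT), n)
    abx_day = rng.integers(-1, 2, n)
    com_day = rng.integers(-365, 0, (n, len(CHARLSON_CATEGORIES)))
    renal_code_idx = rng.integers(0, len(_SEVERE_RENAL_EMIT), n)
    renal_day = rng.integers(-450, -59, n)
    lab_base_day = rng.integers(-300, -19, (n, 3))
    lab_win_day = rng.integers(-1, 2, (n, 3))

    creat_base = rng.uniform(0.6, 1.1, n)
    creat_win = creat_base * np.where(lat["renal"], rng.uniform(2.1, 3.0, n),
                                      rng.uniform(1.0, 1.7, n))
    bili_base = rng.uniform(0.3, 0.8, n)
    bili_win = np.where(lat["hepatic"], 2.05 + rng.uniform(0.0, 1.5, n),
                        bili_base * rng.uniform(1.0, 1.45, n))
    plat_base = rng.uniform(150.0, 350.0, n)  # 10^3/uL
    plat_win = np.where(
        lat["hematologic"],
        np.minimum(99.0, 0.5 * plat_base) * rng.uniform(0.75, 0.98, n),
        plat_base * rng.uniform(0.55, 0.95, n))

    shock_is_icd10 = rng.random(n) < 0.7
    shock_day = rng.integers(-1, 2, n)
    circ_branch_a = rng.random(n) < 0.5          # norepinephrine vs inotrope branch
    dopamine_echo_neg = rng.random(n) < 0.05     # inotrope vetoed by stress echo
    keyword_noise = rng.random(n) < 0.10         # single keyword mention
    vent_only_neg = rng.random(n) < 0.08
    icu_only_neg = rng.random(n) < 0.08
    sirs_draw = rng.random(n) < config.p_sirs_given_sepsis
    prosthetic = rng.random(n) < np.where(
        lat["severe_renal"], config.p_prosthetic_infection_given_renal,
        config.p_prosthetic_infection_base)
    single_mention = rng.random(n) < config.p_single_sepsis_mention
    late_death = rng.random(n) < config.p_late_death
    late_death_day = rng.integers(31, 400, n)
    hospice_draw = rng.random(n) < 0.5

    lat_rows = lat.to_dict("records")
    for i, row in enumerate(lat_rows):
        pid = int(row["patient_id"])
        discharge = int(row["discharge_day"])

        def ev(day, system, code, value=1.0):
            events.append((pid, int(day), system, code, float(value)))

        def lab(day, analyte, value, units):
            labs.append((pid, int(day), analyte, float(value), units))

        # qualifying infection billing codes + peri-admission antibiotic
        for t in INFECTION_TYPES:
            if row[f"inf_{t}"]:
                system, code = _INFECTION_EMIT[t]
                ev(0, system, code)
        ev(abx_day[i], "MED", _ANTIBIOTIC_EMIT[abx_idx[i]])

        # comorbidity codes in the lookback year
        for j, c in enumerate(CHARLSON_CATEGORIES):
            if row[f"cm_{c}"]:
                system, code = _CHARLSON_EMIT[c]
                ev(com_day[i, j], system, code)

        if row["severe_renal"]:
            system, code = _SEVERE_RENAL_EMIT[renal_code_idx[i]]
            ev(renal_day[i], system, code)

        # labs: baseline + peri-admission value for all three analytes
        lab(lab_base_day[i, 0], "creatinine", creat_base[i], "mg/dL")
        lab(lab_win_day[i, 0], "creatinine", creat_win[i], "mg/dL")
        lab(lab_base_day[i, 1], "bilirubin_total", bili_base[i], "mg/dL")
        lab(lab_win_day[i, 1], "bilirubin_total", bili_win[i], "mg/dL")
        lab(lab_base_day[i, 2], "platelets", plat_base[i], "10^3/uL")
        lab(lab_win_day[i, 2], "platelets", plat_win[i], "10^3/uL")

        # circulatory: vasopressor use (branch a: norepinephrine; branch
        # b: inotrope without stress echo plus >=2 keyword mentions)
        if row["circulatory"]:
            if circ_branch_a[i]:
                ev(0, "MED", "norepinephrine")
            else:
                ev(0, "MED", "dobutamine")
                ev(0, "KEYWORD", "sepsis", 2.0)
        elif dopamine_echo_neg[i]:
            ev(0, "MED", "dopamine")
            ev(0, "CPT", "93015")
        if keyword_noise[i]:
            ev(0, "KEYWORD", "infection", 1.0)

        # respiratory: ventilation AND ICU within the stay
        if row["respiratory"]:
            ev(0, "CPT", "94002")
            ev(min(1, discharge), "CPT", "99291")
        elif vent_only_neg[i]:
            ev(0, "CPT", "94002")
        elif icu_only_neg[i]:
            ev(0, "CPT", "99291")

        # septic shock / severe sepsis billing codes (peri-admission),
        # repeated outside the window for the phecode layer
        if row["shock_code"]:
            system, code = (("ICD10CM", "R65.21") if shock_is_icd10[i]
                            else ("ICD9CM", "995.92"))
            ev(shock_day[i], system, code)
            ev(3, system, code)

        # phecode layer: sepsis-related diagnosis codes on distinct days
        # outside the peri-admission window
        if row["sepsis"]:
            ev(3, "ICD10CM", "R65.20")
            ev(5, "ICD10CM", "R65.20")
            ev(3, "ICD10CM", "A41.9")
            ev(5, "ICD10CM", "A41.9")
            if sirs_draw[i]:
                ev(4, "ICD10CM", "R65.10")
                ev(6, "ICD10CM", "R65.10")
        elif single_mention[i]:
            ev(3, "ICD10CM", "R65.20")
        if prosthetic[i]:
            ev(3, "ICD10CM", "T85.79")
            ev(5, "ICD10CM", "T85.79")

    # --- assemble tables ---
    death_day = np.full(n, np.nan)
    disposition = np.full(n, "home", dtype=object)
    mort = lat["mortality"].to_numpy()
    expired = mort & ~hospice_draw
    hospice = mort & hospice_draw
    discharge_arr = lat["discharge_day"].to_numpy()
    death_day[expired] = discharge_arr[expired]
    disposition[expired] = "expired"
    disposition[hospice] = "hospice"
    late = ~mort & late_death
    death_day[late] = discharge_arr[late] + late_death_day[late]

    patients = pd.DataFrame({
        "patient_id": lat["patient_id"],
        "age": lat["age"].round(2),
        "sex": lat["sex"],
        "g1_dosage": pd.array(lat["g1_dosage"], dtype="Int64"),
        "g2_dosage": pd.array(lat["g2_dosage"], dtype="Int64"),
        "pc1": lat["pc1"], "pc2": lat["pc2"], "pc3": lat["pc3"],
        "admission_day": 0,
        "discharge_day": lat["discharge_day"],
        "death_day": pd.array(death_day, dtype="Int64"),
        "disposition": disposition,
        "covid_positive": 0,
    })

    events_df = pd.DataFrame(
        events, columns=["patient_id", "day", "code_system", "code", "value"])
    events_df.insert(0, "event_id", np.arange(len(events_df), dtype=int))
    labs_df = pd.DataFrame(
        labs, columns=["patient_id", "day", "analyte", "value", "units"])
    labs_df.insert(0, "lab_id", np.arange(len(labs_df), dtype=int))

    types_joined = [
        "|".join(t for t in INFECTION_TYPES if row[f"inf_{t}"])
        for row in lat_rows
    ]
    ground_truth = pd.DataFrame({
        "patient_id": lat["patient_id"],
        "true_high_risk": lat["high_risk"],
        "true_severe_renal": lat["severe_renal"],
        "true_sepsis": lat["sepsis"],
        "true_circulatory": lat["circulatory"],
        "true_respiratory": lat["respiratory"],
        "true_renal": lat["renal"],
        "true_hepatic": lat["hepatic"],
        "true_hematologic": lat["hematologic"],
        "true_shock_code": lat["shock_code"],
        "true_mortality": lat["mortality"],
        "true_infection_types": types_joined,
    })
    for df in (events_df, labs_df):  # empty frames come out as object dtype
        df["patient_id"] = df["patient_id"].astype("int64")
        df["day"] = df["day"].astype("int64")
        df["value"] = df["value"].astype("float64")
    return Population(patients=patients, events=events_df, labs=labs_df,
                      ground_truth=ground_truth)


def write_fixture(population: Population, directory) -> list:
    """Write the population to ``directory`` as the four-file CSV set."""
    return pio.write_population(population, directory)


def simulate_phewas_population(n: int, seed, freq_g1=0.27, freq_g2=0.13,
                               p_renal_high=0.35, p_renal_low=0.18,
                               or_phecode_renal=1.0, or_phecode_genotype=1.0,
                               base_prevalence=None, p_single_mention=0.01):
    """Draw a population-wide table plus phecode case/control assignments.

    Used for calibration studies of the restricted PheWAS: per-phecode
    case status is logistic in severe renal disease and (optionally)
    genotype; a small fraction of non-cases carry a single mention and
    are excluded.  Defaults are a null model (both odds ratios 1).

    Returns ``(patients, assignments)`` ready for
    :func:`~apol1sepsis.phewas.run_restricted_phewas`.
    """
    from .phewas import TARGET_PHECODES

    rng = _rng(seed)
    if base_prevalence is None:
        base_prevalence = {"038": 0.06, "081": 0.02, "994.1": 0.02,
                           "994.2": 0.05, "994.21": 0.02}
    cfg = SimulationConfig(n_patients=n, freq_g1=freq_g1, freq_g2=freq_g2)
    g1, g2 = draw_genotypes(cfg, rng)
    high = (g1 == 2) | (g2 == 2) | ((g1 >= 1) & (g2 >= 1))
    renal = rng.random(n) < np.where(high, p_renal_high, p_renal_low)
    patients = pd.DataFrame({
        "patient_id": np.arange(n, dtype=int),
        "high_risk": high,
        "severe_renal": renal,
        "age": np.clip(rng.normal(48, 17, n), 18, 92),
        "sex": np.where(rng.random(n) < 0.583, "F", "M"),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "pc3": rng.standard_normal(n),
    })
    rows = []
    for code in TARGET_PHECODES:
        base = base_prevalence[code]
        logit = (np.log(base / (1 - base))
                 + np.log(or_phecode_renal) * renal
                 + np.log(or_phecode_genotype) * high)
        case = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        single = ~case & (rng.random(n) < p_single_mention)
        status = np.where(case, "case", np.where(single, "excluded", "control"))
        rows.append(pd.DataFrame({
            "patient_id": patients["patient_id"],
            "phecode": code,
            "status": status,
        }))
    return patients, pd.concat(rows, ignore_index=True)
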