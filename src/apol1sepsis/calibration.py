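"""Replicated simulation studies of the pipeline's statistical behavior.

These run the generator's latent layer (the same causal model as the
full event stream; the event encoding is separately verified to round-
trip exactly through the phenotyper) and the association/PheWAS fitting
machinery many times to measure calibration: type-I error under the
null, recovery of a known direct effect, reproduction of the
renal-mediation signature, and the PheWAS multiplicity rate.

All functions derive replicate seeds from a single master seed via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import numpy as np

from .association import ModelSpec, fit_logistic
from .config import SimulationConfig
from .phewas import load_definitions, run_restricted_phewas
from .simulate import generate_cohort_rows, simulate_phewas_population


def _rngs(seed: int, n_reps: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(int(seed)).spawn(n_reps)]


def type_i_error_rate(n_reps: int = 500, n: int = 2_000, seed: int = 0,
                      alpha: float = 0.05) -> float:
    """Empirical size of the base-model Wald test under a global null.

    All effect odds ratios are 1, so rejections of the genotype
    coefficient at level ``alpha`` should occur in ~5% of replicates.
    """
    config = SimulationConfig(n_patients=n, or_sepsis_renal=1.0,
                              or_sepsis_genotype_direct=1.0)
    rejections = 0
    for rng in _rngs(seed, n_reps):
        rows = generate_cohort_rows(config, rng_state=rng)
        res = fit_logistic(rows, ModelSpec(outcome="sepsis"))
        rejections += res.p < alpha
    return rejections / n_reps


def or_recovery_mean(n_reps: int = 200, n: int = 20_000,
                     or_direct: float = 1.5, seed: int = 0) -> float:
    """Mean estimated odds ratio for a purely direct genotype effect.

    The renal pathway is switched off (renal odds ratio 1), so the
    adjusted model's exposure coefficient targets ``or_direct`` exactly.
    """
    config = SimulationConfig(n_patients=n, or_sepsis_renal=1.0,
                              or_sepsis_genotype_direct=or_direct)
    estimates = []
    for rng in _rngs(seed, n_reps):
        rows = generate_cohort_rows(config, rng_state=rng)
        res = fit_logistic(rows, ModelSpec(outcome="sepsis"))
        estimates.append(res.odds_ratio)
    return float(np.mean(estimates))


def mediation_pattern_rate(n_reps: int = 100, n: int = 20_000,
                           seed: int = 0) -> dict:
    """How often the renal-mediation signature is reproduced.

    A replicate succeeds when the base model finds a significantly
    elevated genotype odds ratio (p < 0.05, OR > 1) while the severe-
    renal-exclusion subset's confidence interval covers 1.
    """
    config = SimulationConfig(n_patients=n)  # defaults: renal-mediated
    successes, base_ors, excl_ors = 0, [], []
    for rng in _rngs(seed, n_reps):
        rows = generate_cohort_rows(config, rng_state=rng)
        base = fit_logistic(rows, ModelSpec(outcome="sepsis"))
        excl = fit_logistic(rows, ModelSpec(outcome="sepsis",
                                            subset="exclude_severe_renal"))
        base_ors.append(base.odds_ratio)
        excl_ors.append(excl.odds_ratio)
        successes += (base.p < 0.05 and base.odds_ratio > 1
                      and excl.ci_low <= 1.0 <= excl.ci_high)
    return {
        "rate": successes / n_reps,
        "mean_base_or": float(np.mean(base_ors)),
        "mean_excluded_or": float(np.mean(excl_ors)),
    }


def phewas_null_mean_significant(n_reps: int = 300, n: int = 2_000,
                                 seed: int = 0) -> float:
    """Mean count of Bonferroni-significant phecodes per null replicate.

    Five phecodes at threshold 0.05/5 give an expected count of 0.05
    when the test is well calibrated.
    """
    definitions = load_definitions()
    total = 0
    for k, rng in enumerate(_rngs(seed, n_reps)):
        patients, assignments = simulate_phewas_population(n, rng)
        res = run_restricted_phewas(patients, assignments, definitions)
        total += int(res["significant"].sum())
    return total / n_reps
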