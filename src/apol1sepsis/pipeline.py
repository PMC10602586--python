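"""End-to-end orchestration: simulate -> cohort -> phenotype -> associate -> phewas.

A single master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(master).spawn``, so each stage is
independently reproducible; identical config + seed give identical
output files (the manifest differs only in timestamps).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os

import pandas as pd

from . import __version__
from .association import run_analysis_suite, table_one
from .codes import CodeConfig, load_charlson_map
from .cohort import assemble_cohort
from .config import SimulationConfig
from .phenotype import Thresholds
from .phewas import (assign_case_control, load_definitions,
                     map_icd_to_phecodes, phewas_table_from_population,
                     run_restricted_phewas)
from .simulate import generate_population, write_fixture

logger = logging.getLogger("apol1sepsis")

CONFIG_SCHEMA_VERSION = "1"


def child_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    import numpy as np

    children = np.random.SeedSequence(int(master_seed)).spawn(stage_index + 1)
    return int(children[stage_index].generate_state(1)[0] % (2 ** 31))


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_all(config: SimulationConfig, out_dir, codes: CodeConfig | None = None,
            charlson_map: dict | None = None,
            thresholds: Thresholds = Thresholds()) -> dict:
    """Run every stage, writing all artifacts plus a run manifest.

    Returns the manifest dict.  Any stage error propagates (and aborts
    the downstream stages) after being logged with its stage name.
    """
    os.makedirs(out_dir, exist_ok=True)
    codes = codes or CodeConfig.default()
    charlson_map = charlson_map or load_charlson_map()
    counts: dict[str, int] = {}
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        stage("simulate")
        sim_config = SimulationConfig(**{
            **config.to_dict(), "seed": child_seed(config.seed, 0)}).validate()
        population = generate_population(sim_config)
        data_dir = os.path.join(out_dir, "data")
        write_fixture(population, data_dir)
        counts["patients"] = len(population.patients)
        counts["events"] = len(population.events)
        counts["labs"] = len(population.labs)

        stage("build-cohort")
        cohort, attrition = assemble_cohort(
            population.patients, population.events, population.labs,
            codes, charlson_map, thresholds)
        cohort.to_csv(os.path.join(out_dir, "cohort.csv"), index=False,
                      lineterminator="\n")
        attrition.to_csv(os.path.join(out_dir, "attrition.csv"), index=False,
                         lineterminator="\n")
        counts["cohort_rows"] = len(cohort)
        for _, r in attrition.iterrows():
            if r["n_removed"]:
                logger.info("attrition %s: removed %d", r["step"], r["n_removed"])

        stage("phenotype")
        call_cols = ["patient_id", "sepsis", "shock_code", "circulatory",
                     "respiratory", "renal", "hepatic", "hematologic",
                     "mortality", "evidence"]
        cohort[call_cols].to_csv(os.path.join(out_dir, "sepsis_calls.csv"),
                                 index=False, lineterminator="\n")
        counts["sepsis_cases"] = int(cohort["sepsis"].sum())

        stage("associate")
        results = run_analysis_suite(cohort)
        results.to_csv(os.path.join(out_dir, "results.csv"), index=False,
                       lineterminator="\n")
        t1 = table_one(cohort)
        t1.to_csv(os.path.join(out_dir, "table1.csv"), index=False,
                  lineterminator="\n")
        counts["association_rows"] = len(results)

        stage("phewas")
        definitions = load_definitions()
        pop_table = phewas_table_from_population(
            population.patients, population.events)
        phe_counts = map_icd_to_phecodes(population.events, definitions)
        assignments = assign_case_control(
            phe_counts, pop_table["patient_id"], definitions)
        phewas_all = run_restricted_phewas(pop_table, assignments, definitions)
        phewas_excl = run_restricted_phewas(pop_table, assignments, definitions,
                                            exclude_severe_renal=True)
        phewas = pd.concat([phewas_all, phewas_excl], ignore_index=True)
        phewas.to_csv(os.path.join(out_dir, "phewas.csv"), index=False,
                      lineterminator="\n")
        counts["phewas_rows"] = len(phewas)
    except Exception:
        logger.exception("pipeline stage failed; downstream stages aborted")
        raise

    manifest = {
        "package_version": __version__,
        "config_schema_version": CONFIG_SCHEMA_VERSION,
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "stage_seeds": {"simulate": child_seed(config.seed, 0)},
        "row_counts": counts,
        "started_utc": started,
        "finished_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
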