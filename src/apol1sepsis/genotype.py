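"""APOL1 risk-genotype classification under the recessive model.

G1 is tracked at rs73885319 and G2 at its proxy rs12106505.  Carriage
of any two risk alleles — G1/G1, G2/G2, or the G1/G2 compound
heterozygote — is the high-risk genotype; one or zero risk alleles is
low risk.  G1 and G2 arise on distinct haplotypes, so the allele counts
of a valid genotype sum to at most two; violations are rejected as data
errors rather than capped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default fractional-dosage calling thresholds (t1, t2): dosage < t1
#: calls 0, [t1, t2) calls 1, >= t2 calls 2 (half-open convention).
DEFAULT_CALL_THRESHOLDS = (0.5, 1.5)

#: Post-imputation variant QC thresholds.  These document the filters a
#: genotyping pipeline would have applied upstream; they are applied
#: only to optional per-variant metadata (see :func:`apply_variant_qc`),
#: never computed from raw data here.
IMPUTATION_QC = {
    "min_imputation_r2": 0.3,
    "min_maf": 0.005,
    "max_maf_diff_vs_reference": 0.3,
}


def call_from_dosage(dosage, thresholds=DEFAULT_CALL_THRESHOLDS):
    """Convert fractional imputed dosages in [0, 2] to allele counts.

    Missing input (NaN) yields missing output.  Works on scalars or
    array-likes.
    """
    t1, t2 = thresholds
    if not (0.0 < t1 < t2 < 2.0):
        raise ValidationError("thresholds must satisfy 0 < t1 < t2 < 2")
    arr = np.asarray(dosage, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 2)):
        raise ValidationError("dosage outside [0, 2]")
    calls = np.where(arr < t1, 0, np.where(arr < t2, 1, 2)).astype(float)
    calls[~finite] = np.nan
    if np.isscalar(dosage) or np.ndim(dosage) == 0:
        v = calls.item()
        return None if np.isnan(v) else int(v)
    return calls


def _validate_counts(g1, g2):
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    for name, g in (("g1", g1), ("g2", g2)):
        bad = (g < 0) | (g > 2)
        if np.any(bad):
            raise ValidationError(f"{name} allele counts must be integers in 0..2")
    if np.any(g1 + g2 > 2):
        raise ValidationError(
            "g1 + g2 > 2 violates haplotype exclusivity; "
            "rejecting as a data error rather than capping")
    return g1, g2


def classify_risk(g1_dosage: int, g2_dosage: int) -> str:
    """Classify one called genotype as ``"high"`` or ``"low"``.

    High risk iff G1/G1, G2/G2 or G1/G2; symmetric in the two loci.
    """
    g1, g2 = _validate_counts(g1_dosage, g2_dosage)
    high = (g1 == 2) | (g2 == 2) | ((g1 >= 1) & (g2 >= 1))
    return "high" if bool(high) else "low"


def classify_patients(patients: pd.DataFrame) -> tuple[pd.Series, int]:
    """Vectorized risk classification from a patients table.

    Returns a nullable boolean Series ``high_risk`` aligned to
    ``patients`` (``pd.NA`` where either call is missing) and the count
    of unclassifiable patients.
    """
    g1 = patients["g1_dosage"]
    g2 = patients["g2_dosage"]
    missing = g1.isna() | g2.isna()
    _validate_counts(g1.fillna(0).to_numpy(int), g2.fillna(0).to_numpy(int))
    high = (g1 == 2) | (g2 == 2) | ((g1 >= 1) & (g2 >= 1))
    high = high.astype("boolean")
    high[missing] = pd.NA
    return high, int(missing.sum())


def apply_variant_qc(variant_meta: pd.DataFrame, qc: dict = IMPUTATION_QC) -> pd.Series:
    """Flag variants passing the documented post-imputation filters.

    ``variant_meta`` may carry ``imputation_r2``, ``maf`` and
    ``maf_diff_vs_reference`` columns; absent columns are treated as
    passing (no metadata, no filter).
    """
    ok = pd.Series(True, index=variant_meta.index)
    if "imputation_r2" in variant_meta:
        ok &= variant_meta["imputation_r2"] >= qc["min_imputation_r2"]
    if "maf" in variant_meta:
        ok &= variant_meta["maf"] >= qc["min_maf"]
    if "maf_diff_vs_reference" in variant_meta:
        ok &= variant_meta["maf_diff_vs_reference"].abs() <= qc["max_maf_diff_vs_reference"]
    return ok


def read_apol1_vcf(path, g1_site="rs73885319", g2_site="rs12106505",
                   thresholds=DEFAULT_CALL_THRESHOLDS) -> pd.DataFrame:
    """Read called dosages at the two APOL1 sites from a VCF.

    Sites may be given as rs IDs or as ``"chrom:pos"`` (1-based).  Uses
    the GT field when present, otherwise the DS (imputed dosage) FORMAT
    field thresholded through :func:`call_from_dosage`.  Returns a frame
    with ``sample``, ``g1_dosage``, ``g2_dosage``.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}

    def _matches(variant, site: str) -> bool:
        if ":" in site:
            chrom, pos = site.split(":")
            return variant.CHROM == chrom and variant.POS == int(pos)
        return variant.ID == site

    for variant in vcf:
        for name, site in (("g1", g1_site), ("g2", g2_site)):
            if name in found or not _matches(variant, site):
                continue
            fmts = variant.FORMAT
            if "GT" in fmts:
                counts = np.array(
                    [sum(1 for a in gt[:-1] if a == 1) if -1 not in gt[:-1]
                     else np.nan
                     for gt in variant.genotypes], dtype=float)
            elif "DS" in fmts:
                ds = np.asarray(variant.format("DS"), dtype=float).reshape(-1)
                counts = call_from_dosage(ds, thresholds)
            else:
                raise ValidationError(
                    f"variant {site} carries neither GT nor DS")
            found[name] = counts
    missing_sites = [s for n, s in (("g1", g1_site), ("g2", g2_site))
                     if n not in found]
    if missing_sites:
        raise ValidationError(f"sites not found in VCF: {missing_sites}")
    return pd.DataFrame({
        "sample": samples,
        "g1_dosage": pd.array(found["g1"], dtype="Int64"),
        "g2_dosage": pd.array(found["g2"], dtype="Int64"),
    })
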