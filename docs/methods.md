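# Methods

This note documents the generative model, the phenotyping and cohort
rules, the statistical procedures, and the numerical/design choices the
package makes where the design was genuinely open.

## 1. Synthetic-EHR generator

### Latent layer

Each patient is drawn independently:

1. **Genotype.** Two haplotypes from the trinomial (G1, G2, reference)
   with frequencies (`freq_g1`, `freq_g2`, remainder); defaults
   0.27 / 0.13 approximate African-ancestry frequencies and give a
   combined risk frequency of 0.40, hence a recessive high-risk
   fraction of 0.40² = 16%.  Haplotype exclusivity (g1 + g2 ≤ 2) holds
   by construction.
2. **Severe renal disease.** Bernoulli with probability 0.35 (high
   risk) or 0.18 (low risk); at the default mix this yields ≈ 20.7%
   prevalence overall.
3. **Sepsis.** `logit P = logit(baseline_sepsis_prob) +
   ln(or_sepsis_renal)·renal + ln(or_sepsis_genotype_direct)·high_risk`
   with defaults 0.20, 3.0 and 1.0 — i.e. a purely renal-mediated
   genotype effect and ≈ 25% marginal sepsis prevalence.
4. **Organ-dysfunction flags.** For sepsis cases, the five criteria and
   the shock-code arm are independent Bernoulli draws at the observed
   per-case proportions (circulatory 0.161, respiratory 0.241, renal
   0.536, hepatic 0.147, hematologic 0.181, shock codes 0.289).  These
   rates sum above 1 by design: cases may satisfy several criteria.  A
   case that draws none is assigned one flag from the normalized mix so
   that sepsis ⇔ nonempty flag set; this nudges marginal per-criterion
   rates up slightly and is accepted.
5. **Mortality.** Bernoulli(0.149) among sepsis cases (half in-hospital
   death, half hospice discharge); non-sepsis patients never have
   short-term mortality, though 3% die > 30 days after discharge to
   exercise the mortality window rule.
6. **Demographics.** Age ~ Normal(48, 17) clipped to [18, 92] (the
   generated cohort's median sits near 50 with Q1–Q3 ≈ 33–62); 58.3%
   female; three ancestry PCs standard normal, independent of genotype
   unless the `pc_confounding` knob shifts PC1 for carriers.
   Comorbidity and infection-type rates follow the descriptive-table
   proportions of the emulated cohort.

### Event/lab emission

Dates are integer day offsets from admission (day 0); one admission per
generated patient, with length of stay 3 + Poisson(3) days.  For every
latent flag the generator emits rows that *deterministically* satisfy
the corresponding phenotyping rule, and for every unset flag rows that
deterministically fail it, with safety margins that survive CSV
round-tripping:

- every patient gets a baseline + peri-admission value for all three
  analytes (creatinine/bilirubin in mg/dL, platelets in 10³/µL with the
  units column carried so the normalizer is exercised); case values use
  fold-changes ≥ 2.1 (creatinine), an absolute bilirubin ≥ 2.05 mg/dL at
  ≥ 2× baseline, and platelets ≤ min(99k, 0.5·baseline); control values
  stay strictly inside the thresholds;
- circulatory cases split between a norepinephrine branch and a
  dobutamine + ≥2-keyword-mentions branch; a 5% slice of controls gets
  an inotrope *vetoed* by a stress-echo CPT, and 10% a single keyword
  mention, so the negatives exercise every clause;
- respiratory cases get ventilation + ICU codes; slices of controls get
  one without the other;
- shock-arm cases get one of the four septic-shock codes inside the
  day −1..+1 window;
- a phecode layer places sepsis-related diagnosis codes (R65.20, A41.9,
  R65.10 for a SIRS subset, T85.79 for prosthetic-device infections
  enriched in severe-renal patients) on distinct days *outside* the
  peri-admission window, so the PheWAS has realistic case/exclusion
  structure without perturbing the sepsis phenotyper;
- severe-renal patients get one code from the 15-code Stage 4/5
  CKD/ESRD list at a random day in [−450, −60]; comorbidity codes land
  in the look-back year.

Running the cohort and phenotyping stages on this noise-free output
reproduces the latent truth with sensitivity = specificity = 1.0, which
the acceptance suite asserts exactly.  The latent layer is also exposed
directly (`generate_cohort_rows`) and is used for the replicated
calibration studies; because the event encoding round-trips exactly,
this is the same statistical model with the (deterministic) emission
and re-extraction skipped.

**What the generator does not emulate:** coding noise and
misclassification, free-text notes (keyword counts are pre-aggregated),
multiple admissions per patient (the data model supports them; the
generator emits one), correlated comorbidities, realistic ICD
co-occurrence structure, genotype–PC confounding (off by default), or
imperfect phenotyping (the published algorithm's sensitivity against
chart review is far below 1).  Passing tests therefore certify the
*rules and inference machinery*, not performance on real EHR data.

## 2. Phenotyping and cohort rules

- Organ dysfunction is evaluated on days {−1, 0, +1}; lab baselines on
  [admission − 365, discharge] — deliberately including post-window
  days, as the baseline definition states.
- All fold comparisons are inclusive (≥); dosage calling uses the
  half-open convention (< 0.5 → 0, [0.5, 1.5) → 1, ≥ 1.5 → 2).
- Keyword mentions are summed across the three keywords and days
  −1..+1.  The published circulatory clause is ambiguous about whether
  the ≥ 2-mentions requirement also gates the norepinephrine branch; the
  default applies it to the inotrope branch only, with a documented
  switch (`keyword_rule_on_norepinephrine`).
- The ICU requirement is evaluated over the whole index stay by
  default (`icu_window="stay"`), switchable to the peri-admission
  window.
- A missing lab baseline makes that criterion false (dysfunction cannot
  be asserted without a reference) and is logged as not evaluable.
- Cohort inclusion: age ≥ 18 at day 0, an infection billing code and an
  antibiotic administration within days −1..+1; exclusions (in order):
  cardiac surgery, cardiogenic shock, organ transplantation codes, no
  peri-admission creatinine *and* bilirubin *and* platelet value (the
  weaker "all absent" reading, configurable), COVID-19 flag or U07.1.
  First qualifying admission per patient; ties broken by longest stay,
  then lowest admission id.  Patients with a missing genotype call are
  dropped with a logged attrition count; attrition counts conserve n by
  construction and by test.
- Severe renal disease: exact match (after dot-stripping) on the
  15-code list over the whole record up to the admission day — chronic
  states carry no look-back limit, unlike the Charlson year.  Charlson
  categories use prefix matching on [−365, −1].  The two renal flags are
  computed independently.
- The per-admission phenotyper (`call_sepsis`) is the reference
  implementation; the table-level vectorized path is asserted
  row-equivalent to it and to an independent nested-loop oracle in the
  tests.

## 3. Statistical procedures

- Logistic models are maximum-likelihood fits (statsmodels IRLS
  / Newton).  Odds ratio, 95% CI and p are all Wald-based
  (exp(β ± 1.96·SE), two-sided normal p), so printed triples are
  mutually consistent; profile-likelihood intervals are deliberately
  not used.  Separation and non-convergence are flagged on the result
  (extreme-coefficient heuristic |β| > 15 or SE > 50), never silent.
- Covariates: age at admission, sex, PCs 1–3 (the first three columns
  of the PC matrix).  Complete-case analysis with the missing count
  reported.  The three renal strategies are: additional adjustment,
  exclusion, restriction — adjustment and subsetting are never combined.
- Descriptive table: categorical rows as n (%) with Yates
  continuity-corrected chi-square (the correction reproduces the
  reference arithmetic on the renal-comorbidity 2×2: χ² ≈ 40.91,
  p ≈ 1.6 × 10⁻¹⁰, where the uncorrected statistic does not); age as
  median (Q1–Q3) displayed with a two-sample t-test p — both the display
  and the test are as specified, the mismatch left unresolved on
  purpose.  p-values display with two decimals at or above 0.001,
  scientific notation below.  Degenerate margins skip the test with a
  note.
- PheWAS: distinct-day occurrence counting (≥ 2 → case, exactly 1 →
  excluded, any related-range code → excluded for non-cases, otherwise
  control; the case rule takes precedence).  Bonferroni threshold
  0.05/5 = 0.01 with a strict less-than comparison.  The severe-renal
  sensitivity pass excludes patients with any listed renal code in the
  record.  The bundled phecode map is a five-phecode miniature with
  family-range exclusions (038.x, 081.x, 994.x); a full external map in
  the same YAML layout can be substituted.

## 4. Calibration studies and problem sizes

The `calibration` module re-runs the latent generator plus the fitting
machinery with replicate seeds spawned from one master seed
(`numpy.random.SeedSequence.spawn`; all derived seeds < 2³¹):

- **Type-I error:** 500 null replicates at n = 2,000; the base-model
  Wald test should reject at ≈ 5%.
- **Mediation signature:** 100 replicates at n = 20,000 of the default
  renal-mediated model; success = base model significantly above 1 and
  exclusion-subset CI covering 1; the observed rate is ≈ 92–96%.
- **Direct-effect recovery:** 200 replicates at n = 20,000 with the
  renal pathway off and a direct OR of 1.5; because no other covariate
  affects the outcome, the conditional estimand equals 1.5 and the mean
  estimate lands within a few percent.
- **PheWAS multiplicity:** 300 null replicates at n = 2,000; with five
  tests at threshold 0.01 the expected significant count is 0.05 per
  replicate.  The test bound allows three binomial standard errors of
  the Monte-Carlo estimate above 0.05, the same 3-SE convention used
  for the Hardy–Weinberg calibration check — a point mass at the
  expectation cannot be asserted from a finite simulation.

These sizes were chosen to give each check decisive power while keeping
the whole suite and the acceptance script fast on a single CPU.

## 5. Known limitations

- Code lists are compact plausible defaults, not a validated
  institutional terminology; they are data (YAML), and the severe-renal
  list is the only list matched exactly as printed.
- The generator's one-admission-per-patient default leaves the
  multi-admission tie-break logic exercised only by constructed
  fixtures.
- Post-imputation genotype QC (r² < 0.3, MAF < 0.5%, |ΔMAF| > 0.3
  vs reference) is carried as documented constants applied to optional
  per-variant metadata; no imputation is performed.
- PheWAS denominators here are the generated admission population;
  a real deployment would run it on the full genotyped population,
  which the API supports (it takes any patients table).
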