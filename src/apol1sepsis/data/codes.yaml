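# Clinical code lists consumed by the cohort and phenotyping stages.
#
# These lists are editable configuration data, not code.  The published
# source for the cohort definition keeps its exact ICD/CPT/antibiotic
# appendix in a supplement that is not distributed with this package, so
# the entries below are plausible, clearly-labelled defaults covering
# each rule family (bacterial-infection billing codes by organ system,
# systemic antibiotics, admission exclusions, ventilation/ICU markers,
# vasopressors, stress-echocardiography CPTs, septic-shock codes).
# Diagnosis/procedure codes are matched on dot-stripped upper-cased
# prefixes; medications are matched by lower-cased exact name.

infection_types:
  circulatory:
    ICD10CM: ["I33.0"]
    ICD9CM: ["421.0"]
  digestive:
    ICD10CM: ["K81.0", "K65.0"]
    ICD9CM: ["575.0", "567.2"]
  genitourinary:
    ICD10CM: ["N39.0", "N10"]
    ICD9CM: ["599.0", "590.1"]
  intestinal:
    ICD10CM: ["A04.9"]
    ICD9CM: ["008.5"]
  musculoskeletal:
    ICD10CM: ["M86.9", "M00.9"]
    ICD9CM: ["730.2"]
  neurologic:
    ICD10CM: ["G00.9"]
    ICD9CM: ["320.9"]
  other_bacterial:
    ICD10CM: ["A49.9", "A48.8"]
    ICD9CM: ["041.9"]
  respiratory:
    ICD10CM: ["J18.9", "J15.9"]
    ICD9CM: ["486"]
  skin:
    ICD10CM: ["L03.90", "L02.91"]
    ICD9CM: ["682.9"]
  other:
    ICD10CM: ["T81.4"]
    ICD9CM: ["998.59"]

antibiotics:
  - vancomycin
  - cefepime
  - ceftriaxone
  - piperacillin-tazobactam
  - levofloxacin
  - metronidazole
  - meropenem
  - ampicillin-sulbactam

admission_exclusions:
  cardiac_surgery:
    CPT: ["33510", "33533"]
    ICD9CM: ["36.1"]
  cardiogenic_shock:
    ICD9CM: ["785.51"]
    ICD10CM: ["R57.0"]
  organ_transplant:
    ICD10CM: ["Z94"]
    ICD9CM: ["V42"]
    CPT: ["50360"]

covid:
  ICD10CM: ["U07.1"]

# Septic shock / severe sepsis billing codes: these four codes are the
# code-only arm of the sepsis definition.
shock_codes:
  ICD9CM: ["995.92", "785.52"]
  ICD10CM: ["R65.20", "R65.21"]

ventilation:
  CPT: ["94002", "94003", "94660"]
  ICD9CM: ["96.70", "96.71", "96.72"]
  ICD10CM: ["5A1935Z", "5A1945Z", "5A1955Z"]

icu:
  CPT: ["99291", "99292"]

vasopressors:
  norepinephrine: ["norepinephrine", "levophed"]
  inotrope: ["dobutamine", "dopamine"]

stress_echo_cpt: ["78452", "93015", "93016", "93017", "93018", "93351"]

keywords: ["infection", "sepsis", "septic"]
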