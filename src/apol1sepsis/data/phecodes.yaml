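# Miniature phecode map covering the five prespecified sepsis-related
# phenotypes and their related-code exclusion ranges.
#
# ICD lists are exact codes (matched after dot-stripping and
# upper-casing), mirroring how full phecode maps are distributed.  A
# code may roll up to both a child phecode and its parent (e.g. the
# septic-shock ICD-10 code counts toward 994.21 and 994.2).
# `exclude_range` entries are [low, high] intervals on numeric phecode
# values; controls carrying any code mapping into the range are
# excluded.  A complete external phecode map in the same layout can be
# passed in place of this file.

phecodes:
  "038":
    label: "Septicemia"
    icd9: ["038", "038.0", "038.10", "038.11", "038.12", "038.19",
           "038.2", "038.3", "038.40", "038.41", "038.42", "038.43",
           "038.44", "038.49", "038.8", "038.9"]
    icd10: ["A40", "A40.0", "A40.1", "A40.3", "A40.8", "A40.9",
            "A41", "A41.01", "A41.02", "A41.1", "A41.2", "A41.3",
            "A41.4", "A41.50", "A41.51", "A41.59", "A41.81", "A41.89",
            "A41.9"]
    exclude_range: [[38.0, 38.99]]
  "081":
    label: "Infection of internal prosthetic device"
    icd9: ["996.6", "996.60", "996.61", "996.62", "996.66", "996.67",
           "996.69"]
    icd10: ["T82.6", "T82.7", "T83.5", "T83.6", "T84.5", "T84.6",
            "T84.7", "T85.7", "T85.71", "T85.79"]
    exclude_range: [[81.0, 81.99]]
  "994.1":
    label: "Systemic inflammatory response syndrome (SIRS)"
    icd9: ["995.90", "995.93", "995.94"]
    icd10: ["R65.1", "R65.10", "R65.11"]
    exclude_range: [[994.0, 994.99]]
  "994.2":
    label: "Sepsis"
    icd9: ["995.91", "995.92"]
    icd10: ["R65.2", "R65.20", "R65.21"]
    exclude_range: [[994.0, 994.99]]
  "994.21":
    label: "Septic shock"
    icd9: ["785.52"]
    icd10: ["R65.21"]
    exclude_range: [[994.0, 994.99]]
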