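# Charlson/Deyo comorbidity categories -> diagnosis-code prefix lists.
#
# Seventeen categories, matched on dot-stripped upper-cased code
# prefixes within the year before the index admission.  The lists
# follow the familiar Deyo/Quan-style groupings but are deliberately
# compact defaults shipped as editable configuration data; swap in a
# complete institutional map by passing an alternative YAML file.

congestive_heart_failure:
  ICD9CM: ["428"]
  ICD10CM: ["I50"]
chronic_pulmonary_disease:
  ICD9CM: ["490", "491", "492", "493", "494", "495", "496"]
  ICD10CM: ["J40", "J41", "J42", "J43", "J44", "J45", "J47", "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67"]
cerebrovascular_disease:
  ICD9CM: ["430", "431", "432", "433", "434", "435", "436", "437", "438"]
  ICD10CM: ["I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I69", "G45"]
dementia:
  ICD9CM: ["290"]
  ICD10CM: ["F00", "F01", "F02", "F03", "G30"]
diabetes_with_complication:
  ICD9CM: ["250.4", "250.5", "250.6", "250.7"]
  ICD10CM: ["E10.2", "E10.3", "E10.4", "E10.5", "E11.2", "E11.3", "E11.4", "E11.5"]
diabetes_without_complication:
  ICD9CM: ["250.0", "250.1", "250.2", "250.3"]
  ICD10CM: ["E10.9", "E11.9", "E10.0", "E11.0", "E10.1", "E11.1"]
hemiplegia_paraplegia:
  ICD9CM: ["342", "343"]
  ICD10CM: ["G81", "G82"]
aids_hiv:
  ICD9CM: ["042"]
  ICD10CM: ["B20", "B21", "B22", "B24"]
malignancy:
  ICD9CM: ["153", "162", "174", "185", "200", "201", "202", "203", "204", "205"]
  ICD10CM: ["C18", "C34", "C50", "C61", "C81", "C82", "C83", "C85", "C90", "C91", "C92"]
myocardial_infarction:
  ICD9CM: ["410", "412"]
  ICD10CM: ["I21", "I22", "I25.2"]
mild_liver_disease:
  ICD9CM: ["571.2", "571.5", "571.6"]
  ICD10CM: ["K70.3", "K73", "K74", "B18"]
moderate_severe_liver_disease:
  ICD9CM: ["572.2", "572.3", "572.4"]
  ICD10CM: ["K70.4", "K72.1", "K76.6", "K76.7", "I85"]
peptic_ulcer_disease:
  ICD9CM: ["531", "532", "533", "534"]
  ICD10CM: ["K25", "K26", "K27", "K28"]
peripheral_vascular_disease:
  ICD9CM: ["441", "443.9"]
  ICD10CM: ["I70", "I71", "I73.9"]
renal_disease:
  ICD9CM: ["582", "583", "585", "586", "588", "V56"]
  ICD10CM: ["N03", "N18", "N19", "Z49", "Z99.2"]
rheumatic_disease:
  ICD9CM: ["710.0", "714"]
  ICD10CM: ["M05", "M06", "M32", "M33", "M34"]
metastatic_solid_tumor:
  ICD9CM: ["196", "197", "198", "199"]
  ICD10CM: ["C77", "C78", "C79", "C80"]
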