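# Cancer-modified Charlson comorbidity categories, version 1.
#
# The 17 classic categories MINUS the two malignancy categories (any
# malignancy; metastatic solid tumor), which are excluded so that the index
# measures non-cancer comorbidity in a cancer cohort. Code lists are
# Deyo-style ICD-9 families with ICD-10 companions, documented best-effort
# and editable. "supersedes" encodes the hierarchy: when both members of a
# pair are present only the more severe one scores.
version: 1
weights:
  myocardial_infarction: 1
  congestive_heart_failure: 1
  peripheral_vascular_disease: 1
  cerebrovascular_disease: 1
  dementia: 1
  chronic_pulmonary_disease: 1
  rheumatologic_disease: 1
  peptic_ulcer_disease: 1
  mild_liver_disease: 1
  diabetes: 1
  diabetes_with_complications: 2
  hemiplegia: 2
  renal_disease: 2
  severe_liver_disease: 3
  aids: 6
supersedes:
  severe_liver_disease: mild_liver_disease
  diabetes_with_complications: diabetes
categories:
  myocardial_infarction:
    - {system: ICD9Dx, prefixes: ["410", "412"]}
    - {system: ICD10Dx, prefixes: ["I21", "I22", "I252"]}
  congestive_heart_failure:
    - {system: ICD9Dx, prefixes: ["428"]}
    - {system: ICD10Dx, prefixes: ["I50"]}
  peripheral_vascular_disease:
    - {system: ICD9Dx, prefixes: ["440", "441", "4439"]}
    - {system: ICD10Dx, prefixes: ["I70", "I71"]}
  cerebrovascular_disease:
    - {system: ICD9Dx,
       prefixes: ["430", "431", "432", "433", "434", "435", "436", "438"]}
    - {system: ICD10Dx, prefixes: ["I60", "I61", "I62", "I63", "I64", "G45"]}
  dementia:
    - {system: ICD9Dx, prefixes: ["290"]}
    - {system: ICD10Dx, prefixes: ["F00", "F01", "F02", "F03", "G30"]}
  chronic_pulmonary_disease:
    - {system: ICD9Dx,
       prefixes: ["490", "491", "492", "493", "494", "495", "496"]}
    - {system: ICD10Dx,
       prefixes: ["J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47"]}
  rheumatologic_disease:
    - {system: ICD9Dx, prefixes: ["7100", "7101", "7104", "714", "725"]}
    - {system: ICD10Dx, prefixes: ["M05", "M06", "M32", "M34"]}
  peptic_ulcer_disease:
    - {system: ICD9Dx, prefixes: ["531", "532", "533", "534"]}
    - {system: ICD10Dx, prefixes: ["K25", "K26", "K27", "K28"]}
  mild_liver_disease:
    - {system: ICD9Dx, prefixes: ["5712", "5714", "5715", "5716"]}
    - {system: ICD10Dx, prefixes: ["K70", "K73", "K74"]}
  diabetes:
    - {system: ICD9Dx, prefixes: ["2500", "2501", "2502", "2503"]}
    - {system: ICD10Dx, exact: ["E109", "E119"]}
  diabetes_with_complications:
    - {system: ICD9Dx,
       prefixes: ["2504", "2505", "2506", "2507", "2508", "2509"]}
    - {system: ICD10Dx, prefixes: ["E102", "E112", "E113", "E114", "E115"]}
  hemiplegia:
    - {system: ICD9Dx, prefixes: ["342", "3441"]}
    - {system: ICD10Dx, prefixes: ["G81", "G82"]}
  renal_disease:
    - {system: ICD9Dx, prefixes: ["582", "583", "585", "586", "5880"]}
    - {system: ICD10Dx, prefixes: ["N18", "N19"]}
  severe_liver_disease:
    - {system: ICD9Dx,
       prefixes: ["5722", "5723", "5724", "5728", "4560", "4561", "4562"]}
    - {system: ICD10Dx, prefixes: ["K721", "K729", "K766", "I85"]}
  aids:
    - {system: ICD9Dx, prefixes: ["042"]}
    - {system: ICD10Dx, prefixes: ["B20", "B21", "B22", "B24"]}
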