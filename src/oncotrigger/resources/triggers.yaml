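# Default trigger codebook, version 1.
#
# 16 oncology-specific triggers. Each trigger lists one or more clauses; a
# candidate event requires >=1 matching code from EVERY clause within
# co_occurrence_days. Each clause is a list of code sets (match any one).
# ICD-10 companions to the ICD-9 algorithms ship here as explicit editable
# entries; the two systems never cross-match implicitly.
#
# exposures / lookback_days / persistence_days encode the trigger-exposure
# linkage: a candidate becomes an event only when it falls within
# (exposure_date, exposure_date + lookback_days] of an eligible
# cancer-directed treatment, and repeated codes within persistence_days are
# collapsed into one event.
version: 1
new_use_lookback_days: 90
triggers:
  pressure_ulcer:
    display_name: Pressure ulcer
    category: general_care
    clauses:
      - - {system: ICD9Dx, prefixes: ["707"], exclusions: ["70721", "70722"]}
        - {system: ICD10Dx, prefixes: ["L89"]}
    exposures: [surgery]
    lookback_days: 90
    persistence_days: 30
  return_to_or:
    display_name: Return to the operating room or interventional radiology within 30 d of surgery
    category: general_care
    # Best-effort reoperation / interventional-radiology code list
    # (reopening of recent laparotomy site, reclosure of postop disruption,
    # IR abscess drainage, embolization, thrombectomy); configurable.
    clauses:
      - - {system: ICD9Proc, exact: ["5412", "5461"]}
        - {system: CPT, exact: ["49406", "37244", "36870"]}
    constraints: [post_index_surgery_30d]
    exposures: [surgery]
    lookback_days: 30
    persistence_days: 30
  hypoxemia:
    display_name: Low oximetry results (SaO2 < 88%)
    category: vital_signs
    clauses:
      - - {system: ICD9Dx, exact: ["79902"]}
        - {system: ICD10Dx, exact: ["R0902"]}
    exposures: [chemotherapy, radiation]
    lookback_days: 30
    persistence_days: 30
  neutropenic_fever:
    display_name: Neutropenic fever (fever > 38.2 C with neutropenia)
    category: vital_signs
    clauses:
      - - {system: ICD9Dx, exact: ["7806"]}
        - {system: ICD10Dx, exact: ["R509"]}
      - - {system: ICD9Dx, prefixes: ["288"]}
        - {system: ICD10Dx, prefixes: ["D70"]}
    co_occurrence_days: 7
    exposures: [chemotherapy]
    lookback_days: 30
    persistence_days: 30
  blood_transfusion:
    display_name: Blood transfusion
    category: orders
    clauses:
      - - {system: ICD9Dx, exact: ["V582"]}
        - {system: ICD10Dx, exact: ["Z5131"]}
        - {system: CPT, exact: ["36430"]}
    exposures: [chemotherapy, surgery, radiation]
    lookback_days: 30
    persistence_days: 30
  contact_precautions:
    display_name: Contact precautions / order for isolation
    category: orders
    clauses:
      - - {system: ICD9Dx, prefixes: ["V07"]}
        - {system: ICD10Dx, prefixes: ["Z29"]}
    exposures: [chemotherapy, surgery]
    lookback_days: 30
    persistence_days: 30
  nasogastric_tube:
    display_name: Nasogastric tube (not in operating room)
    category: orders
    clauses:
      - - {system: ICD9Proc, exact: ["9607"]}
        - {system: CPT, exact: ["43753"]}
    constraints: [not_same_day_as_surgery]
    exposures: [surgery]
    lookback_days: 30
    persistence_days: 30
  chest_ct_noncontrast:
    display_name: Non-contrast chest CT after radiation
    category: orders
    clauses:
      - - {system: CPT, exact: ["71250"]}
    exposures: [radiation]
    lookback_days: 180
    persistence_days: 30
  percutaneous_drain:
    display_name: Percutaneous drain placement
    category: orders
    clauses:
      - - {system: ICD9Proc, exact: ["5491"]}
        - {system: CPT, exact: ["32557"]}
    exposures: [surgery]
    lookback_days: 30
    persistence_days: 30
  abnormal_bicarbonate:
    display_name: Abnormal serum bicarbonate (< 18, > 36 mEq/L)
    category: laboratories
    clauses:
      - - {system: ICD9Dx, exact: ["7906", "2762", "2763"]}
        - {system: ICD10Dx, exact: ["R791", "E872", "E873"]}
    exposures: [chemotherapy]
    lookback_days: 30
    persistence_days: 30
  abnormal_potassium:
    display_name: Abnormal serum potassium (> 6, < 2.5 mEq/L)
    category: laboratories
    clauses:
      - - {system: ICD9Dx, exact: ["2768", "2767"]}
        - {system: ICD10Dx, exact: ["E876", "E875"]}
    exposures: [chemotherapy]
    lookback_days: 30
    persistence_days: 30
  c_difficile:
    display_name: Clostridium difficile toxin positive
    category: laboratories
    clauses:
      - - {system: ICD9Dx, exact: ["00845"]}
        - {system: ICD10Dx, exact: ["A047"]}
    exposures: [chemotherapy]
    lookback_days: 30
    persistence_days: 30
  elevated_creatinine:
    display_name: Elevated creatinine (acute kidney injury, not present on admission)
    category: laboratories
    clauses:
      - - {system: ICD9Dx, exact: ["5849"]}
        - {system: ICD10Dx, exact: ["N179"]}
    constraints: [requires_not_poa]
    exposures: [chemotherapy]
    lookback_days: 30
    persistence_days: 30
  bacteremia:
    display_name: Positive blood culture without contaminant
    category: laboratories
    # Diagnosis codes are sufficient; blood-culture CPTs (a culture drawn is
    # not a positive culture) ship as supporting evidence only, with a
    # config switch to require dx + culture CPT.
    clauses:
      - - {system: ICD9Dx, exact: ["7907"]}
        - {system: ICD10Dx, exact: ["R7881"]}
    supporting:
      - {system: CPT, exact: ["87040", "87103"]}
    exposures: [chemotherapy, surgery]
    lookback_days: 30
    persistence_days: 30
  anticoagulation:
    display_name: Initiation of therapeutic anticoagulation
    category: medication_related
    clauses:
      - - {system: DRUG,
           exact: [warfarin, enoxaparin, apixaban, rivaroxaban, dabigatran,
                   fondaparinux, edoxaban]}
    constraints: [new_use_only]
    exposures: [chemotherapy, surgery]
    lookback_days: 30
    persistence_days: 30
  nephrology_consult:
    display_name: Nephrology consultation
    category: consultations
    clauses:
      - - {system: CPT,
           exact: ["99241", "99242", "99243", "99244", "99245",
                   "99251", "99252", "99253", "99254", "99255"]}
    constraints: ["requires_specialty:nephrologist"]
    exposures: [chemotherapy, surgery]
    lookback_days: 30
    persistence_days: 30
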