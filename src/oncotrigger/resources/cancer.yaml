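# Cancer diagnosis, recurrence-marker and secondary-malignancy code sets,
# version 1.
#
# Diagnosis families for the four study cancers (ICD-9 and ICD-10 prefix
# form). The recurrence set (personal-history-of-malignancy markers) is a
# documented placeholder for the validated recurrence algorithms the tool
# approximates; the secondary-malignancy set backs the metastatic-status
# classifier.
version: 1
cancers:
  breast:
    - {system: ICD9Dx, prefixes: ["174", "175"]}
    - {system: ICD10Dx, prefixes: ["C50"]}
  colorectal:
    - {system: ICD9Dx, prefixes: ["153", "154"]}
    - {system: ICD10Dx, prefixes: ["C18", "C19", "C20"]}
  lung:
    - {system: ICD9Dx, prefixes: ["162"]}
    - {system: ICD10Dx, prefixes: ["C34"]}
  prostate:
    - {system: ICD9Dx, prefixes: ["185"]}
    - {system: ICD10Dx, prefixes: ["C61"]}
recurrence:
  - {system: ICD9Dx, prefixes: ["V10"]}
  - {system: ICD10Dx, prefixes: ["Z85"]}
secondary_malignancy:
  - {system: ICD9Dx, prefixes: ["196", "197", "198"]}
  - {system: ICD10Dx, prefixes: ["C77", "C78", "C79"]}
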