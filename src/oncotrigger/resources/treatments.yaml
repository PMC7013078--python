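# Cancer-directed treatment code sets, version 1.
#
# Best-effort editable lists: site surgeries (lumpectomy/mastectomy,
# colectomy, lobectomy, prostatectomy), the CPT radiation-oncology family,
# chemotherapy administration CPTs plus infusional / oral oncolytic and
# hormonal agents by generic name. The three sets must be disjoint within
# each coding system; overlaps are fatal at load.
version: 1
treatments:
  surgery:
    - {system: CPT,
       exact: ["19301", "19303", "44140", "44204", "32480", "32663",
               "55840", "55866"]}
    - {system: ICD9Proc, prefixes: ["854", "457", "324", "605"]}
  radiation:
    - {system: CPT, prefixes: ["77"]}
  chemotherapy:
    - {system: CPT, prefixes: ["964"]}
    - {system: DRUG,
       exact: [fluorouracil, capecitabine, oxaliplatin, carboplatin,
               cisplatin, paclitaxel, docetaxel, doxorubicin,
               cyclophosphamide, gemcitabine, pemetrexed, etoposide,
               irinotecan, erlotinib, trastuzumab,
               tamoxifen, anastrozole, letrozole, exemestane,
               leuprolide, bicalutamide, abiraterone, enzalutamide]}
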