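# Methods

This note documents the detection model, the cohort and covariate
definitions, the synthetic-data generator, the numerical and design
choices that were genuinely open, and the limits of what the test suite
demonstrates.

## The trigger model

A *trigger* is a coded clinical signal — a diagnosis, procedure, order or
medication start — that flags a *possible* treatment-related adverse
event; it is not itself confirmation of harm. The tool ships 16
oncology-specific triggers in six groups (general care, vital signs,
orders, laboratories, medication-related, consultations), each defined by:

* **Clauses.** One or more groups of code sets; a candidate event requires
  at least one matching code from *every* clause within the trigger's
  co-occurrence window. Fifteen triggers are single-clause; neutropenic
  fever is the conjunction of a fever code (ICD-9 780.6 / ICD-10 R50.9)
  and a neutropenia code (288.x / D70.x) within 7 days. A fever-only
  trigger is deliberately not shipped: the conjunction is the published
  algorithm, and a lone fever code is nonspecific. Code sets are
  exact-or-prefix with explicit exclusions (pressure ulcer is 707.x
  excluding 707.21/707.22), always qualified by coding system — ICD-9 and
  ICD-10 never cross-match by string; the ICD-10 companions ship as
  explicit editable codebook entries.
* **Constraints.** Trigger-specific filters beyond codes: acute kidney
  injury (584.9/N17.9) must be *not present on admission* (a claim whose
  matching diagnosis carries `poa=no`; when the extract carries no POA
  flags at all, the trigger cannot fire and one warning is logged —
  conservative by design); the nephrology consult requires an E&M visit
  CPT (99241–45, 99251–55) billed by a nephrologist (case-insensitive
  specialty match); anticoagulation must be a *new* start, i.e. no fill of
  any listed anticoagulant in the prior 90 days; nasogastric-tube
  placement on the same day as a surgery exposure is suppressed (claims
  carry no room-level location, so same-day placement is presumed
  intra-operative); the reoperation trigger keeps only events 1–30 days
  after the index surgery.
* **Exposure rule.** The eligible treatment types (subset of surgery /
  radiation / chemotherapy), a lookback *L* and a persistence window *P*.
  The linkage window is **half-open**: an event on day *t* links to an
  exposure on day *e* iff `e < t ≤ e + L`. Same-day codes never link —
  this keeps an index surgery's own claims from firing the surgical
  triggers, which would otherwise dominate the counts. Every chemotherapy
  administration or fill opens its own window (courses are multi-dose);
  the event links to the *latest* qualifying exposure, with same-day ties
  broken chemotherapy > surgery > radiation. Defaults are L = P = 30 days
  for all triggers except pressure ulcer (L = 90; pressure injury evolves
  slowly) and non-contrast chest CT after radiation (L = 180; radiation
  pneumonitis imaging lags the exposure). Only the neutropenic-fever
  30/30 pairing is fixed by published precedent; the rest of the
  trigger-exposure map is a declared, fully overridable default.
* **Dedup.** Within (patient, trigger), a greedy left-to-right pass drops
  any event within *P* days after the last retained event: repeated codes
  for one clinical episode count once. Greedy-from-the-left retains the
  minimal chain deterministically.

Events are confined to `[index_date, followup_end]` and to days the
patient is enrolled (claims cannot be observed while disenrolled). A
single claim matching two triggers fires each independently — one
clinical adverse event may legitimately produce several triggers, and the
tool counts triggers, not adjudicated harms.

Blood-culture CPTs (87040/87103) are recorded as supporting evidence for
the bacteremia trigger but are not sufficient on their own — a culture
*drawn* is not a culture *positive*; a config switch can require dx+CPT.
The reoperation code list is a small documented best-effort set of
reoperation/interventional-radiology codes, configurable; it approximates
rather than reproduces the published reoperation claims algorithm.
Laboratory thresholds printed alongside the lab triggers (bicarbonate
< 18 / > 36 mEq/L, potassium > 6 / < 2.5 mEq/L, creatinine > 1 mg/dL and
50 % above baseline) are not computable from claims, which carry codes,
not values; the codes operationalize them, and ICD-9 790.6 in the
bicarbonate set is a known nonspecific-laboratory-abnormality code kept
deliberately, as a documented specificity limitation.

## Cohort

Incident cohort of adults with a first breast, colorectal, lung or
prostate cancer diagnosis between 2008-01-01 and 2014-12-31 who initiate
cancer-directed treatment in that window. Specifics:

* **Washout**: any cancer diagnosis or treatment code in the 1095 days
  before first diagnosis excludes the patient (`washout_dx` /
  `washout_treatment`), as does any recurrence-marker code (personal-
  history-of-malignancy V10.x / Z85.x — a documented placeholder for
  validated recurrence algorithms) at any time before index
  (`recurrence`). The washout is a rolling patient-level lookback rather
  than fixed calendar years so the tool generalizes beyond one accrual
  window.
* **Index date** = first eligible treatment on/after first diagnosis;
  follow-up ends at `min(index + 365, death, end of enrollment
  coverage)`. Events during enrollment gaps inside follow-up are
  suppressed but follow-up is not truncated at the first gap.
* Exclusions: male breast cancer, age < 18 at index, no treatment, and
  (defensively) follow-up ending before index. When several reasons
  apply the fixed precedence washout_dx > washout_treatment > recurrence
  > male_breast > no_treatment > under_18 makes the partition
  deterministic.
* Patients qualifying for two cancer types get the earliest diagnosis;
  same-day ties break lung > colorectal > breast > prostate (descending
  acuity) and are logged.
* No minimum continuous-enrollment requirement is imposed by default.

## Covariates

* **Charlson index, cancer-modified**: the 15 non-malignancy categories
  (the any-malignancy and metastatic-solid-tumor categories are excluded
  so the index measures non-cancer comorbidity in a cancer cohort),
  classic weights 1/2/3/6, hierarchy pairs (severe liver > mild liver,
  complicated > uncomplicated diabetes), 365-day pre-index lookback.
  Code lists are Deyo-style families shipped as editable YAML; excluding
  the malignancy categories makes the index provably invariant to adding
  cancer diagnoses (tested).
* **Metastatic status**: ≥ 1 secondary-malignancy code (196–198 /
  C77–C79) in `[first_dx, index + 60]`. Late progression does not
  reclassify baseline status, since metastatic disease is used as a
  baseline stratifier. A stricter two-claims-≥30-days-apart mode is
  provided.
* **Utilization**: unplanned admissions = inpatient stays admitted
  during follow-up not on a surgery date (claims extracts often lack
  admission-type flags; the surgery-date rule is the stated
  approximation); inpatient days = discharge − admission (min 1 per
  stay), clipped to follow-up.

## Tabulation and inference

Per-trigger prevalence uses the **exposed denominator** (patients with
≥ 1 eligible-type exposure during follow-up); the any-trigger row uses
the full stratum. Percentages display at one decimal; exact fractions
are retained in machine output. Cells with 0 < numerator < 11 are
masked as "< 11 events" in released tables (0 and ≥ 11 are shown).
Group comparisons use Pearson chi-square without continuity correction
for categorical covariates and the two-sample Wilcoxon rank-sum
(normal approximation, tie-corrected) for continuous ones; p-values are
unadjusted, and no multiplicity correction is applied.

The PPV-weighted burden reports `E[AEs] = Σ_k n_k · PPV_k` and
`E[preventable] = Σ_k n_k · PPV_k^prev`. Trigger-specific chart-review
PPVs are not public, so the shipped default applies the overall
chart-review values 0.48 (AE) and 0.18 (preventable) uniformly; a
per-trigger table can be supplied in config and should be for any
substantive use. The percent-of-patients-affected figure uses the
independence approximation `1 − Π_k (1 − PPV_k)^{n_k}` per patient,
averaged over the cohort — events within a patient are treated as
independent draws, which overstates the percentage when one clinical
event fires several triggers.

## Synthetic data generator

The generator emulates the *structure* of a commercial-claims extract for
this design, with ground-truth labels for everything the pipeline infers:

* Cohort composition follows the published cohort table: case mix
  breast/colorectal/lung/prostate ≈ 0.385/0.162/0.159/0.294, per-type
  metastatic fractions 0.216/0.356/0.588/0.114, per-type treatment-
  modality mixes, per-type age means (≈ 59.5–67.1, SD 11.5).
* Treatment schedules: surgery as a single index-day procedure;
  radiation as five weekly fractions; chemotherapy as 4–8 cycles 21 days
  apart (70 % administration CPTs, 30 % pharmacy fills); multimodality
  as surgery + chemotherapy from day 28, half adding radiation from day
  120. Claims stop at death.
* **Planted triggers**: per trigger, each exposed patient receives one
  in-window event with probability 0.10 (uniform offset in
  `(e, e + L]`), emitted with its constraints satisfied (POA = no,
  nephrologist specialty, no prior anticoagulant fill), at most one per
  (patient, trigger). **Decoys** place the same codes strictly outside
  every window — before index, or beyond the last eligible exposure's
  lookback — at rate 0.05; additional hard negatives are lone fever
  codes without neutropenia, POA = yes kidney-injury claims, and consult
  E&M codes billed by the wrong specialty. Because generator and engine
  share one window convention, a correct engine scores sensitivity 1.0
  with zero false positives — the central acceptance property.
* Ineligible patients are generated too (5 % washout violators with a
  pre-accrual cancer claim, 2 % recurrence-marked, 2 % under-18, 1 % of
  breast patients male, 3 % untreated), each single-fault so the
  exclusion partition is checkable exactly. 8 % of eligible patients die
  30–400 days after index; 5 % have a 30-day enrollment gap placed after
  their last treatment; comorbidity noise plants each Charlson category
  pre-index at rate 0.08; filler hypertension codes pad inpatient stays.
  All noise vocabularies are disjoint from trigger, cancer and treatment
  code sets, so chance false positives cannot arise from noise.
* Dates are integer days rendered as ISO dates from a 2008-01-01 epoch;
  a single seeded NumPy generator drives every draw, so bundles are
  byte-reproducible given the seed.

What the generator does **not** emulate: realistic billing intensity or
cost fields, code co-occurrence correlations beyond what window logic
needs, regionally varying coding practice, ICD-9→ICD-10 switchover by
calendar date (systems are mixed at a fixed 30 % ICD-10 rate to exercise
both vocabularies), or miscoded/ambiguous events. Passing tests
therefore demonstrate that the *logic* — windows, constraints, cohort
rules, tabulation — is correct, not that the shipped code lists achieve
any particular sensitivity or PPV on real claims; that requires chart
review against a real warehouse.

## Numerical and degenerate-input choices

* All window arithmetic is integer days on calendar dates; claims carry
  no finer resolution.
* Multi-clause event date = earliest clause date of a co-occurring set;
  the clause window is symmetric (all pairwise gaps ≤ the co-occurrence
  window). All tie-breaks (exposure linkage, same-day diagnosis
  priority, dedup order) are total orders, so identical inputs give
  byte-identical outputs.
* Zero denominators yield flagged undefined-rate cells rather than
  errors; an empty cohort produces empty tables and a warning; rows with
  unparseable dates or malformed code cells are rejected individually
  and logged, while missing required columns abort the run.
* Degenerate comparison tables (empty row/column or a single outcome
  group) are skipped with a note instead of raising.

## Problem sizes in the shipped checks

The test suite and acceptance script run on synthetic bundles of 500
patients (engine-vs-oracle equivalence, across five seeds), 2,000
patients (planted-rate recovery and the acceptance pipeline) and 5,000
patients (composition-recovery checks) — sizes at which the brute-force
quadratic oracle remains tractable while binomial checks retain power.
Worked-example tabulations run on patient sets of up to ~323 k rows
built directly from published cohort counts.

## Known limitations

* Code lists for treatments, reoperation and recurrence markers are
  documented best-effort defaults, not validated lists; fidelity on real
  data requires substituting validated sets via the codebook override.
* The uniform 0.48/0.18 PPV default is a placeholder for the per-trigger
  chart-review values any real burden estimate needs.
* POA-dependent logic silently (single warning) disables the
  kidney-injury trigger on extracts without POA flags.
* Attribution is temporal, not causal: a linked trigger means a
  compatible exposure existed in the window, nothing more. Severity
  grading, causality adjudication and chart-review validation are out of
  scope.
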