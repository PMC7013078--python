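"""Patient-level baseline covariates.

Three ingredients the prevalence analysis stratifies and compares on:

* a cancer-modified Charlson comorbidity index (the two malignancy
  categories are excluded, so adding cancer diagnoses never changes the
  score) over a 365-day pre-index lookback, with the classic 1/2/3/6
  weights and severity hierarchies;
* baseline metastatic status from secondary-malignancy diagnosis codes in
  a window around treatment start ([first diagnosis, index + 60 days] by
  default; a stricter two-claims-30-days-apart mode is available);
* utilization within follow-up: unplanned admissions (inpatient stays not
  admitted on a surgery date) and inpatient days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources as importlib_resources

import yaml

from .claims_model import ClaimsBundle, MedicalClaim
from .codebook import CodeSet, match_any
from .cohort_builder import CohortRecord
from .treatment_classifier import ExposureEvent

DEFAULT_CHARLSON_LOOKBACK_DAYS = 365
DEFAULT_METASTATIC_POST_INDEX_DAYS = 60


@dataclass(frozen=True)
class RiskProfile:
    patient_id: str
    charlson: int
    metastatic: bool
    unplanned_admissions: int
    inpatient_days: int


@dataclass(frozen=True)
class CharlsonMap:
    """Comorbidity categories as code sets, weights and hierarchy."""

    categories: dict[str, tuple[CodeSet, ...]]
    weights: dict[str, int]
    supersedes: dict[str, str]  # severe -> mild: mild ignored if severe present


def load_charlson_map(path=None) -> CharlsonMap:
    if path is None:
        ref = importlib_resources.files("oncotrigger.resources").joinpath(
            "charlson.yaml"
        )
        with ref.open("r") as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    categories = {}
    for name, entries in doc["categories"].items():
        categories[name] = tuple(
            CodeSet(
                system=e["system"],
                exact=frozenset(e.get("exact", ())),
                prefixes=frozenset(e.get("prefixes", ())),
                exclusions=frozenset(e.get("exclusions", ())),
            )
            for e in entries
        )
    return CharlsonMap(
        categories=categories,
        weights={k: int(v) for k, v in doc["weights"].items()},
        supersedes=dict(doc.get("supersedes", {})),
    )


def charlson_modified(
    claims: list[MedicalClaim],
    index_date: dt.date,
    charlson_map: CharlsonMap | None = None,
    lookback_days: int = DEFAULT_CHARLSON_LOOKBACK_DAYS,
) -> int:
    """Weighted count of comorbidity categories present pre-index.

    A category scores when >=1 qualifying diagnosis falls in
    ``[index - lookback_days, index)``; hierarchical pairs score only the
    more severe member.
    """
    cmap = charlson_map or load_charlson_map()
    start = index_date - dt.timedelta(days=lookback_days)
    present: set[str] = set()
    for claim in claims:
        if not (start <= claim.service_date < index_date):
            continue
        for dx in claim.dx_codes:
            for name, codesets in cmap.categories.items():
                if name not in present and match_any(dx.code, dx.system, codesets):
                    present.add(name)
    for severe, mild in cmap.supersedes.items():
        if severe in present:
            present.discard(mild)
    return sum(cmap.weights[name] for name in present)


def classify_metastatic(
    claims: list[MedicalClaim],
    first_dx_date: dt.date,
    index_date: dt.date,
    secondary_malignancy: tuple[CodeSet, ...],
    post_index_days: int = DEFAULT_METASTATIC_POST_INDEX_DAYS,
    require_confirmation: bool = False,
) -> bool:
    """Baseline metastatic status from secondary-malignancy codes.

    True when a qualifying diagnosis falls in
    ``[first_dx_date, index + post_index_days]``; late progression does not
    reclassify baseline status. ``require_confirmation`` demands two
    qualifying claims >= 30 days apart (stricter mode).
    """
    end = index_date + dt.timedelta(days=post_index_days)
    hits: list[dt.date] = []
    for claim in claims:
        if not (first_dx_date <= claim.service_date <= end):
            continue
        for dx in claim.dx_codes:
            if match_any(dx.code, dx.system, secondary_malignancy):
                hits.append(claim.service_date)
                break
    if not hits:
        return False
    if not require_confirmation:
        return True
    return max(hits) - min(hits) >= dt.timedelta(days=30)


def _stays(claims: list[MedicalClaim]) -> list[tuple[dt.date, dt.date]]:
    """Distinct inpatient stays as (admit, discharge) pairs."""
    seen = set()
    out = []
    for claim in claims:
        if claim.setting != "inpatient":
            continue
        admit = claim.admit_date or claim.service_date
        discharge = claim.discharge_date or claim.service_date
        key = (claim.patient_id, admit, discharge)
        if key not in seen:
            seen.add(key)
            out.append((admit, discharge))
    return out


def utilization(
    claims: list[MedicalClaim],
    cohort_record: CohortRecord,
    exposures: list[ExposureEvent] = (),
) -> tuple[int, int]:
    """(unplanned admissions, inpatient days) within follow-up.

    A stay counts when its admission date falls in follow-up and does not
    coincide with a surgery exposure (treated as planned). Inpatient days
    are discharge minus admission (minimum 1), clipped to follow-up.
    """
    if cohort_record.index_date is None or cohort_record.followup_end is None:
        return (0, 0)
    start, end = cohort_record.index_date, cohort_record.followup_end
    surgery_dates = {
        e.date for e in exposures if e.exposure_type == "surgery"
    }
    admissions = 0
    days = 0
    for admit, discharge in _stays(claims):
        if not (start <= admit <= end):
            continue
        if admit in surgery_dates:
            continue
        admissions += 1
        clipped = min(discharge, end)
        days += max((clipped - admit).days, 1)
    return admissions, days


def build_risk_profiles(
    bundle: ClaimsBundle,
    cohort: list[CohortRecord],
    exposures: list[ExposureEvent],
    secondary_malignancy: tuple[CodeSet, ...],
    charlson_map: CharlsonMap | None = None,
) -> dict[str, RiskProfile]:
    """Risk profile for every included cohort member."""
    cmap = charlson_map or load_charlson_map()
    claims_by_patient: dict[str, list[MedicalClaim]] = {}
    for claim in bundle.medical:
        claims_by_patient.setdefault(claim.patient_id, []).append(claim)
    expo_by_patient: dict[str, list[ExposureEvent]] = {}
    for ev in exposures:
        expo_by_patient.setdefault(ev.patient_id, []).append(ev)

    profiles: dict[str, RiskProfile] = {}
    for rec in cohort:
        if not rec.included:
            continue
        claims = claims_by_patient.get(rec.patient_id, [])
        pexpo = expo_by_patient.get(rec.patient_id, [])
        admissions, days = utilization(claims, rec, pexpo)
        profiles[rec.patient_id] = RiskProfile(
            patient_id=rec.patient_id,
            charlson=charlson_modified(claims, rec.index_date, cmap),
            metastatic=classify_metastatic(
                claims, rec.first_dx_date, rec.index_date, secondary_malignancy
            ),
            unplanned_admissions=admissions,
            inpatient_days=days,
        )
    return profiles
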