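"""Incident-cancer cohort selection with washout and index-date assignment.

The cohort comprises adults with a first breast, colorectal, lung or
prostate cancer diagnosis inside the accrual window who initiate
cancer-directed treatment; follow-up runs one year from the first treatment
(the index date), censored at death or disenrollment. A claim-free washout
lookback before first diagnosis guards against prevalent or recurrent
disease.

Exclusion reasons are assigned with a fixed precedence so that every
candidate is partitioned deterministically:
``washout_dx`` > ``washout_treatment`` > ``recurrence`` > ``male_breast`` >
``no_treatment`` > ``under_18`` > ``no_followup``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

from .claims_model import ClaimsBundle
from .codebook import Codebook, match_any
from .treatment_classifier import ExposureEvent

logger = logging.getLogger(__name__)

DEFAULT_ACCRUAL_START = dt.date(2008, 1, 1)
DEFAULT_ACCRUAL_END = dt.date(2014, 12, 31)
DEFAULT_WASHOUT_DAYS = 1095
FOLLOWUP_DAYS = 365

# Same-day tie on first diagnosis across cancer types: descending acuity.
_TYPE_PRIORITY = {"lung": 0, "colorectal": 1, "breast": 2, "prostate": 3}


@dataclass
class CohortRecord:
    patient_id: str
    cancer_type: str
    first_dx_date: dt.date
    index_date: dt.date | None = None
    followup_end: dt.date | None = None
    age_at_index: int | None = None
    exclusion_reason: str | None = None

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


def find_first_cancer_dx(
    bundle: ClaimsBundle,
    codebook: Codebook,
    accrual_start: dt.date = DEFAULT_ACCRUAL_START,
    accrual_end: dt.date = DEFAULT_ACCRUAL_END,
) -> dict[str, tuple[str, dt.date]]:
    """Earliest qualifying cancer diagnosis per patient within accrual.

    Patients qualifying for two cancer types get the type of the earliest
    diagnosis; a same-day tie is broken by fixed priority
    (lung > colorectal > breast > prostate) and logged.
    """
    best: dict[str, tuple[dt.date, int, str]] = {}
    multi: set[str] = set()
    for claim in bundle.medical:
        if not (accrual_start <= claim.service_date <= accrual_end):
            continue
        for dx in claim.dx_codes:
            for ctype, codesets in codebook.cancers.items():
                if not match_any(dx.code, dx.system, codesets):
                    continue
                key = (claim.service_date, _TYPE_PRIORITY[ctype], ctype)
                prev = best.get(claim.patient_id)
                if prev is None:
                    best[claim.patient_id] = key
                else:
                    if prev[2] != ctype:
                        multi.add(claim.patient_id)
                    if key < prev:
                        best[claim.patient_id] = key
    for pid in multi:
        logger.info(
            "patient %s qualifies for multiple cancer types; assigned %s",
            pid,
            best[pid][2],
        )
    return {pid: (ctype, date) for pid, (date, _, ctype) in best.items()}


def _any_cancer_codesets(codebook: Codebook):
    return [cs for codesets in codebook.cancers.values() for cs in codesets]


def apply_washout(
    candidates: dict[str, tuple[str, dt.date]],
    bundle: ClaimsBundle,
    codebook: Codebook,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
) -> tuple[dict[str, tuple[str, dt.date]], dict[str, str]]:
    """Drop candidates with prior cancer claims or recurrence markers.

    A patient is excluded when any cancer diagnosis or cancer-directed
    treatment code falls in the open interval
    ``(first_dx - washout_days, first_dx)``, or when any recurrence-marker
    code appears at any time before first diagnosis. Returns the retained
    candidates and a reason map for the excluded.
    """
    cancer_sets = _any_cancer_codesets(codebook)
    excluded: dict[str, str] = {}

    for claim in bundle.medical:
        pid = claim.patient_id
        if pid not in candidates or pid in excluded:
            continue
        ctype, first_dx = candidates[pid]
        in_washout = (
            first_dx - dt.timedelta(days=washout_days)
            < claim.service_date
            < first_dx
        )
        for dx in claim.dx_codes:
            if in_washout and match_any(dx.code, dx.system, cancer_sets):
                excluded[pid] = "washout_dx"
                break
            if claim.service_date < first_dx and match_any(
                dx.code, dx.system, codebook.recurrence
            ):
                excluded[pid] = "recurrence"
                break
        if pid in excluded:
            continue
        if in_washout:
            for proc in claim.proc_codes:
                for codesets in codebook.treatments.values():
                    if match_any(proc.code, proc.system, codesets):
                        excluded[pid] = "washout_treatment"
                        break
                if pid in excluded:
                    break

    for fill in bundle.pharmacy:
        pid = fill.patient_id
        if pid not in candidates or pid in excluded:
            continue
        _, first_dx = candidates[pid]
        if first_dx - dt.timedelta(days=washout_days) < fill.fill_date < first_dx:
            if match_any(fill.generic_name, "DRUG", codebook.treatments["chemotherapy"]):
                excluded[pid] = "washout_treatment"

    # When several claims justify different reasons the first in claim order
    # wins (claim order is stable, so assignment is deterministic); within a
    # claim, dx reasons are preferred over treatment reasons.
    kept = {pid: v for pid, v in candidates.items() if pid not in excluded}
    return kept, excluded


def assign_index_and_followup(
    candidates: dict[str, tuple[str, dt.date]],
    exposures: list[ExposureEvent],
    bundle: ClaimsBundle,
    accrual_end: dt.date = DEFAULT_ACCRUAL_END,
    followup_days: int = FOLLOWUP_DAYS,
) -> list[CohortRecord]:
    """Set index date (first eligible treatment) and censored follow-up end.

    ``followup_end = min(index + followup_days, death_date, last day of
    enrollment coverage)``. Patients with no treatment on/after first
    diagnosis inside the accrual window are excluded (``no_treatment``);
    demographic exclusions (male breast, under 18 at index) are applied
    here because age-at-index needs the index date.
    """
    by_patient: dict[str, list[ExposureEvent]] = {}
    for ev in exposures:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    records: list[CohortRecord] = []
    for pid, (ctype, first_dx) in sorted(candidates.items()):
        rec = CohortRecord(patient_id=pid, cancer_type=ctype, first_dx_date=first_dx)
        patient = bundle.patients.get(pid)
        if patient is not None and ctype == "breast" and patient.sex == "male":
            rec.exclusion_reason = "male_breast"
            records.append(rec)
            continue
        eligible = [
            ev
            for ev in by_patient.get(pid, ())
            if first_dx <= ev.date <= accrual_end
        ]
        if not eligible:
            rec.exclusion_reason = "no_treatment"
            records.append(rec)
            continue
        index_date = min(ev.date for ev in eligible)
        rec.index_date = index_date
        if patient is not None:
            rec.age_at_index = index_date.year - patient.birth_year
            if rec.age_at_index < 18:
                rec.exclusion_reason = "under_18"
                records.append(rec)
                continue
        end = index_date + dt.timedelta(days=followup_days)
        if patient is not None and patient.death_date is not None:
            end = min(end, patient.death_date)
        spans = bundle.enrollment.get(pid)
        if spans:
            end = min(end, max(s.end_date for s in spans))
        if end < index_date:
            rec.exclusion_reason = "no_followup"
            records.append(rec)
            continue
        rec.followup_end = end
        records.append(rec)
    return records


def build_cohort(
    bundle: ClaimsBundle,
    exposures: list[ExposureEvent],
    codebook: Codebook,
    accrual_start: dt.date = DEFAULT_ACCRUAL_START,
    accrual_end: dt.date = DEFAULT_ACCRUAL_END,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    followup_days: int = FOLLOWUP_DAYS,
) -> list[CohortRecord]:
    """Full cohort construction; returns included and excluded records.

    Included records plus excluded-with-reason records partition the
    candidate set (everyone with a qualifying in-window first diagnosis).
    """
    candidates = find_first_cancer_dx(bundle, codebook, accrual_start, accrual_end)
    kept, washed = apply_washout(candidates, bundle, codebook, washout_days)
    records = assign_index_and_followup(
        kept, exposures, bundle, accrual_end, followup_days
    )
    for pid, reason in sorted(washed.items()):
        ctype, first_dx = candidates[pid]
        records.append(
            CohortRecord(
                patient_id=pid,
                cancer_type=ctype,
                first_dx_date=first_dx,
                exclusion_reason=reason,
            )
        )
    records.sort(key=lambda r: r.patient_id)
    return records
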