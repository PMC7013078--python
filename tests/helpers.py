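"""Small builders for hand-constructed claims fixtures."""

import datetime as dt
import itertools

from oncotrigger import (
    ClaimsBundle,
    DxCode,
    EnrollmentSpan,
    MedicalClaim,
    PatientRecord,
    PharmacyClaim,
    ProcCode,
)

_ids = itertools.count(1)


def patient(pid, birth_year=1950, sex="female", **kw):
    return PatientRecord(patient_id=pid, birth_year=birth_year, sex=sex, **kw)


def dx_claim(pid, date, code, system="ICD9Dx", poa="unknown", setting="outpatient",
             specialty=None, admit=None, discharge=None):
    return MedicalClaim(
        claim_id=f"M{next(_ids)}",
        patient_id=pid,
        service_date=date,
        setting=setting,
        dx_codes=(DxCode(code, system, poa),),
        admit_date=admit,
        discharge_date=discharge,
        provider_specialty=specialty,
    )


def proc_claim(pid, date, code, system="CPT", specialty=None):
    return MedicalClaim(
        claim_id=f"M{next(_ids)}",
        patient_id=pid,
        service_date=date,
        setting="outpatient",
        proc_codes=(ProcCode(code, system),),
        provider_specialty=specialty,
    )


def fill(pid, date, drug):
    return PharmacyClaim(
        claim_id=f"P{next(_ids)}", patient_id=pid, fill_date=date, generic_name=drug
    )


def bundle_of(patients=(), medical=(), pharmacy=(), enrollment=None):
    """Bundle with wide default enrollment (2000-2020) for every patient."""
    b = ClaimsBundle()
    for p in patients:
        b.patients[p.patient_id] = p
    b.medical = list(medical)
    b.pharmacy = list(pharmacy)
    pids = {p.patient_id for p in patients}
    pids |= {c.patient_id for c in b.medical} | {c.patient_id for c in b.pharmacy}
    if enrollment is None:
        for pid in pids:
            b.enrollment[pid] = [
                EnrollmentSpan(pid, dt.date(2000, 1, 1), dt.date(2020, 12, 31))
            ]
    else:
        for span in enrollment:
            b.enrollment.setdefault(span.patient_id, []).append(span)
    return b
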