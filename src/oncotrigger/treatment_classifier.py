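"""Classify claims into dated cancer-directed treatment exposures.

Exposure events (surgery, radiation, chemotherapy — the latter including
oral oncolytic and hormonal fills) anchor the temporal windows in which a
trigger may be attributed to treatment. Every chemotherapy administration or
fill opens its own window; courses are multi-dose.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .claims_model import ClaimsBundle, DRUG
from .codebook import Codebook, match_any

TREATMENT_CATEGORIES = (
    "chemotherapy_only",
    "radiation_only",
    "surgery_only",
    "multimodality",
)


@dataclass(frozen=True, order=True)
class ExposureEvent:
    patient_id: str
    date: dt.date
    exposure_type: str  # surgery | radiation | chemotherapy
    source: str  # medical_claim | pharmacy_claim
    code: str


def classify_exposures(bundle: ClaimsBundle, codebook: Codebook) -> list[ExposureEvent]:
    """One exposure event per qualifying (patient, type, date, code).

    Duplicates with the same patient, type and date are collapsed (the
    first-seen code is kept); output is sorted.
    """
    seen: dict[tuple[str, str, dt.date], ExposureEvent] = {}
    for claim in bundle.medical:
        for proc in claim.proc_codes:
            for etype, codesets in codebook.treatments.items():
                if match_any(proc.code, proc.system, codesets):
                    key = (claim.patient_id, etype, claim.service_date)
                    seen.setdefault(
                        key,
                        ExposureEvent(
                            patient_id=claim.patient_id,
                            date=claim.service_date,
                            exposure_type=etype,
                            source="medical_claim",
                            code=proc.code,
                        ),
                    )
    for fill in bundle.pharmacy:
        for etype, codesets in codebook.treatments.items():
            if match_any(fill.generic_name, DRUG, codesets):
                key = (fill.patient_id, etype, fill.fill_date)
                seen.setdefault(
                    key,
                    ExposureEvent(
                        patient_id=fill.patient_id,
                        date=fill.fill_date,
                        exposure_type=etype,
                        source="pharmacy_claim",
                        code=fill.generic_name,
                    ),
                )
    return sorted(seen.values())


def treatment_category(events) -> str:
    """Patient-level modality category from the exposures within follow-up.

    The single modality present, else ``multimodality``; zero events is a
    cohort-invariant violation and raises.
    """
    modalities = {e.exposure_type for e in events}
    if not modalities:
        raise ValueError("treatment_category requires at least one exposure event")
    if len(modalities) > 1:
        return "multimodality"
    return f"{next(iter(modalities))}_only"
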