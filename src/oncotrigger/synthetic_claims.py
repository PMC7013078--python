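"""Synthetic claims bundles with known ground truth.

The generator emulates the structure of a commercial-claims extract for an
incident-cancer cohort: multi-year per-patient claim sequences carrying
cancer diagnoses, cancer-directed treatment codes, comorbidity noise, and —
crucially — trigger codes planted at controlled temporal offsets from
treatment. Planted events land strictly inside an eligible exposure window,
``(exposure, exposure + lookback]``; decoys land strictly outside every
window (before the index date, or beyond the last eligible exposure's
lookback), so a correct engine detects every planted event and none of the
decoys. The generator draws codes only from the shipped codebook, so
detection and generation share one vocabulary.

Cohort composition targets the study population the tool was built for:
the four-cancer case mix, per-type metastatic fractions and treatment-
modality mixes follow the published cohort table; ineligible patients
(washout violators, recurrence-marked, under-18, male breast, untreated)
are emitted too, so the exclusion paths are exercised, not assumed.

Dates use a synthetic epoch: integer days rendered as ISO dates from
2008-01-01, mirroring the tool's default accrual window.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import (
    ClaimsBundle,
    DxCode,
    EnrollmentSpan,
    MedicalClaim,
    PatientRecord,
    PharmacyClaim,
    ProcCode,
)
from .codebook import Codebook, default_codebook

logger = logging.getLogger(__name__)

EPOCH = dt.date(2008, 1, 1)
ACCRUAL_DAYS = (dt.date(2014, 12, 31) - EPOCH).days  # 2556


def _d(day: int) -> dt.date:
    return EPOCH + dt.timedelta(days=int(day))


# Cohort composition defaults: published four-cancer case mix, per-type
# metastatic fractions and treatment-modality mixes.
DEFAULT_CANCER_MIX = {
    "breast": 0.385,
    "colorectal": 0.162,
    "lung": 0.159,
    "prostate": 0.294,
}
DEFAULT_METASTATIC_PROB = {
    "breast": 0.216,
    "colorectal": 0.356,
    "lung": 0.588,
    "prostate": 0.114,
}
DEFAULT_TREATMENT_MIX = {
    "breast": {"chemotherapy_only": 0.148, "radiation_only": 0.092,
               "surgery_only": 0.185, "multimodality": 0.575},
    "colorectal": {"chemotherapy_only": 0.167, "radiation_only": 0.024,
                   "surgery_only": 0.435, "multimodality": 0.374},
    "lung": {"chemotherapy_only": 0.224, "radiation_only": 0.141,
             "surgery_only": 0.133, "multimodality": 0.502},
    "prostate": {"chemotherapy_only": 0.198, "radiation_only": 0.224,
                 "surgery_only": 0.333, "multimodality": 0.245},
}
DEFAULT_AGE_MEAN = {"breast": 59.5, "colorectal": 63.2, "lung": 67.1, "prostate": 66.9}

_CANCER_DX = {  # (ICD-9, ICD-10) emitted for the first diagnosis
    "breast": ("1749", "C509"),
    "colorectal": ("1530", "C189"),
    "lung": ("1629", "C349"),
    "prostate": ("185", "C61"),
}
_SURGERY_CPT = {
    "breast": "19303",
    "colorectal": "44140",
    "lung": "32480",
    "prostate": "55840",
}
_CHEMO_DRUGS = {
    "breast": ["paclitaxel", "doxorubicin", "tamoxifen"],
    "colorectal": ["fluorouracil", "oxaliplatin", "capecitabine"],
    "lung": ["carboplatin", "pemetrexed", "erlotinib"],
    "prostate": ["docetaxel", "leuprolide", "bicalutamide"],
}
_ANTICOAGULANTS = [
    "warfarin", "enoxaparin", "apixaban", "rivaroxaban",
    "dabigatran", "fondaparinux", "edoxaban",
]
# One representative code per comorbidity category (ICD-9 form).
_COMORBIDITY_CODES = {
    "myocardial_infarction": "41001",
    "congestive_heart_failure": "4280",
    "peripheral_vascular_disease": "4400",
    "cerebrovascular_disease": "43491",
    "dementia": "2900",
    "chronic_pulmonary_disease": "49121",
    "rheumatologic_disease": "7140",
    "peptic_ulcer_disease": "5319",
    "mild_liver_disease": "5715",
    "diabetes": "25000",
    "diabetes_with_complications": "25040",
    "hemiplegia": "3420",
    "renal_disease": "5859",
    "severe_liver_disease": "5722",
    "aids": "0420",
}
_FILLER_DX = "4019"  # hypertension: matches no trigger, cancer or comorbidity set

# Concrete emittable codes per trigger: (dx ICD-9, dx ICD-10) choices per
# clause, or procedure / drug emissions handled specially below.
_DX_EMIT = {
    "pressure_ulcer": (["70703", "70714"], ["L8990"]),
    "hypoxemia": (["79902"], ["R0902"]),
    "blood_transfusion": (["V582"], ["Z5131"]),
    "contact_precautions": (["V070", "V071"], ["Z290"]),
    "abnormal_bicarbonate": (["7906", "2762", "2763"], ["R791", "E872"]),
    "abnormal_potassium": (["2767", "2768"], ["E875", "E876"]),
    "c_difficile": (["00845"], ["A047"]),
    "bacteremia": (["7907"], ["R7881"]),
}


@dataclass
class SimConfig:
    """Generator knobs; defaults are the study conditions the tool targets."""

    n_patients: int = 2000
    seed: int = 0
    cancer_mix: dict = field(default_factory=lambda: dict(DEFAULT_CANCER_MIX))
    metastatic_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_METASTATIC_PROB)
    )
    treatment_mix: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TREATMENT_MIX.items()}
    )
    planted_rate: float | dict = 0.10  # per trigger, among exposed patients
    decoy_rate: float = 0.05
    half_clause_rate: float = 0.05  # lone fever code without neutropenia
    constraint_negative_rate: float = 0.03
    comorbidity_rate: float = 0.08  # per Charlson category
    washout_violator_rate: float = 0.05
    recurrence_violator_rate: float = 0.02
    under18_rate: float = 0.02
    male_breast_rate: float = 0.01
    no_treatment_rate: float = 0.03
    enrollment_gap_rate: float = 0.05
    death_rate: float = 0.08
    icd10_fraction: float = 0.3
    mean_inpatient_stays: float = 0.4

    def __post_init__(self) -> None:
        for name in ("decoy_rate", "half_clause_rate", "comorbidity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if abs(sum(self.cancer_mix.values()) - 1) > 1e-6:
            raise ValueError("cancer_mix must sum to 1")
        for ctype, mix in self.treatment_mix.items():
            total = sum(mix.values())
            self.treatment_mix[ctype] = {k: v / total for k, v in mix.items()}

    def rate_for(self, trigger_id: str) -> float:
        if isinstance(self.planted_rate, dict):
            return float(self.planted_rate.get(trigger_id, 0.0))
        return float(self.planted_rate)


@dataclass
class GroundTruth:
    """Per-patient labels plus planted events and decoys."""

    patients: pd.DataFrame
    planted: pd.DataFrame
    decoys: pd.DataFrame


class _Emitter:
    """Accumulates claims for one simulated bundle."""

    def __init__(self) -> None:
        self.bundle = ClaimsBundle()
        self._mid = 0
        self._pid = 0

    def medical(self, pid, day, dx=(), proc=(), setting="outpatient",
                admit=None, discharge=None, specialty=None) -> None:
        self._mid += 1
        self.bundle.medical.append(
            MedicalClaim(
                claim_id=f"M{self._mid}",
                patient_id=pid,
                service_date=_d(day),
                setting=setting,
                dx_codes=tuple(dx),
                proc_codes=tuple(proc),
                admit_date=_d(admit) if admit is not None else None,
                discharge_date=_d(discharge) if discharge is not None else None,
                provider_specialty=specialty,
            )
        )

    def fill(self, pid, day, drug) -> None:
        self._pid += 1
        self.bundle.pharmacy.append(
            PharmacyClaim(
                claim_id=f"P{self._pid}",
                patient_id=pid,
                fill_date=_d(day),
                generic_name=drug,
                days_supply=30,
            )
        )


def _choice(rng: np.random.Generator, items):
    return items[int(rng.integers(0, len(items)))]


def _emit_trigger_claims(
    emit: _Emitter,
    rng: np.random.Generator,
    cfg: SimConfig,
    pid: str,
    trigger_id: str,
    day: int,
    followup_end: int,
    enrolled,
) -> None:
    """Emit the claims that realize one occurrence of a trigger on ``day``.

    Constraint triggers are emitted with their constraints satisfied, so
    that only the temporal linkage decides detection.
    """
    use_icd10 = rng.random() < cfg.icd10_fraction
    if trigger_id in _DX_EMIT:
        icd9, icd10 = _DX_EMIT[trigger_id]
        if use_icd10:
            code, system = _choice(rng, icd10), "ICD10Dx"
        else:
            code, system = _choice(rng, icd9), "ICD9Dx"
        if trigger_id == "blood_transfusion" and rng.random() < 0.5:
            emit.medical(pid, day, proc=[ProcCode("36430", "CPT")])
        elif trigger_id == "bacteremia" and rng.random() < 0.5:
            emit.medical(
                pid, day,
                dx=[DxCode(code, system)],
                proc=[ProcCode("87040", "CPT")],
            )
        else:
            emit.medical(pid, day, dx=[DxCode(code, system)])
    elif trigger_id == "neutropenic_fever":
        fever = DxCode("R509", "ICD10Dx") if use_icd10 else DxCode("7806", "ICD9Dx")
        anc = DxCode("D700", "ICD10Dx") if use_icd10 else DxCode("2880", "ICD9Dx")
        emit.medical(pid, day, dx=[fever])
        second = day + int(rng.integers(0, min(7, max(followup_end - day, 0)) + 1))
        if not enrolled(second):
            second = day
        emit.medical(pid, second, dx=[anc])
    elif trigger_id == "return_to_or":
        emit.medical(pid, day, proc=[ProcCode("49406", "CPT")])
    elif trigger_id == "nasogastric_tube":
        proc = ProcCode("43753", "CPT") if rng.random() < 0.5 else ProcCode("9607", "ICD9Proc")
        emit.medical(pid, day, proc=[proc])
    elif trigger_id == "chest_ct_noncontrast":
        emit.medical(pid, day, proc=[ProcCode("71250", "CPT")])
    elif trigger_id == "percutaneous_drain":
        proc = ProcCode("32557", "CPT") if rng.random() < 0.5 else ProcCode("5491", "ICD9Proc")
        emit.medical(pid, day, proc=[proc])
    elif trigger_id == "elevated_creatinine":
        code = DxCode("N179", "ICD10Dx", poa="no") if use_icd10 else DxCode(
            "5849", "ICD9Dx", poa="no"
        )
        discharge = min(day + 2, max(followup_end, day))
        emit.medical(
            pid, day, dx=[code], setting="inpatient",
            admit=day, discharge=discharge,
        )
    elif trigger_id == "anticoagulation":
        emit.fill(pid, day, _choice(rng, _ANTICOAGULANTS))
    elif trigger_id == "nephrology_consult":
        emit.medical(
            pid, day, proc=[ProcCode("99244", "CPT")], specialty="Nephrologist"
        )
    else:  # pragma: no cover - the 16 defaults are enumerated above
        raise ValueError(f"no emission rule for trigger {trigger_id}")


def simulate(cfg: SimConfig, codebook: Codebook | None = None) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle and its ground truth, reproducibly."""
    book = codebook or default_codebook()
    rng = np.random.default_rng(cfg.seed)
    emit = _Emitter()

    cancer_types = sorted(cfg.cancer_mix)
    cancer_p = np.array([cfg.cancer_mix[t] for t in cancer_types])
    races = ["white", "black", "hispanic", "asian", "unknown"]
    race_p = np.array([0.53, 0.08, 0.04, 0.02, 0.33])
    income_bands = ["unknown", "<25K", "25-149K", "150-249K", "250K+"]
    education_bands = ["unknown", "high_school", "some_college", "bachelor_plus"]

    patient_rows = []
    planted_rows = []
    decoy_rows = []

    for i in range(cfg.n_patients):
        pid = f"SYN{i:06d}"
        # Violator class (mutually exclusive by construction).
        u = rng.random()
        violator = None
        acc = 0.0
        for name, rate in (
            ("washout_dx", cfg.washout_violator_rate),
            ("recurrence", cfg.recurrence_violator_rate),
            ("under_18", cfg.under18_rate),
            ("no_treatment", cfg.no_treatment_rate),
        ):
            acc += rate
            if u < acc:
                violator = name
                break

        ctype = cancer_types[int(rng.choice(len(cancer_types), p=cancer_p))]
        if violator is None and ctype == "breast" and rng.random() < cfg.male_breast_rate:
            violator = "male_breast"

        if ctype == "breast":
            sex = "male" if violator == "male_breast" else "female"
        elif ctype == "prostate":
            sex = "male"
        else:
            sex = "male" if rng.random() < 0.5 else "female"

        # Timeline (integer days from the epoch).
        if violator == "washout_dx":
            dx_day = int(rng.integers(0, 201))
        else:
            dx_day = int(rng.integers(0, ACCRUAL_DAYS - 120 + 1))
        index_day = dx_day + int(rng.integers(7, 61))
        dx_year = _d(dx_day).year
        if violator == "under_18":
            # cap at 16 so the patient is still a minor at index even when
            # treatment starts the following calendar year
            age_at_dx = int(rng.integers(5, 17))
        else:
            age_at_dx = int(np.clip(rng.normal(DEFAULT_AGE_MEAN[ctype], 11.5), 19, 90))
        birth_year = dx_year - age_at_dx

        metastatic = bool(rng.random() < cfg.metastatic_prob[ctype])

        # Treatment schedule: {exposure_type: [days]}
        if violator == "no_treatment":
            category = None
            schedule: dict[str, list[int]] = {}
        else:
            mix = cfg.treatment_mix[ctype]
            cats = sorted(mix)
            category = cats[int(rng.choice(len(cats), p=np.array([mix[c] for c in cats])))]
            schedule = {}
            if category in ("surgery_only", "multimodality"):
                schedule["surgery"] = [index_day]
            if category == "chemotherapy_only":
                start = index_day
            elif category == "multimodality":
                start = index_day + 28
            else:
                start = None
            if start is not None:
                n_cycles = int(rng.integers(4, 9))
                schedule["chemotherapy"] = [start + 21 * j for j in range(n_cycles)]
            if category == "radiation_only":
                schedule["radiation"] = [index_day + 7 * j for j in range(5)]
            elif category == "multimodality" and rng.random() < 0.5:
                rstart = index_day + 120
                schedule["radiation"] = [rstart + 7 * j for j in range(5)]

        death_day = None
        if violator is None and rng.random() < cfg.death_rate:
            death_day = index_day + int(rng.integers(30, 401))

        enroll_start = dx_day - 1200
        enroll_end = index_day + 400
        followup_end = min(index_day + 365, enroll_end)
        if death_day is not None:
            followup_end = min(followup_end, death_day)

        # Drop treatment events past follow-up (no claims after death).
        schedule = {
            etype: [d for d in days if d <= followup_end]
            for etype, days in schedule.items()
        }
        schedule = {etype: days for etype, days in schedule.items() if days}

        # Enrollment gap strictly after the last treatment event.
        gap = None
        all_expo_days = sorted(d for days in schedule.values() for d in days)
        if (
            violator is None
            and all_expo_days
            and rng.random() < cfg.enrollment_gap_rate
        ):
            gap_start = all_expo_days[-1] + 5
            gap_end = gap_start + 29
            if gap_end < enroll_end:
                gap = (gap_start, gap_end)

        def enrolled(day: int) -> bool:
            if not (enroll_start <= day <= enroll_end):
                return False
            if gap and gap[0] <= day <= gap[1]:
                return False
            return True

        spans = []
        if gap:
            spans.append(EnrollmentSpan(pid, _d(enroll_start), _d(gap[0] - 1)))
            spans.append(EnrollmentSpan(pid, _d(gap[1] + 1), _d(enroll_end)))
        else:
            spans.append(EnrollmentSpan(pid, _d(enroll_start), _d(enroll_end)))
        emit.bundle.enrollment[pid] = spans

        emit.bundle.patients[pid] = PatientRecord(
            patient_id=pid,
            birth_year=birth_year,
            sex=sex,
            race=races[int(rng.choice(len(races), p=race_p))],
            income_band=_choice(rng, income_bands),
            education_band=_choice(rng, education_bands),
            insurance="private" if rng.random() < 0.77 else "medicare_advantage",
            death_date=_d(death_day) if death_day is not None else None,
        )

        # First cancer diagnosis claim.
        icd9_code, icd10_code = _CANCER_DX[ctype]
        use10 = rng.random() < cfg.icd10_fraction
        dx_code = DxCode(icd10_code if use10 else icd9_code,
                         "ICD10Dx" if use10 else "ICD9Dx")
        emit.medical(pid, dx_day, dx=[dx_code])

        if violator == "washout_dx":
            prior_day = dx_day - int(rng.integers(300, 1001))
            emit.medical(pid, prior_day, dx=[DxCode(icd9_code, "ICD9Dx")])
        elif violator == "recurrence":
            marker_day = dx_day - int(rng.integers(30, 201))
            emit.medical(pid, marker_day, dx=[DxCode("V103", "ICD9Dx")])

        # Treatment claims.
        drugs = _CHEMO_DRUGS[ctype]
        for etype, days in schedule.items():
            for day in days:
                if etype == "surgery":
                    emit.medical(pid, day, proc=[ProcCode(_SURGERY_CPT[ctype], "CPT")])
                elif etype == "radiation":
                    emit.medical(pid, day, proc=[ProcCode("77402", "CPT")])
                else:
                    if rng.random() < 0.7:
                        emit.medical(pid, day, proc=[ProcCode("96413", "CPT")])
                    else:
                        emit.fill(pid, day, _choice(rng, drugs))

        # Comorbidity noise (pre-index, so it feeds the comorbidity score).
        for cat, code in _COMORBIDITY_CODES.items():
            if rng.random() < cfg.comorbidity_rate:
                day = index_day - int(rng.integers(30, 301))
                emit.medical(pid, day, dx=[DxCode(code, "ICD9Dx")])

        # Baseline metastatic marker (between diagnosis and index: always
        # inside the classifier window and never inside an enrollment gap).
        if metastatic:
            day = int(rng.integers(dx_day, index_day + 1))
            emit.medical(pid, day, dx=[DxCode("1970", "ICD9Dx")])

        # Inpatient utilization noise.
        if violator is None and schedule:
            surgery_days = set(schedule.get("surgery", ()))
            for _ in range(rng.poisson(cfg.mean_inpatient_stays)):
                if followup_end <= index_day + 1:
                    break
                admit = int(rng.integers(index_day, followup_end))
                length = int(rng.integers(2, 9))
                discharge = min(admit + length, followup_end)
                if admit in surgery_days or not enrolled(admit) or not enrolled(discharge):
                    continue
                emit.medical(
                    pid, admit, dx=[DxCode(_FILLER_DX, "ICD9Dx", poa="yes")],
                    setting="inpatient", admit=admit, discharge=discharge,
                )

        eligible = violator is None and bool(schedule)
        if violator is None and not schedule:
            violator = "no_treatment"  # degenerate: all treatment past follow-up

        patient_rows.append(
            {
                "patient_id": pid,
                "eligible": eligible,
                "exclusion_reason": None if eligible else violator,
                "cancer_type": ctype,
                "metastatic": metastatic,
                "treatment_category": category if eligible else None,
                "first_dx_date": _d(dx_day),
                "index_date": _d(index_day) if eligible else None,
                "followup_end": _d(followup_end) if eligible else None,
            }
        )

        if not eligible:
            continue

        # ---- planted triggers (strictly in-window) ----
        modalities = set(schedule)
        planted_here: set[str] = set()
        for tid, rule in book.rules.items():
            elig_types = sorted(rule.eligible_exposures & modalities)
            if not elig_types or rng.random() >= cfg.rate_for(tid):
                continue
            event_day = None
            anchor = None
            for _attempt in range(40):
                if tid in ("return_to_or", "nasogastric_tube"):
                    cand_anchor = schedule["surgery"][0]
                    offset = int(rng.integers(1, 31))
                else:
                    etype = _choice(rng, elig_types)
                    cand_anchor = _choice(rng, schedule[etype])
                    offset = int(rng.integers(1, rule.lookback_days + 1))
                day = cand_anchor + offset
                if day > followup_end or not enrolled(day):
                    continue
                event_day, anchor = day, cand_anchor
                break
            if event_day is None:
                logger.debug("skipped infeasible plant %s for %s", tid, pid)
                continue
            _emit_trigger_claims(
                emit, rng, cfg, pid, tid, event_day, followup_end, enrolled
            )
            anchor_type = (
                "surgery"
                if tid in ("return_to_or", "nasogastric_tube")
                else next(
                    t for t in elig_types if anchor in schedule[t]
                )
            )
            planted_here.add(tid)
            planted_rows.append(
                {
                    "patient_id": pid,
                    "trigger_id": tid,
                    "event_date": _d(event_day),
                    "exposure_type": anchor_type,
                    "exposure_date": _d(anchor),
                }
            )

        # ---- decoys (strictly out of every window) ----
        decoyed_here: set[str] = set()
        for tid, rule in book.rules.items():
            elig_types = sorted(rule.eligible_exposures & modalities)
            if not elig_types or rng.random() >= cfg.decoy_rate:
                continue
            last_expo = max(d for t in elig_types for d in schedule[t])
            pre_index = rng.random() < 0.5
            if tid == "anticoagulation" and pre_index:
                day = index_day - int(rng.integers(120, 301))
            elif pre_index:
                day = index_day - int(rng.integers(10, 201))
            else:
                day = last_expo + rule.lookback_days + 1 + int(rng.integers(0, 31))
            _emit_trigger_claims(
                emit, rng, cfg, pid, tid, day, max(day, followup_end), enrolled
            )
            decoyed_here.add(tid)
            decoy_rows.append(
                {
                    "patient_id": pid,
                    "trigger_id": tid,
                    "date": _d(day),
                    "kind": "pre_index" if pre_index else "post_window",
                }
            )

        # ---- hard negatives ----
        # Lone fever code without a neutropenia code: no candidate forms.
        # Skipped when the patient carries any other neutropenic-fever
        # claims, so the lone code cannot pair with an out-of-window
        # neutropenia code into a spurious in-window candidate.
        if (
            "chemotherapy" in modalities
            and "neutropenic_fever" not in planted_here
            and "neutropenic_fever" not in decoyed_here
            and rng.random() < cfg.half_clause_rate
        ):
            anchor = _choice(rng, schedule["chemotherapy"])
            day = anchor + int(rng.integers(1, 31))
            if day <= followup_end and enrolled(day):
                emit.medical(pid, day, dx=[DxCode("7806", "ICD9Dx")])
                decoy_rows.append(
                    {"patient_id": pid, "trigger_id": "neutropenic_fever",
                     "date": _d(day), "kind": "half_clause"}
                )
        # Acute kidney injury present on admission: constraint must drop it.
        if "chemotherapy" in modalities and rng.random() < cfg.constraint_negative_rate:
            anchor = _choice(rng, schedule["chemotherapy"])
            day = anchor + int(rng.integers(1, 31))
            if day <= followup_end and enrolled(day):
                emit.medical(
                    pid, day, dx=[DxCode("5849", "ICD9Dx", poa="yes")],
                    setting="inpatient", admit=day, discharge=min(day + 2, followup_end),
                )
                decoy_rows.append(
                    {"patient_id": pid, "trigger_id": "elevated_creatinine",
                     "date": _d(day), "kind": "poa_yes"}
                )
        # Consult E&M billed by the wrong specialty: constraint must drop it.
        if all_expo_days and rng.random() < cfg.constraint_negative_rate:
            day = all_expo_days[0] + int(rng.integers(1, 31))
            if day <= followup_end and enrolled(day):
                emit.medical(
                    pid, day, proc=[ProcCode("99244", "CPT")], specialty="Cardiology"
                )
                decoy_rows.append(
                    {"patient_id": pid, "trigger_id": "nephrology_consult",
                     "date": _d(day), "kind": "wrong_specialty"}
                )

    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id", "eligible", "exclusion_reason", "cancer_type",
            "metastatic", "treatment_category", "first_dx_date",
            "index_date", "followup_end",
        ],
    )
    planted = pd.DataFrame(
        planted_rows,
        columns=["patient_id", "trigger_id", "event_date", "exposure_type",
                 "exposure_date"],
    )
    decoys = pd.DataFrame(
        decoy_rows, columns=["patient_id", "trigger_id", "date", "kind"]
    )
    return emit.bundle, GroundTruth(patients=patients, planted=planted, decoys=decoys)


def score_detection(
    events,
    truth: GroundTruth,
    codebook: Codebook | None = None,
) -> tuple[float, int]:
    """Score detected events against the planted ground truth.

    A planted event is matched when a detected event of the same patient
    and trigger lies within that trigger's persistence window of it; a
    detected event matching no planted event is a false positive. Returns
    ``(sensitivity, false_positive_count)``; sensitivity is 1.0 when
    nothing was planted.
    """
    book = codebook or default_codebook()
    detected: dict[tuple[str, str], list[dt.date]] = {}
    for ev in events:
        detected.setdefault((ev.patient_id, ev.trigger_id), []).append(ev.event_date)

    matched = 0
    n_planted = len(truth.planted)
    matched_detected: set[tuple[str, str, dt.date]] = set()
    for row in truth.planted.itertuples(index=False):
        persistence = book.rules[row.trigger_id].persistence_days
        for d in detected.get((row.patient_id, row.trigger_id), ()):
            if abs((d - row.event_date).days) <= persistence:
                matched += 1
                matched_detected.add((row.patient_id, row.trigger_id, d))
                break
    false_positives = sum(
        1
        for ev in events
        if (ev.patient_id, ev.trigger_id, ev.event_date) not in matched_detected
    )
    sensitivity = matched / n_planted if n_planted else 1.0
    return sensitivity, false_positives
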