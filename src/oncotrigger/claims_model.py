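"""Typed model of administrative claims streams and their CSV interchange format.

The package operates on four longitudinal streams — medical claims, pharmacy
claims, enrollment spans, and patient demographics — at day granularity.
Diagnosis and procedure codes are stored normalized (uppercase, dots and
whitespace stripped) and are always qualified by a coding system; ICD-9 and
ICD-10 codes never cross-match implicitly.

CSV schema (one row per claim; dates ISO-8601):

* ``patients.csv``: patient_id, birth_year, sex, race, income_band,
  education_band, insurance, death_date
* ``medical_claims.csv``: claim_id, patient_id, service_date, setting,
  admit_date, discharge_date, dx, proc, provider_specialty —
  dx cells are ``code^system^poa|code^system^poa|...`` and proc cells
  ``code^system|...``
* ``pharmacy_claims.csv``: claim_id, patient_id, fill_date, generic_name,
  days_supply
* ``enrollment.csv``: patient_id, start_date, end_date

A schema config (dict or YAML) may remap arbitrary source column names onto
these canonical names.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Coding systems
ICD9DX = "ICD9Dx"
ICD10DX = "ICD10Dx"
ICD9PROC = "ICD9Proc"
CPT = "CPT"
DRUG = "DRUG"

DX_SYSTEMS = frozenset({ICD9DX, ICD10DX})
PROC_SYSTEMS = frozenset({ICD9PROC, CPT})
ALL_SYSTEMS = DX_SYSTEMS | PROC_SYSTEMS | {DRUG}

POA_VALUES = ("yes", "no", "unknown")


class ClaimsSchemaError(ValueError):
    """A required column is missing or a config value is invalid."""


def normalize_code(raw: str, system: str) -> str:
    """Normalize a raw code for the given coding system.

    ICD/CPT codes are uppercased with dots and all whitespace removed
    ("790.6" -> "7906", "36 430" -> "36430"); DRUG names are lowercased and
    trimmed. Idempotent.
    """
    if system not in ALL_SYSTEMS:
        raise ValueError(f"unknown coding system {system!r}")
    if raw is None:
        raise ValueError("empty code")
    if system == DRUG:
        out = str(raw).strip().lower()
    else:
        out = "".join(str(raw).split()).replace(".", "").upper()
    if not out:
        raise ValueError(f"code {raw!r} empty after normalization")
    return out


@dataclass(frozen=True)
class DxCode:
    code: str
    system: str  # ICD9Dx | ICD10Dx
    poa: str = "unknown"  # present-on-admission flag


@dataclass(frozen=True)
class ProcCode:
    code: str
    system: str  # ICD9Proc | CPT


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_year: int
    sex: str  # male | female
    race: str = "unknown"
    income_band: str = "unknown"
    education_band: str = "unknown"
    insurance: str = "private"
    death_date: dt.date | None = None


@dataclass(frozen=True)
class MedicalClaim:
    claim_id: str
    patient_id: str
    service_date: dt.date
    setting: str  # inpatient | outpatient
    dx_codes: tuple[DxCode, ...] = ()
    proc_codes: tuple[ProcCode, ...] = ()
    admit_date: dt.date | None = None
    discharge_date: dt.date | None = None
    provider_specialty: str | None = None


@dataclass(frozen=True)
class PharmacyClaim:
    claim_id: str
    patient_id: str
    fill_date: dt.date
    generic_name: str
    days_supply: int | None = None


@dataclass(frozen=True)
class EnrollmentSpan:
    patient_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"enrollment span for {self.patient_id} has start after end"
            )


@dataclass
class ClaimsBundle:
    """All four claim streams for a study population."""

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    medical: list[MedicalClaim] = field(default_factory=list)
    pharmacy: list[PharmacyClaim] = field(default_factory=list)
    enrollment: dict[str, list[EnrollmentSpan]] = field(default_factory=dict)

    def merged_enrollment(self) -> dict[str, list[EnrollmentSpan]]:
        return {
            pid: merge_enrollment(spans) for pid, spans in self.enrollment.items()
        }

    def enrolled_on(self, patient_id: str, date: dt.date) -> bool:
        for span in self.enrollment.get(patient_id, ()):
            if span.start_date <= date <= span.end_date:
                return True
        return False


def merge_enrollment(spans: Sequence[EnrollmentSpan]) -> list[EnrollmentSpan]:
    """Merge overlapping or adjacent spans into disjoint sorted spans.

    Adjacent means end + 1 day == next start; coverage (the set of covered
    days) is preserved exactly.
    """
    if not spans:
        return []
    pids = {s.patient_id for s in spans}
    if len(pids) > 1:
        raise ValueError("merge_enrollment requires spans of a single patient")
    ordered = sorted(spans, key=lambda s: (s.start_date, s.end_date))
    out = [ordered[0]]
    one_day = dt.timedelta(days=1)
    for span in ordered[1:]:
        last = out[-1]
        if span.start_date <= last.end_date + one_day:
            if span.end_date > last.end_date:
                out[-1] = replace(last, end_date=span.end_date)
        else:
            out.append(span)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "patient_id",
        "birth_year": "birth_year",
        "sex": "sex",
        "race": "race",
        "income_band": "income_band",
        "education_band": "education_band",
        "insurance": "insurance",
        "death_date": "death_date",
    },
    "medical": {
        "claim_id": "claim_id",
        "patient_id": "patient_id",
        "service_date": "service_date",
        "setting": "setting",
        "admit_date": "admit_date",
        "discharge_date": "discharge_date",
        "dx": "dx",
        "proc": "proc",
        "provider_specialty": "provider_specialty",
    },
    "pharmacy": {
        "claim_id": "claim_id",
        "patient_id": "patient_id",
        "fill_date": "fill_date",
        "generic_name": "generic_name",
        "days_supply": "days_supply",
    },
    "enrollment": {
        "patient_id": "patient_id",
        "start_date": "start_date",
        "end_date": "end_date",
    },
}

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "patients": ("patient_id", "birth_year", "sex"),
    "medical": ("patient_id", "service_date", "setting"),
    "pharmacy": ("patient_id", "fill_date", "generic_name"),
    "enrollment": ("patient_id", "start_date", "end_date"),
}


@dataclass
class RejectedRow:
    stream: str
    row_index: int
    reason: str


def _load_schema(schema_config) -> dict[str, dict[str, str]]:
    if schema_config is None:
        return DEFAULT_SCHEMA
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            schema_config = yaml.safe_load(fh)
    merged = {k: dict(v) for k, v in DEFAULT_SCHEMA.items()}
    for stream, cols in schema_config.items():
        if stream not in merged:
            raise ClaimsSchemaError(f"unknown stream {stream!r} in schema config")
        merged[stream].update(cols)
    return merged


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"nan", "none", ""}:
        return None
    return dt.date.fromisoformat(s)


def _parse_dx_cell(cell) -> tuple[DxCode, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    out = []
    for part in str(cell).split("|"):
        fields = part.split("^")
        if len(fields) < 2:
            raise ValueError(f"malformed dx entry {part!r}")
        code, system = fields[0], fields[1]
        poa = fields[2] if len(fields) > 2 and fields[2] else "unknown"
        if system not in DX_SYSTEMS:
            raise ValueError(f"bad dx system {system!r}")
        if poa not in POA_VALUES:
            raise ValueError(f"bad poa value {poa!r}")
        out.append(DxCode(normalize_code(code, system), system, poa))
    return tuple(out)


def _parse_proc_cell(cell) -> tuple[ProcCode, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    out = []
    for part in str(cell).split("|"):
        fields = part.split("^")
        if len(fields) < 2:
            raise ValueError(f"malformed proc entry {part!r}")
        code, system = fields[0], fields[1]
        if system not in PROC_SYSTEMS:
            raise ValueError(f"bad proc system {system!r}")
        out.append(ProcCode(normalize_code(code, system), system))
    return tuple(out)


def _read_stream(path, stream: str, schema: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {src: dst for dst, src in schema.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS[stream] if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(
            f"{stream} file {path} missing required columns: {missing}"
        )
    return df


def read_claims_bundle(
    paths: Mapping[str, str | Path], schema_config=None
) -> tuple[ClaimsBundle, list[RejectedRow]]:
    """Read the four claim streams into a validated, code-normalized bundle.

    ``paths`` maps stream names (patients, medical, pharmacy, enrollment) to
    CSV file paths. Rows failing hard validation (unparseable dates,
    malformed code cells, inpatient date-order violations) are rejected and
    reported; missing required columns are fatal.
    """
    schema = _load_schema(schema_config)
    bundle = ClaimsBundle()
    rejects: list[RejectedRow] = []

    if "patients" in paths:
        df = _read_stream(paths["patients"], "patients", schema["patients"])
        for i, row in df.iterrows():
            try:
                rec = PatientRecord(
                    patient_id=str(row["patient_id"]),
                    birth_year=int(row["birth_year"]),
                    sex=str(row["sex"]).strip().lower(),
                    race=str(row.get("race", "") or "unknown").strip().lower(),
                    income_band=str(row.get("income_band", "") or "unknown").strip(),
                    education_band=str(row.get("education_band", "") or "unknown").strip(),
                    insurance=str(row.get("insurance", "") or "private").strip().lower(),
                    death_date=_parse_date(row.get("death_date")),
                )
                if rec.sex not in {"male", "female"}:
                    raise ValueError(f"bad sex {rec.sex!r}")
                if rec.patient_id in bundle.patients:
                    raise ValueError(f"duplicate patient_id {rec.patient_id}")
                bundle.patients[rec.patient_id] = rec
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow("patients", int(i), str(exc)))

    if "medical" in paths:
        df = _read_stream(paths["medical"], "medical", schema["medical"])
        for i, row in df.iterrows():
            try:
                service = _parse_date(row["service_date"])
                if service is None:
                    raise ValueError("missing service_date")
                setting = str(row["setting"]).strip().lower()
                if setting not in {"inpatient", "outpatient"}:
                    raise ValueError(f"bad setting {setting!r}")
                admit = _parse_date(row.get("admit_date"))
                discharge = _parse_date(row.get("discharge_date"))
                if setting == "inpatient" and admit and discharge:
                    if not (admit <= service <= discharge):
                        raise ValueError("inpatient dates out of order")
                spec = str(row.get("provider_specialty", "") or "").strip() or None
                claim = MedicalClaim(
                    claim_id=str(row.get("claim_id", "") or f"M{i}"),
                    patient_id=str(row["patient_id"]),
                    service_date=service,
                    setting=setting,
                    dx_codes=_parse_dx_cell(row.get("dx")),
                    proc_codes=_parse_proc_cell(row.get("proc")),
                    admit_date=admit,
                    discharge_date=discharge,
                    provider_specialty=spec,
                )
                bundle.medical.append(claim)
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow("medical", int(i), str(exc)))

    if "pharmacy" in paths:
        df = _read_stream(paths["pharmacy"], "pharmacy", schema["pharmacy"])
        for i, row in df.iterrows():
            try:
                fill = _parse_date(row["fill_date"])
                if fill is None:
                    raise ValueError("missing fill_date")
                name = normalize_code(row["generic_name"], DRUG)
                ds = str(row.get("days_supply", "") or "").strip()
                days = int(ds) if ds else None
                if days is not None and days <= 0:
                    raise ValueError("days_supply must be positive")
                bundle.pharmacy.append(
                    PharmacyClaim(
                        claim_id=str(row.get("claim_id", "") or f"P{i}"),
                        patient_id=str(row["patient_id"]),
                        fill_date=fill,
                        generic_name=name,
                        days_supply=days,
                    )
                )
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow("pharmacy", int(i), str(exc)))

    if "enrollment" in paths:
        df = _read_stream(paths["enrollment"], "enrollment", schema["enrollment"])
        for i, row in df.iterrows():
            try:
                start = _parse_date(row["start_date"])
                end = _parse_date(row["end_date"])
                if start is None or end is None:
                    raise ValueError("missing enrollment date")
                span = EnrollmentSpan(str(row["patient_id"]), start, end)
                bundle.enrollment.setdefault(span.patient_id, []).append(span)
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow("enrollment", int(i), str(exc)))

    bundle.enrollment = bundle.merged_enrollment()
    for rej in rejects:
        logger.warning("rejected %s row %d: %s", rej.stream, rej.row_index, rej.reason)
    validate_bundle(bundle)
    return bundle, rejects


def validate_bundle(bundle: ClaimsBundle, strict: bool = False) -> list[str]:
    """Cross-stream consistency checks.

    Currently: death_date, when present, must be on/after every claim date
    for the patient. Violations are warnings by default (``strict=True``
    raises).
    """
    problems: list[str] = []
    last_claim: dict[str, dt.date] = {}
    for mc in bundle.medical:
        d = max(filter(None, [mc.service_date, mc.discharge_date]))
        if mc.patient_id not in last_claim or d > last_claim[mc.patient_id]:
            last_claim[mc.patient_id] = d
    for pc in bundle.pharmacy:
        if pc.patient_id not in last_claim or pc.fill_date > last_claim[pc.patient_id]:
            last_claim[pc.patient_id] = pc.fill_date
    for pid, rec in bundle.patients.items():
        if rec.death_date is not None and pid in last_claim:
            if last_claim[pid] > rec.death_date:
                problems.append(
                    f"patient {pid}: claim on {last_claim[pid]} after death "
                    f"{rec.death_date}"
                )
    for msg in problems:
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return problems


def _fmt_date(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def write_claims_bundle(bundle: ClaimsBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle back to the canonical four-file CSV layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "medical": outdir / "medical_claims.csv",
        "pharmacy": outdir / "pharmacy_claims.csv",
        "enrollment": outdir / "enrollment.csv",
    }
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_year": p.birth_year,
                "sex": p.sex,
                "race": p.race,
                "income_band": p.income_band,
                "education_band": p.education_band,
                "insurance": p.insurance,
                "death_date": _fmt_date(p.death_date),
            }
            for p in bundle.patients.values()
        ],
        columns=list(DEFAULT_SCHEMA["patients"]),
    ).to_csv(paths["patients"], index=False)

    pd.DataFrame(
        [
            {
                "claim_id": c.claim_id,
                "patient_id": c.patient_id,
                "service_date": _fmt_date(c.service_date),
                "setting": c.setting,
                "admit_date": _fmt_date(c.admit_date),
                "discharge_date": _fmt_date(c.discharge_date),
                "dx": "|".join(f"{d.code}^{d.system}^{d.poa}" for d in c.dx_codes),
                "proc": "|".join(f"{p.code}^{p.system}" for p in c.proc_codes),
                "provider_specialty": c.provider_specialty or "",
            }
            for c in bundle.medical
        ],
        columns=list(DEFAULT_SCHEMA["medical"]),
    ).to_csv(paths["medical"], index=False)

    pd.DataFrame(
        [
            {
                "claim_id": c.claim_id,
                "patient_id": c.patient_id,
                "fill_date": _fmt_date(c.fill_date),
                "generic_name": c.generic_name,
                "days_supply": c.days_supply if c.days_supply is not None else "",
            }
            for c in bundle.pharmacy
        ],
        columns=list(DEFAULT_SCHEMA["pharmacy"]),
    ).to_csv(paths["pharmacy"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "start_date": _fmt_date(s.start_date),
                "end_date": _fmt_date(s.end_date),
            }
            for spans in bundle.enrollment.values()
            for s in spans
        ],
        columns=list(DEFAULT_SCHEMA["enrollment"]),
    ).to_csv(paths["enrollment"], index=False)
    return paths
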