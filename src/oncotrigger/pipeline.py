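"""End-to-end orchestration: claims in, analysis tables out.

``run_pipeline`` wires the stages together — read (or simulate) a claims
bundle, classify treatment exposures, build the incident cohort, derive
risk profiles, run trigger detection, and tabulate prevalence,
events-per-patient distributions, group comparisons and the PPV-weighted
burden — writing one CSV per table plus a run log of counts at every
filtering stage. The pipeline is deterministic: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import pandas as pd
import yaml

from .claims_model import ClaimsBundle, read_claims_bundle
from .codebook import Codebook, load_codebook
from .cohort_builder import CohortRecord, build_cohort
from .prevalence_analysis import (
    cells_to_frame,
    compare_groups,
    ppv_adjust,
    suppress_small_cells,
    tabulate_prevalence,
    trigger_count_distribution,
)
from .risk_profile import build_risk_profiles
from .treatment_classifier import ExposureEvent, classify_exposures, treatment_category
from .trigger_engine import TriggerEvent, detect

logger = logging.getLogger(__name__)


def cohort_to_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "cancer_type": r.cancer_type,
                "first_dx_date": r.first_dx_date,
                "index_date": r.index_date,
                "followup_end": r.followup_end,
                "age_at_index": r.age_at_index,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in cohort
        ],
        columns=[
            "patient_id", "cancer_type", "first_dx_date", "index_date",
            "followup_end", "age_at_index", "exclusion_reason",
        ],
    )


def exposures_to_frame(exposures: list[ExposureEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date,
                "exposure_type": e.exposure_type,
                "source": e.source,
                "code": e.code,
            }
            for e in exposures
        ],
        columns=["patient_id", "date", "exposure_type", "source", "code"],
    )


def events_to_frame(events: list[TriggerEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "trigger_id": e.trigger_id,
                "event_date": e.event_date,
                "linked_exposure_type": e.linked_exposure_type,
                "linked_exposure_date": e.linked_exposure_date,
                "days_since_exposure": e.days_since_exposure,
                "matched_codes": ";".join(f"{c}^{s}" for c, s in e.matched_codes),
            }
            for e in events
        ],
        columns=[
            "patient_id", "trigger_id", "event_date", "linked_exposure_type",
            "linked_exposure_date", "days_since_exposure", "matched_codes",
        ],
    )


def flags_to_frame(flags: dict[tuple[str, str], bool]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": pid, "trigger_id": tid, "exposed": bool(v)}
            for (pid, tid), v in sorted(flags.items())
        ],
        columns=["patient_id", "trigger_id", "exposed"],
    )


def analyze_bundle(
    bundle: ClaimsBundle,
    codebook: Codebook | None = None,
    ppv_table: dict | None = None,
    suppress: bool = True,
    log_lines: list[str] | None = None,
) -> dict:
    """Run every analysis stage on an in-memory bundle.

    Returns a dict of results: cohort / exposures / events / exposure flag
    DataFrames, the risk-profile map, prevalence and distribution tables,
    group comparisons, and the burden estimate.
    """
    book = codebook or load_codebook()
    log = log_lines if log_lines is not None else []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    note(f"patients in bundle: {len(bundle.patients)}")
    note(f"medical claims: {len(bundle.medical)}; pharmacy claims: {len(bundle.pharmacy)}")

    exposures = classify_exposures(bundle, book)
    note(f"treatment exposure events: {len(exposures)}")

    cohort = build_cohort(bundle, exposures, book)
    included = [r for r in cohort if r.included]
    note(f"cohort candidates: {len(cohort)}; included: {len(included)}")
    reasons = pd.Series([r.exclusion_reason for r in cohort if not r.included])
    for reason, n in reasons.value_counts().items():
        note(f"  excluded {reason}: {n}")

    profiles = build_risk_profiles(
        bundle, cohort, exposures, book.secondary_malignancy
    )

    events, flags = detect(bundle, cohort, exposures, book)
    note(f"trigger events after dedup: {len(events)}")

    cohort_df = cohort_to_frame(cohort)
    included_df = cohort_df[cohort_df["exclusion_reason"].isna()].copy()
    included_df["metastatic"] = included_df["patient_id"].map(
        lambda pid: profiles[pid].metastatic
    )
    events_df = events_to_frame(events)
    flags_df = flags_to_frame(flags)

    cells = tabulate_prevalence(events_df, flags_df, included_df)
    if suppress:
        cells = suppress_small_cells(cells)
    prevalence_df = cells_to_frame(cells, suppress=suppress)
    distribution_df = trigger_count_distribution(events_df, included_df)
    burden = ppv_adjust(events_df, n_patients=len(included_df), ppv_table=ppv_table)
    note(
        f"expected adverse events (PPV-weighted): {burden.expected_aes:.1f}; "
        f"preventable: {burden.expected_preventable:.1f}"
    )

    # Covariate comparison: any-trigger vs none among included patients.
    expo_by_patient: dict[str, list[ExposureEvent]] = {}
    for ev in exposures:
        expo_by_patient.setdefault(ev.patient_id, []).append(ev)
    cov_rows = []
    with_any = set(events_df["patient_id"]) if len(events_df) else set()
    for rec in included:
        patient = bundle.patients.get(rec.patient_id)
        prof = profiles[rec.patient_id]
        in_followup = [
            e
            for e in expo_by_patient.get(rec.patient_id, ())
            if rec.index_date <= e.date <= rec.followup_end
        ]
        cov_rows.append(
            {
                "patient_id": rec.patient_id,
                "any_trigger": rec.patient_id in with_any,
                "age": rec.age_at_index,
                "sex": patient.sex if patient else "unknown",
                "race": patient.race if patient else "unknown",
                "insurance": patient.insurance if patient else "unknown",
                "cancer_type": rec.cancer_type,
                "metastatic": prof.metastatic,
                "treatment_category": treatment_category(in_followup),
                "charlson": prof.charlson,
                "inpatient_days": prof.inpatient_days,
                "unplanned_admissions": prof.unplanned_admissions,
            }
        )
    covariates_df = pd.DataFrame(cov_rows)
    if len(covariates_df) and covariates_df["any_trigger"].nunique() == 2:
        comparisons_df = compare_groups(
            covariates_df,
            categorical=("sex", "race", "insurance", "cancer_type",
                         "metastatic", "treatment_category"),
            continuous=("age", "charlson", "inpatient_days"),
        )
    else:
        comparisons_df = pd.DataFrame(
            columns=["covariate", "test", "statistic", "p_value", "note"]
        )
        note("comparison skipped: fewer than two outcome groups")

    return {
        "codebook": book,
        "exposures": exposures,
        "cohort": cohort,
        "profiles": profiles,
        "events": events,
        "flags": flags,
        "cohort_df": cohort_df,
        "included_df": included_df,
        "exposures_df": exposures_to_frame(exposures),
        "events_df": events_df,
        "flags_df": flags_df,
        "prevalence_df": prevalence_df,
        "distribution_df": distribution_df,
        "comparisons_df": comparisons_df,
        "covariates_df": covariates_df,
        "burden": burden,
        "log": log,
    }


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline from a config mapping or YAML file.

    Config keys: ``inputs`` (stream-name -> CSV path), optional
    ``schema`` (column mapping), ``codebook`` (override file),
    ``ppv_table`` (trigger_id -> [ppv_ae, ppv_preventable]),
    ``suppress`` (bool, default true), ``outdir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    outdir = Path(outdir or config.get("outdir", "oncotrigger_output"))

    log: list[str] = [f"run started {dt.datetime.now().isoformat(timespec='seconds')}"]
    bundle, rejects = read_claims_bundle(
        config["inputs"], schema_config=config.get("schema")
    )
    log.append(f"rejected input rows: {len(rejects)}")
    for rej in rejects:
        log.append(f"  {rej.stream} row {rej.row_index}: {rej.reason}")

    book = load_codebook(config.get("codebook"))
    ppv_table = {
        tid: (float(v[0]), float(v[1]))
        for tid, v in (config.get("ppv_table") or {}).items()
    }
    results = analyze_bundle(
        bundle,
        codebook=book,
        ppv_table=ppv_table or None,
        suppress=bool(config.get("suppress", True)),
        log_lines=log,
    )

    outdir.mkdir(parents=True, exist_ok=True)
    results["cohort_df"].to_csv(outdir / "cohort.csv", index=False)
    results["exposures_df"].to_csv(outdir / "exposures.csv", index=False)
    results["events_df"].to_csv(outdir / "trigger_events.csv", index=False)
    results["flags_df"].to_csv(outdir / "exposure_flags.csv", index=False)
    results["prevalence_df"].to_csv(outdir / "prevalence.csv", index=False)
    results["distribution_df"].to_csv(outdir / "distribution.csv", index=False)
    results["comparisons_df"].to_csv(outdir / "comparisons.csv", index=False)
    burden = results["burden"]
    pd.DataFrame(
        [
            {
                "n_patients": burden.n_patients,
                "n_events": burden.n_events,
                "expected_aes": burden.expected_aes,
                "expected_preventable": burden.expected_preventable,
                "pct_patients_with_ae": burden.pct_patients_with_ae,
                "pct_patients_with_preventable": burden.pct_patients_with_preventable,
            }
        ]
    ).to_csv(outdir / "burden.csv", index=False)
    riskprofile_df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "charlson": p.charlson,
                "metastatic": p.metastatic,
                "unplanned_admissions": p.unplanned_admissions,
                "inpatient_days": p.inpatient_days,
            }
            for p in results["profiles"].values()
        ]
    )
    riskprofile_df.to_csv(outdir / "riskprofile.csv", index=False)
    (outdir / "run_log.txt").write_text("\n".join(results["log"]) + "\n")
    results["outdir"] = outdir
    return results
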