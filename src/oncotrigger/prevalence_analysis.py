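"""Tabulation and analysis of detected trigger events.

Outputs mirror the standard reporting of claims-based trigger studies:
per-trigger prevalence over *exposed* denominators (patients with at least
one eligible treatment during follow-up), an any-trigger row over the full
stratum, the 0 / 1 / 2+ events-per-patient distribution, small-cell
suppression for released tables, group comparisons (chi-square for
categorical covariates, Wilcoxon rank-sum for continuous ones), and a
PPV-weighted estimate of the underlying adverse-event burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ANY_TRIGGER = "any_trigger"
ALL_STRATA = "ALL"
DEFAULT_SUPPRESSION_THRESHOLD = 11
SUPPRESSED_DISPLAY = "< 11 events"

# Overall chart-review PPVs from the developmental study; trigger-specific
# values are not public and should be supplied via config for fidelity.
DEFAULT_PPV_AE = 0.48
DEFAULT_PPV_PREVENTABLE = 0.18


@dataclass
class PrevalenceCell:
    cancer_type: str  # specific type or "ALL"
    metastatic: str  # "yes" / "no" / "ALL"
    trigger_id: str  # specific trigger or "any_trigger"
    numerator: int
    denominator: int
    suppressed: bool = False

    @property
    def rate(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def display(self) -> str:
        if self.suppressed:
            return SUPPRESSED_DISPLAY
        if self.rate is None:
            return "undefined"
        return f"{100 * self.rate:.1f}% ({self.numerator}/{self.denominator})"


def _strata(cohort_df: pd.DataFrame) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = [(ALL_STRATA, ALL_STRATA)]
    for ctype in sorted(cohort_df["cancer_type"].unique()):
        out.append((ctype, ALL_STRATA))
        for met in ("no", "yes"):
            out.append((ctype, met))
    for met in ("no", "yes"):
        out.append((ALL_STRATA, met))
    return out


def _stratum_mask(cohort_df: pd.DataFrame, ctype: str, met: str) -> pd.Series:
    mask = pd.Series(True, index=cohort_df.index)
    if ctype != ALL_STRATA:
        mask &= cohort_df["cancer_type"] == ctype
    if met != ALL_STRATA:
        mask &= cohort_df["metastatic"] == (met == "yes")
    return mask


def tabulate_prevalence(
    events_df: pd.DataFrame,
    exposure_flags_df: pd.DataFrame,
    cohort_df: pd.DataFrame,
    trigger_ids=None,
) -> list[PrevalenceCell]:
    """Prevalence cells per stratum x trigger, plus the any-trigger row.

    ``cohort_df`` holds one row per included patient (patient_id,
    cancer_type, metastatic). Per-trigger denominators are exposed-patient
    counts; the any-trigger denominator is the whole stratum. Numerators
    count distinct patients with >= 1 deduplicated event.
    """
    if trigger_ids is None:
        trigger_ids = sorted(exposure_flags_df["trigger_id"].unique())
    patients_with: dict[str, set[str]] = {t: set() for t in trigger_ids}
    any_with: set[str] = set()
    for row in events_df.itertuples(index=False):
        patients_with.setdefault(row.trigger_id, set()).add(row.patient_id)
        any_with.add(row.patient_id)
    exposed: dict[str, set[str]] = {t: set() for t in trigger_ids}
    for row in exposure_flags_df.itertuples(index=False):
        if row.exposed:
            exposed.setdefault(row.trigger_id, set()).add(row.patient_id)

    cells: list[PrevalenceCell] = []
    for ctype, met in _strata(cohort_df):
        stratum_ids = set(
            cohort_df.loc[_stratum_mask(cohort_df, ctype, met), "patient_id"]
        )
        cells.append(
            PrevalenceCell(
                cancer_type=ctype,
                metastatic=met,
                trigger_id=ANY_TRIGGER,
                numerator=len(any_with & stratum_ids),
                denominator=len(stratum_ids),
            )
        )
        for tid in trigger_ids:
            denom = exposed.get(tid, set()) & stratum_ids
            cells.append(
                PrevalenceCell(
                    cancer_type=ctype,
                    metastatic=met,
                    trigger_id=tid,
                    numerator=len(patients_with.get(tid, set()) & denom),
                    denominator=len(denom),
                )
            )
    return cells


def suppress_small_cells(
    cells: list[PrevalenceCell],
    threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
) -> list[PrevalenceCell]:
    """Flag cells with 0 < numerator < threshold for masked display.

    Zero cells and cells at/above the threshold stay unmasked; machine
    fields are retained on the cell but the display value is masked and
    exported aggregates should exclude suppressed cells.
    """
    for cell in cells:
        cell.suppressed = 0 < cell.numerator < threshold
    return cells


def cells_to_frame(cells: list[PrevalenceCell], suppress: bool = True) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "cancer_type": c.cancer_type,
                "metastatic": c.metastatic,
                "trigger_id": c.trigger_id,
                "numerator": None if (suppress and c.suppressed) else c.numerator,
                "denominator": c.denominator,
                "rate_pct": None
                if (suppress and c.suppressed) or c.rate is None
                else round(100 * c.rate, 1),
                "display": c.display if suppress else (
                    f"{100 * c.rate:.1f}% ({c.numerator}/{c.denominator})"
                    if c.rate is not None
                    else "undefined"
                ),
            }
        )
    return pd.DataFrame(rows)


def trigger_count_distribution(
    events_df: pd.DataFrame, cohort_df: pd.DataFrame
) -> pd.DataFrame:
    """Shares of patients with 0, 1, and 2+ deduplicated events per stratum."""
    counts = events_df.groupby("patient_id").size() if len(events_df) else pd.Series(dtype=int)
    rows = []
    for ctype, met in _strata(cohort_df):
        ids = cohort_df.loc[_stratum_mask(cohort_df, ctype, met), "patient_id"]
        n = len(ids)
        k = counts.reindex(ids).fillna(0).astype(int)
        n0 = int((k == 0).sum())
        n1 = int((k == 1).sum())
        n2 = int((k >= 2).sum())
        rows.append(
            {
                "cancer_type": ctype,
                "metastatic": met,
                "n": n,
                "n_zero": n0,
                "n_one": n1,
                "n_two_plus": n2,
                "pct_zero": round(100 * n0 / n, 1) if n else None,
                "pct_one": round(100 * n1 / n, 1) if n else None,
                "pct_two_plus": round(100 * n2 / n, 1) if n else None,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BurdenEstimate:
    """PPV-weighted expected adverse-event burden.

    ``expected_aes`` and ``expected_preventable`` are expectation sums
    (events per trigger times that trigger's PPV). The percent-of-patients
    figures use the independence approximation
    ``1 - prod_t (1 - ppv_t)^{k_t}`` per patient, averaged over the cohort.
    """

    n_patients: int
    n_events: int
    expected_aes: float
    expected_preventable: float
    pct_patients_with_ae: float
    pct_patients_with_preventable: float


def ppv_adjust(
    events_df: pd.DataFrame,
    n_patients: int,
    ppv_table: dict[str, tuple[float, float]] | None = None,
    default_ppv: tuple[float, float] = (DEFAULT_PPV_AE, DEFAULT_PPV_PREVENTABLE),
) -> BurdenEstimate:
    """Weight event counts by per-trigger PPVs to estimate true AE burden.

    ``ppv_table`` maps trigger_id to (ppv_ae, ppv_preventable); triggers
    absent from the table fall back to the overall defaults.
    """
    ppv_table = ppv_table or {}
    for tid, (a, p) in ppv_table.items():
        if not (0 <= a <= 1 and 0 <= p <= 1):
            raise ValueError(f"PPV for {tid} outside [0, 1]")
    if not all(0 <= v <= 1 for v in default_ppv):
        raise ValueError("default PPV outside [0, 1]")

    expected_aes = 0.0
    expected_prev = 0.0
    per_patient_ae: dict[str, float] = {}
    per_patient_prev: dict[str, float] = {}
    if len(events_df):
        grouped = events_df.groupby(["patient_id", "trigger_id"]).size()
        for (pid, tid), k in grouped.items():
            ppv_ae, ppv_prev = ppv_table.get(tid, default_ppv)
            expected_aes += k * ppv_ae
            expected_prev += k * ppv_prev
            per_patient_ae[pid] = per_patient_ae.get(pid, 1.0) * (1 - ppv_ae) ** k
            per_patient_prev[pid] = per_patient_prev.get(pid, 1.0) * (1 - ppv_prev) ** k

    p_ae = sum(1 - v for v in per_patient_ae.values())
    p_prev = sum(1 - v for v in per_patient_prev.values())
    return BurdenEstimate(
        n_patients=n_patients,
        n_events=int(len(events_df)),
        expected_aes=expected_aes,
        expected_preventable=expected_prev,
        pct_patients_with_ae=100 * p_ae / n_patients if n_patients else 0.0,
        pct_patients_with_preventable=100 * p_prev / n_patients if n_patients else 0.0,
    )


def compare_groups(
    covariates_df: pd.DataFrame,
    group_col: str = "any_trigger",
    categorical=(),
    continuous=(),
) -> pd.DataFrame:
    """Compare covariates between patients with and without any trigger.

    Categorical covariates get a Pearson chi-square on the contingency
    table (no continuity correction); continuous ones a two-sample Wilcoxon
    rank-sum with normal approximation and tie correction. P-values are
    unadjusted. Degenerate tables (an empty row or column, or an empty
    group) are skipped with a warning row.
    """
    rows = []
    groups = covariates_df[group_col].astype(bool)
    for col in categorical:
        table = pd.crosstab(covariates_df[col], groups)
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append(
                {"covariate": col, "test": "chi_square", "statistic": np.nan,
                 "p_value": np.nan, "note": "degenerate table; skipped"}
            )
            continue
        stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append(
            {"covariate": col, "test": "chi_square", "statistic": float(stat),
             "p_value": float(p), "note": f"dof={dof}"}
        )
    for col in continuous:
        a = covariates_df.loc[groups, col].dropna().to_numpy(dtype=float)
        b = covariates_df.loc[~groups, col].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            rows.append(
                {"covariate": col, "test": "wilcoxon_rank_sum",
                 "statistic": np.nan, "p_value": np.nan,
                 "note": "empty group; skipped"}
            )
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append(
            {"covariate": col, "test": "wilcoxon_rank_sum",
             "statistic": float(res.statistic), "p_value": float(res.pvalue),
             "note": ""}
        )
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p_value", "note"])
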