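"""The trigger detection engine.

Detection proceeds in four stages, composed by :func:`detect`:

1. **find_candidates** — scan each patient's claims for trigger code
   matches. A multi-clause trigger (e.g. fever plus neutropenia) yields a
   candidate on date *d* when every clause has a match in
   ``[d, d + co_occurrence_days]`` and *d* itself is a clause match — so the
   event date is the earliest clause date and all clause dates are pairwise
   within the co-occurrence window.
2. **apply_constraints** — trigger-specific filters: present-on-admission
   logic, provider specialty, new-use-only medication starts, not-same-day-
   as-surgery, and the within-30-days-of-index-surgery rule for
   reoperation.
3. **link_exposure** — a candidate becomes an event only when an eligible
   cancer-directed treatment precedes it within the trigger's lookback
   window. The window is half-open, ``(exposure, exposure + lookback]``:
   same-day codes do not link, which keeps an index surgery's own claims
   from firing surgical triggers. The event is linked to the latest
   qualifying exposure (ties broken chemotherapy > surgery > radiation).
4. **dedup_persistence** — greedy left-to-right collapse of repeat codes:
   an event is suppressed when a retained event of the same patient and
   trigger lies within the persistence window before it.

Events are confined to follow-up and to days the patient is enrolled; all
tie-breaks are total orders, so identical inputs give identical output.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

from .claims_model import ClaimsBundle, DRUG
from .codebook import Codebook, TriggerDefinition, match_code
from .cohort_builder import CohortRecord
from .treatment_classifier import ExposureEvent

logger = logging.getLogger(__name__)

_EXPOSURE_PRIORITY = {"chemotherapy": 0, "surgery": 1, "radiation": 2}


@dataclass(frozen=True)
class _Match:
    """One code match feeding a trigger clause."""

    date: dt.date
    clause_idx: int
    code: str
    system: str
    poa: str | None  # None for non-dx matches
    specialty: str | None
    claim_id: str


@dataclass
class TriggerCandidate:
    patient_id: str
    trigger_id: str
    event_date: dt.date
    clause_dates: tuple[dt.date, ...]
    matches: tuple[_Match, ...]  # the matches at the chosen clause dates

    @property
    def matched_codes(self) -> tuple[tuple[str, str], ...]:
        return tuple(dict.fromkeys((m.code, m.system) for m in self.matches))


@dataclass(frozen=True)
class TriggerEvent:
    patient_id: str
    trigger_id: str
    event_date: dt.date
    clause_dates: tuple[dt.date, ...]
    matched_codes: tuple[tuple[str, str], ...]
    linked_exposure_type: str
    linked_exposure_date: dt.date
    days_since_exposure: int


class _Matcher:
    """Memoized (system, code) -> [(trigger_id, clause_idx)] lookup."""

    def __init__(self, definitions: dict[str, TriggerDefinition]):
        self.definitions = definitions
        self._cache: dict[tuple[str, str], tuple[tuple[str, int], ...]] = {}

    def lookup(self, code: str, system: str) -> tuple[tuple[str, int], ...]:
        key = (system, code)
        hit = self._cache.get(key)
        if hit is None:
            out = []
            for tid, definition in self.definitions.items():
                for ci, clause in enumerate(definition.clauses):
                    if any(match_code(code, system, cs) for cs in clause):
                        out.append((tid, ci))
            hit = tuple(out)
            self._cache[key] = hit
        return hit


def _collect_matches(
    bundle: ClaimsBundle, matcher: _Matcher
) -> dict[tuple[str, str], list[_Match]]:
    """All clause matches, keyed by (patient_id, trigger_id)."""
    out: dict[tuple[str, str], list[_Match]] = {}
    for claim in bundle.medical:
        for dx in claim.dx_codes:
            for tid, ci in matcher.lookup(dx.code, dx.system):
                out.setdefault((claim.patient_id, tid), []).append(
                    _Match(
                        date=claim.service_date,
                        clause_idx=ci,
                        code=dx.code,
                        system=dx.system,
                        poa=dx.poa,
                        specialty=claim.provider_specialty,
                        claim_id=claim.claim_id,
                    )
                )
        for proc in claim.proc_codes:
            for tid, ci in matcher.lookup(proc.code, proc.system):
                out.setdefault((claim.patient_id, tid), []).append(
                    _Match(
                        date=claim.service_date,
                        clause_idx=ci,
                        code=proc.code,
                        system=proc.system,
                        poa=None,
                        specialty=claim.provider_specialty,
                        claim_id=claim.claim_id,
                    )
                )
    for fill in bundle.pharmacy:
        for tid, ci in matcher.lookup(fill.generic_name, DRUG):
            out.setdefault((fill.patient_id, tid), []).append(
                _Match(
                    date=fill.fill_date,
                    clause_idx=ci,
                    code=fill.generic_name,
                    system=DRUG,
                    poa=None,
                    specialty=None,
                    claim_id=fill.claim_id,
                )
            )
    return out


def find_candidates(
    bundle: ClaimsBundle, definitions: dict[str, TriggerDefinition]
) -> list[TriggerCandidate]:
    """One candidate per (patient, trigger, event date).

    Single-clause triggers yield one candidate per distinct matching claim
    date. For multi-clause triggers the event date is the earliest clause
    date of a co-occurring set (see module docstring).
    """
    matcher = _Matcher(definitions)
    grouped = _collect_matches(bundle, matcher)
    candidates: list[TriggerCandidate] = []
    for (pid, tid), matches in sorted(grouped.items()):
        definition = definitions[tid]
        n_clauses = len(definition.clauses)
        window = dt.timedelta(days=definition.co_occurrence_days)
        by_clause: dict[int, dict[dt.date, list[_Match]]] = {}
        for m in matches:
            by_clause.setdefault(m.clause_idx, {}).setdefault(m.date, []).append(m)
        if len(by_clause) < n_clauses:
            continue
        anchor_dates = sorted({m.date for m in matches})
        for d in anchor_dates:
            chosen: list[tuple[dt.date, list[_Match]]] = []
            ok = True
            for ci in range(n_clauses):
                dates = [
                    cd for cd in by_clause[ci] if d <= cd <= d + window
                ]
                if not dates:
                    ok = False
                    break
                first = min(dates)
                chosen.append((first, by_clause[ci][first]))
            if not ok:
                continue
            if min(cd for cd, _ in chosen) != d:
                continue  # d is not the earliest clause date of this set
            candidates.append(
                TriggerCandidate(
                    patient_id=pid,
                    trigger_id=tid,
                    event_date=d,
                    clause_dates=tuple(cd for cd, _ in chosen),
                    matches=tuple(m for _, ms in chosen for m in ms),
                )
            )
    return candidates


@dataclass
class ConstraintContext:
    """Everything the trigger-specific filters need to see."""

    exposures_by_patient: dict[str, list[ExposureEvent]]
    pharmacy_by_patient: dict[str, list]
    cohort_by_patient: dict[str, CohortRecord]
    codebook: Codebook
    _warned: set[str] = field(default_factory=set)


def _index_surgery_date(ctx: ConstraintContext, pid: str) -> dt.date | None:
    rec = ctx.cohort_by_patient.get(pid)
    if rec is None or rec.index_date is None:
        return None
    dates = [
        e.date
        for e in ctx.exposures_by_patient.get(pid, ())
        if e.exposure_type == "surgery" and e.date >= rec.index_date
    ]
    return min(dates) if dates else None


def apply_constraints(
    candidates: list[TriggerCandidate], ctx: ConstraintContext
) -> list[TriggerCandidate]:
    """Drop candidates failing their trigger's special constraints."""
    out: list[TriggerCandidate] = []
    for cand in candidates:
        definition = ctx.codebook.triggers[cand.trigger_id]
        keep = True
        for flag in sorted(definition.constraints):
            if flag == "requires_not_poa":
                dx_matches = [m for m in cand.matches if m.poa is not None]
                if not any(m.poa == "no" for m in dx_matches):
                    if all(m.poa == "unknown" for m in dx_matches):
                        if cand.trigger_id not in ctx._warned:
                            ctx._warned.add(cand.trigger_id)
                            logger.warning(
                                "%s requires present-on-admission flags but "
                                "the data carries none; candidates dropped",
                                cand.trigger_id,
                            )
                    keep = False
            elif flag.startswith("requires_specialty:"):
                wanted = flag.split(":", 1)[1].lower()
                specialties = {
                    (m.specialty or "").lower() for m in cand.matches
                }
                if wanted not in specialties:
                    keep = False
            elif flag == "new_use_only":
                lookback = ctx.codebook.new_use_lookback_days
                start = cand.event_date - dt.timedelta(days=lookback)
                drug_sets = [
                    cs
                    for clause in definition.clauses
                    for cs in clause
                    if cs.system == DRUG
                ]
                for fill in ctx.pharmacy_by_patient.get(cand.patient_id, ()):
                    if start <= fill.fill_date < cand.event_date and any(
                        match_code(fill.generic_name, DRUG, cs)
                        for cs in drug_sets
                    ):
                        keep = False
                        break
            elif flag == "not_same_day_as_surgery":
                for ev in ctx.exposures_by_patient.get(cand.patient_id, ()):
                    if ev.exposure_type == "surgery" and ev.date == cand.event_date:
                        keep = False
                        break
            elif flag == "post_index_surgery_30d":
                anchor = _index_surgery_date(ctx, cand.patient_id)
                if anchor is None:
                    keep = False
                else:
                    delta = (cand.event_date - anchor).days
                    if not (1 <= delta <= 30):
                        keep = False
            elif flag == "post_radiation_only":
                pass  # expressed through the exposure rule's eligible types
            if not keep:
                break
        if keep:
            out.append(cand)
    return out


def link_exposure(
    candidates: list[TriggerCandidate],
    exposures_by_patient: dict[str, list[ExposureEvent]],
    codebook: Codebook,
    cohort_by_patient: dict[str, CohortRecord],
    bundle: ClaimsBundle,
) -> list[TriggerEvent]:
    """Attach each candidate to its latest qualifying exposure, or drop it."""
    events: list[TriggerEvent] = []
    for cand in candidates:
        rec = cohort_by_patient.get(cand.patient_id)
        if rec is None or not rec.included:
            continue
        if not (rec.index_date <= cand.event_date <= rec.followup_end):
            continue
        if not bundle.enrolled_on(cand.patient_id, cand.event_date):
            continue
        rule = codebook.rules[cand.trigger_id]
        lookback = dt.timedelta(days=rule.lookback_days)
        qualifying = [
            ev
            for ev in exposures_by_patient.get(cand.patient_id, ())
            if ev.exposure_type in rule.eligible_exposures
            and ev.date < cand.event_date <= ev.date + lookback
        ]
        if not qualifying:
            continue
        linked = min(
            qualifying,
            key=lambda ev: (-ev.date.toordinal(), _EXPOSURE_PRIORITY[ev.exposure_type]),
        )
        events.append(
            TriggerEvent(
                patient_id=cand.patient_id,
                trigger_id=cand.trigger_id,
                event_date=cand.event_date,
                clause_dates=cand.clause_dates,
                matched_codes=cand.matched_codes,
                linked_exposure_type=linked.exposure_type,
                linked_exposure_date=linked.date,
                days_since_exposure=(cand.event_date - linked.date).days,
            )
        )
    return events


def dedup_persistence(
    events: list[TriggerEvent], codebook: Codebook
) -> list[TriggerEvent]:
    """Greedy left-to-right persistence-window deduplication."""
    ordered = sorted(events, key=lambda e: (e.patient_id, e.trigger_id, e.event_date))
    kept: list[TriggerEvent] = []
    last_kept: dict[tuple[str, str], dt.date] = {}
    for ev in ordered:
        key = (ev.patient_id, ev.trigger_id)
        persistence = codebook.rules[ev.trigger_id].persistence_days
        prev = last_kept.get(key)
        if prev is not None and (ev.event_date - prev).days <= persistence:
            continue
        kept.append(ev)
        last_kept[key] = ev.event_date
    return kept


def exposure_flags(
    cohort: list[CohortRecord],
    exposures_by_patient: dict[str, list[ExposureEvent]],
    codebook: Codebook,
) -> dict[tuple[str, str], bool]:
    """Per (patient, trigger): has an eligible-type exposure in follow-up.

    This is the exposed denominator of the prevalence table.
    """
    flags: dict[tuple[str, str], bool] = {}
    for rec in cohort:
        if not rec.included:
            continue
        types_present = {
            ev.exposure_type
            for ev in exposures_by_patient.get(rec.patient_id, ())
            if rec.index_date <= ev.date <= rec.followup_end
        }
        for tid, rule in codebook.rules.items():
            flags[(rec.patient_id, tid)] = bool(
                types_present & rule.eligible_exposures
            )
    return flags


def detect(
    bundle: ClaimsBundle,
    cohort: list[CohortRecord],
    exposures: list[ExposureEvent],
    codebook: Codebook,
) -> tuple[list[TriggerEvent], dict[tuple[str, str], bool]]:
    """Full detection: candidates -> constraints -> linkage -> dedup.

    Returns the deduplicated exposure-linked events plus the per-(patient,
    trigger) exposed flags.
    """
    expo_by_patient: dict[str, list[ExposureEvent]] = {}
    for ev in exposures:
        expo_by_patient.setdefault(ev.patient_id, []).append(ev)
    pharm_by_patient: dict[str, list] = {}
    for fill in bundle.pharmacy:
        pharm_by_patient.setdefault(fill.patient_id, []).append(fill)
    cohort_by_patient = {rec.patient_id: rec for rec in cohort}

    candidates = find_candidates(bundle, codebook.triggers)
    ctx = ConstraintContext(
        exposures_by_patient=expo_by_patient,
        pharmacy_by_patient=pharm_by_patient,
        cohort_by_patient=cohort_by_patient,
        codebook=codebook,
    )
    candidates = apply_constraints(candidates, ctx)
    events = link_exposure(
        candidates, expo_by_patient, codebook, cohort_by_patient, bundle
    )
    events = dedup_persistence(events, codebook)
    flags = exposure_flags(cohort, expo_by_patient, codebook)
    return events, flags
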