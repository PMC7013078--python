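"""Independent brute-force oracles for the test suite.

These re-implement the detection semantics directly as quadratic scans —
claims x definitions x exposures per patient — without using the engine's
indexing, candidate generation or linkage code, so they can serve as an
independent check that the engine implements the stated rules.
"""

from __future__ import annotations

import datetime as dt


def brute_match(code: str, system: str, cs) -> bool:
    """Regex-free scan: exact-or-prefix within one system, minus exclusions."""
    if system != cs.system or code in cs.exclusions:
        return False
    if code in cs.exact:
        return True
    for p in cs.prefixes:
        if code[: len(p)] == p:
            return True
    return False


def enumerate_covered_days(spans) -> set[dt.date]:
    """Day-by-day enumeration of enrollment coverage."""
    days: set[dt.date] = set()
    for s in spans:
        d = s.start_date
        while d <= s.end_date:
            days.add(d)
            d += dt.timedelta(days=1)
    return days


def greedy_dedup_dates(dates, persistence_days: int):
    """Reference left-to-right persistence dedup over a sorted date train."""
    kept = []
    for d in sorted(dates):
        if kept and (d - kept[-1]).days <= persistence_days:
            continue
        kept.append(d)
    return kept


def _patient_match_records(claims, fills, definition):
    """(date, clause_idx, poa, specialty) for every clause match."""
    recs = []
    for c in claims:
        for dx in c.dx_codes:
            for ci, clause in enumerate(definition.clauses):
                for cs in clause:
                    if brute_match(dx.code, dx.system, cs):
                        recs.append((c.service_date, ci, dx.poa, c.provider_specialty))
                        break
        for proc in c.proc_codes:
            for ci, clause in enumerate(definition.clauses):
                for cs in clause:
                    if brute_match(proc.code, proc.system, cs):
                        recs.append((c.service_date, ci, None, c.provider_specialty))
                        break
    for f in fills:
        for ci, clause in enumerate(definition.clauses):
            for cs in clause:
                if brute_match(f.generic_name, "DRUG", cs):
                    recs.append((f.fill_date, ci, None, None))
                    break
    return recs


def oracle_detect(bundle, cohort, exposures, book):
    """Quadratic-scan reference detection.

    Returns the set of
    (patient_id, trigger_id, event_date, linked_type, linked_date) tuples
    after constraints, exposure linkage and persistence dedup.
    """
    out = set()
    for rec in cohort:
        if not rec.included:
            continue
        pid = rec.patient_id
        claims = [c for c in bundle.medical if c.patient_id == pid]
        fills = [f for f in bundle.pharmacy if f.patient_id == pid]
        expos = [e for e in exposures if e.patient_id == pid]
        spans = bundle.enrollment.get(pid, [])
        surgery_days = {e.date for e in expos if e.exposure_type == "surgery"}
        index_surgeries = sorted(
            d for d in surgery_days if d >= rec.index_date
        )
        index_surgery = index_surgeries[0] if index_surgeries else None

        for tid, definition in book.triggers.items():
            rule = book.rules[tid]
            recs = _patient_match_records(claims, fills, definition)
            n_clauses = len(definition.clauses)
            window = dt.timedelta(days=definition.co_occurrence_days)

            # candidate dates: earliest clause date of a co-occurring set
            all_dates = sorted({r[0] for r in recs})
            candidates = []
            for d in all_dates:
                per_clause = []
                for ci in range(n_clauses):
                    sel = [r for r in recs if r[1] == ci and d <= r[0] <= d + window]
                    per_clause.append(sel)
                if any(not sel for sel in per_clause):
                    continue
                earliest = min(min(r[0] for r in sel) for sel in per_clause)
                if earliest != d:
                    continue
                # records at the chosen (earliest-per-clause) dates
                chosen = []
                for sel in per_clause:
                    first = min(r[0] for r in sel)
                    chosen.extend(r for r in sel if r[0] == first)
                candidates.append((d, chosen))

            linked = []
            for d, chosen in candidates:
                ok = True
                for flag in definition.constraints:
                    if flag == "requires_not_poa":
                        dx_recs = [r for r in chosen if r[2] is not None]
                        ok = any(r[2] == "no" for r in dx_recs)
                    elif flag.startswith("requires_specialty:"):
                        wanted = flag.split(":", 1)[1].lower()
                        ok = any((r[3] or "").lower() == wanted for r in chosen)
                    elif flag == "new_use_only":
                        drug_sets = [
                            cs
                            for clause in definition.clauses
                            for cs in clause
                            if cs.system == "DRUG"
                        ]
                        lb = dt.timedelta(days=book.new_use_lookback_days)
                        ok = not any(
                            d - lb <= f.fill_date < d
                            and any(
                                brute_match(f.generic_name, "DRUG", cs)
                                for cs in drug_sets
                            )
                            for f in fills
                        )
                    elif flag == "not_same_day_as_surgery":
                        ok = d not in surgery_days
                    elif flag == "post_index_surgery_30d":
                        ok = index_surgery is not None and 1 <= (
                            d - index_surgery
                        ).days <= 30
                    if not ok:
                        break
                if not ok:
                    continue
                if not (rec.index_date <= d <= rec.followup_end):
                    continue
                if not any(s.start_date <= d <= s.end_date for s in spans):
                    continue
                qualifying = [
                    e
                    for e in expos
                    if e.exposure_type in rule.eligible_exposures
                    and e.date < d <= e.date + dt.timedelta(days=rule.lookback_days)
                ]
                if not qualifying:
                    continue
                prio = {"chemotherapy": 0, "surgery": 1, "radiation": 2}
                best = sorted(
                    qualifying,
                    key=lambda e: (-e.date.toordinal(), prio[e.exposure_type]),
                )[0]
                linked.append((d, best.exposure_type, best.date))

            persistence = rule.persistence_days
            last = None
            for d, etype, edate in sorted(linked):
                if last is not None and (d - last).days <= persistence:
                    continue
                out.add((pid, tid, d, etype, edate))
                last = d
    return out
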