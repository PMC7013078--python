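import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotrigger import classify_exposures, build_cohort, detect
from oncotrigger.trigger_engine import (
    ConstraintContext,
    apply_constraints,
    dedup_persistence,
    find_candidates,
    link_exposure,
)
from oncotrigger.cohort_builder import CohortRecord

from conftest import d
from helpers import bundle_of, dx_claim, fill, patient, proc_claim
from oracle import greedy_dedup_dates, oracle_detect

INDEX = d("2010-04-15")


def _chemo_patient(extra_medical=(), pharmacy=(), birth_year=1950, sex="female"):
    """Breast patient, chemo on index day, one year of follow-up."""
    medical = [
        dx_claim("p1", d("2010-03-01"), "1749"),
        proc_claim("p1", INDEX, "96413"),
    ] + list(extra_medical)
    return bundle_of([patient("p1", birth_year=birth_year, sex=sex)], medical, pharmacy)


def _detect(bundle, book):
    exposures = classify_exposures(bundle, book)
    cohort = build_cohort(bundle, exposures, book)
    return detect(bundle, cohort, exposures, book)


class TestFindCandidates:
    def test_compound_clause_pair_forms_candidate_at_earliest_date(self, book):
        b = _chemo_patient(
            [
                dx_claim("p1", INDEX + dt.timedelta(days=10), "7806"),
                dx_claim("p1", INDEX + dt.timedelta(days=12), "2880"),
            ]
        )
        cands = [
            c
            for c in find_candidates(b, book.triggers)
            if c.trigger_id == "neutropenic_fever"
        ]
        assert len(cands) == 1
        assert cands[0].event_date == INDEX + dt.timedelta(days=10)
        assert set(cands[0].clause_dates) == {
            INDEX + dt.timedelta(days=10),
            INDEX + dt.timedelta(days=12),
        }

    def test_lone_fever_clause_yields_no_candidate(self, book):
        b = _chemo_patient([dx_claim("p1", INDEX + dt.timedelta(days=10), "7806")])
        assert not [
            c
            for c in find_candidates(b, book.triggers)
            if c.trigger_id == "neutropenic_fever"
        ]

    def test_clauses_beyond_co_occurrence_window_do_not_pair(self, book):
        b = _chemo_patient(
            [
                dx_claim("p1", INDEX + dt.timedelta(days=10), "7806"),
                dx_claim("p1", INDEX + dt.timedelta(days=18), "2880"),
            ]
        )
        assert not [
            c
            for c in find_candidates(b, book.triggers)
            if c.trigger_id == "neutropenic_fever"
        ]

    def test_clause_order_is_symmetric(self, book):
        """Neutropenia first, fever second still forms one candidate."""
        b = _chemo_patient(
            [
                dx_claim("p1", INDEX + dt.timedelta(days=12), "7806"),
                dx_claim("p1", INDEX + dt.timedelta(days=10), "2880"),
            ]
        )
        cands = [
            c
            for c in find_candidates(b, book.triggers)
            if c.trigger_id == "neutropenic_fever"
        ]
        assert len(cands) == 1
        assert cands[0].event_date == INDEX + dt.timedelta(days=10)


class TestConstraints:
    def _ctx(self, bundle, book):
        exposures = classify_exposures(bundle, book)
        cohort = build_cohort(bundle, exposures, book)
        by_p = {}
        for e in exposures:
            by_p.setdefault(e.patient_id, []).append(e)
        pharm = {}
        for f in bundle.pharmacy:
            pharm.setdefault(f.patient_id, []).append(f)
        return ConstraintContext(
            exposures_by_patient=by_p,
            pharmacy_by_patient=pharm,
            cohort_by_patient={r.patient_id: r for r in cohort},
            codebook=book,
        )

    def test_poa_yes_acute_kidney_injury_dropped(self, book):
        day = INDEX + dt.timedelta(days=10)
        b = _chemo_patient(
            [dx_claim("p1", day, "5849", poa="yes", setting="inpatient",
                      admit=day, discharge=day + dt.timedelta(days=2))]
        )
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "elevated_creatinine"]
        assert cands and not apply_constraints(cands, self._ctx(b, book))

    def test_poa_no_acute_kidney_injury_kept(self, book):
        day = INDEX + dt.timedelta(days=10)
        b = _chemo_patient(
            [dx_claim("p1", day, "5849", poa="no", setting="inpatient",
                      admit=day, discharge=day + dt.timedelta(days=2))]
        )
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "elevated_creatinine"]
        assert apply_constraints(cands, self._ctx(b, book))

    @pytest.mark.parametrize(
        "specialty, kept", [("Nephrologist", True), ("cardiology", False)]
    )
    def test_consult_requires_nephrology_specialty(self, book, specialty, kept):
        day = INDEX + dt.timedelta(days=10)
        b = _chemo_patient([proc_claim("p1", day, "99244", specialty=specialty)])
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "nephrology_consult"]
        assert bool(apply_constraints(cands, self._ctx(b, book))) is kept

    def test_anticoagulation_prior_fill_blocks_new_use(self, book):
        day = INDEX + dt.timedelta(days=20)
        b = _chemo_patient(
            pharmacy=[
                fill("p1", day - dt.timedelta(days=30), "warfarin"),
                fill("p1", day, "warfarin"),
            ]
        )
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "anticoagulation"]
        kept = apply_constraints(cands, self._ctx(b, book))
        # the later fill is blocked; the first fill (no prior use) survives
        assert [c.event_date for c in kept] == [day - dt.timedelta(days=30)]

    def test_nasogastric_tube_suppressed_on_surgery_day(self, book):
        b = bundle_of(
            [patient("p1")],
            [
                dx_claim("p1", d("2010-03-01"), "1749"),
                proc_claim("p1", INDEX, "19303"),
                proc_claim("p1", INDEX, "43753"),
                proc_claim("p1", INDEX + dt.timedelta(days=5), "43753"),
            ],
        )
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "nasogastric_tube"]
        kept = apply_constraints(cands, self._ctx(b, book))
        assert [c.event_date for c in kept] == [INDEX + dt.timedelta(days=5)]

    def test_return_to_or_only_within_30_days_of_index_surgery(self, book):
        b = bundle_of(
            [patient("p1")],
            [
                dx_claim("p1", d("2010-03-01"), "1749"),
                proc_claim("p1", INDEX, "19303"),
                proc_claim("p1", INDEX + dt.timedelta(days=10), "49406"),
                proc_claim("p1", INDEX + dt.timedelta(days=40), "49406"),
            ],
        )
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "return_to_or"]
        kept = apply_constraints(cands, self._ctx(b, book))
        assert [c.event_date for c in kept] == [INDEX + dt.timedelta(days=10)]


class TestLinkExposure:
    def _events(self, b, book, extra_days):
        exposures = classify_exposures(b, book)
        cohort = build_cohort(b, exposures, book)
        by_p = {}
        for e in exposures:
            by_p.setdefault(e.patient_id, []).append(e)
        cands = [c for c in find_candidates(b, book.triggers)
                 if c.trigger_id == "abnormal_bicarbonate"]
        return link_exposure(
            cands, by_p, book, {r.patient_id: r for r in cohort}, b
        )

    @pytest.mark.parametrize(
        "offset, linked",
        [(0, False), (1, True), (30, True), (31, False)],
    )
    def test_half_open_window_boundaries(self, book, offset, linked):
        """Same-day codes never link; the boundary day does."""
        b = _chemo_patient(
            [dx_claim("p1", INDEX + dt.timedelta(days=offset), "7906")]
        )
        events = self._events(b, book, offset)
        assert bool(events) is linked
        if linked:
            assert events[0].days_since_exposure == offset

    def test_chemo_trigger_with_only_surgery_exposure_discarded(self, book):
        b = bundle_of(
            [patient("p1")],
            [
                dx_claim("p1", d("2010-03-01"), "1749"),
                proc_claim("p1", INDEX, "19303"),  # surgery only
                dx_claim("p1", INDEX + dt.timedelta(days=10), "7806"),
                dx_claim("p1", INDEX + dt.timedelta(days=10), "2880"),
            ],
        )
        events, _ = _detect(b, book)
        assert not [e for e in events if e.trigger_id == "neutropenic_fever"]

    def test_linked_to_latest_qualifying_exposure(self, book):
        b = _chemo_patient(
            [
                proc_claim("p1", INDEX + dt.timedelta(days=21), "96413"),
                dx_claim("p1", INDEX + dt.timedelta(days=30), "7906"),
            ]
        )
        events = self._events(b, book, 30)
        assert events[0].linked_exposure_date == INDEX + dt.timedelta(days=21)
        assert events[0].days_since_exposure == 9

    def test_event_during_enrollment_gap_suppressed(self, book):
        from oncotrigger import EnrollmentSpan

        gap_day = INDEX + dt.timedelta(days=10)
        b = bundle_of(
            [patient("p1")],
            [
                dx_claim("p1", d("2010-03-01"), "1749"),
                proc_claim("p1", INDEX, "96413"),
                dx_claim("p1", gap_day, "7906"),
            ],
            enrollment=[
                EnrollmentSpan("p1", d("2000-01-01"), gap_day - dt.timedelta(days=1)),
                EnrollmentSpan("p1", gap_day + dt.timedelta(days=5), d("2020-12-31")),
            ],
        )
        events, _ = _detect(b, book)
        assert not events


class TestDedup:
    def test_greedy_chain_5_20_50(self, book):
        base = d("2010-06-01")
        b = _chemo_patient(
            [
                proc_claim("p1", base - dt.timedelta(days=10), "96413"),
                proc_claim("p1", base + dt.timedelta(days=15), "96413"),
                proc_claim("p1", base + dt.timedelta(days=40), "96413"),
                dx_claim("p1", base, "7906"),
                dx_claim("p1", base + dt.timedelta(days=15), "7906"),
                dx_claim("p1", base + dt.timedelta(days=45), "7906"),
            ]
        )
        events, _ = _detect(b, book)
        dates = [e.event_date for e in events if e.trigger_id == "abnormal_bicarbonate"]
        assert dates == [base, base + dt.timedelta(days=45)]

    @given(
        st.lists(st.integers(0, 200), min_size=1, max_size=30),
        st.integers(1, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_greedy_dedup_matches_oracle_on_random_trains(
        self, offsets, persistence
    ):
        from oncotrigger.codebook import ExposureRule

        base = d("2010-01-01")
        dates = sorted({base + dt.timedelta(days=o) for o in offsets})
        from oncotrigger.trigger_engine import TriggerEvent

        events = [
            TriggerEvent(
                patient_id="p1", trigger_id="t", event_date=dd,
                clause_dates=(dd,), matched_codes=(("X", "ICD9Dx"),),
                linked_exposure_type="chemotherapy",
                linked_exposure_date=dd - dt.timedelta(days=1),
                days_since_exposure=1,
            )
            for dd in dates
        ]

        class FakeBook:
            rules = {
                "t": ExposureRule(
                    trigger_id="t",
                    eligible_exposures=frozenset({"chemotherapy"}),
                    lookback_days=30,
                    persistence_days=persistence,
                )
            }

        kept = dedup_persistence(events, FakeBook())
        assert [e.event_date for e in kept] == greedy_dedup_dates(dates, persistence)


class TestEngineProperties:
    def test_engine_equals_brute_force_oracle_on_synthetic_patients(
        self, book, sim500
    ):
        bundle, _ = sim500
        exposures = classify_exposures(bundle, book)
        cohort = build_cohort(bundle, exposures, book)
        events, _ = detect(bundle, cohort, exposures, book)
        got = {
            (e.patient_id, e.trigger_id, e.event_date,
             e.linked_exposure_type, e.linked_exposure_date)
            for e in events
        }
        assert got == oracle_detect(bundle, cohort, exposures, book)

    def test_lookback_monotonicity(self, book, sim500):
        """Raising every lookback never loses an event pre-dedup."""
        import dataclasses

        bundle, _ = sim500
        exposures = classify_exposures(bundle, book)
        cohort = build_cohort(bundle, exposures, book)

        def pre_dedup(bk):
            by_p = {}
            for e in exposures:
                by_p.setdefault(e.patient_id, []).append(e)
            pharm = {}
            for f in bundle.pharmacy:
                pharm.setdefault(f.patient_id, []).append(f)
            cands = find_candidates(bundle, bk.triggers)
            ctx = ConstraintContext(by_p, pharm,
                                    {r.patient_id: r for r in cohort}, bk)
            cands = apply_constraints(cands, ctx)
            evs = link_exposure(cands, by_p, bk,
                                {r.patient_id: r for r in cohort}, bundle)
            return {(e.patient_id, e.trigger_id, e.event_date) for e in evs}

        wide = dataclasses.replace(
            book,
            rules={
                t: dataclasses.replace(r, lookback_days=r.lookback_days + 30)
                for t, r in book.rules.items()
            },
        )
        assert pre_dedup(book) <= pre_dedup(wide)

    def test_dedup_count_nonincreasing_in_persistence(self, book, sim500):
        import dataclasses

        bundle, _ = sim500
        exposures = classify_exposures(bundle, book)
        cohort = build_cohort(bundle, exposures, book)
        counts = []
        for p in (5, 15, 30, 60):
            bk = dataclasses.replace(
                book,
                rules={
                    t: dataclasses.replace(r, persistence_days=p)
                    for t, r in book.rules.items()
                },
            )
            events, _ = detect(bundle, cohort, exposures, bk)
            counts.append(len(events))
        assert counts == sorted(counts, reverse=True)

    def test_no_event_outside_followup_or_unexposed(self, book, analyzed500):
        res = analyzed500
        rec_by_pid = {r.patient_id: r for r in res["cohort"]}
        flags = res["flags"]
        for e in res["events"]:
            rec = rec_by_pid[e.patient_id]
            assert rec.index_date <= e.event_date <= rec.followup_end
            assert flags[(e.patient_id, e.trigger_id)]

    def test_determinism_identical_inputs_identical_events(self, book, sim500):
        bundle, _ = sim500
        exposures = classify_exposures(bundle, book)
        cohort = build_cohort(bundle, exposures, book)
        e1, f1 = detect(bundle, cohort, exposures, book)
        e2, f2 = detect(bundle, cohort, exposures, book)
        assert e1 == e2 and f1 == f2
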