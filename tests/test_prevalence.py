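import numpy as np
import pandas as pd
import pytest

from oncotrigger import (
    compare_groups,
    ppv_adjust,
    suppress_small_cells,
    tabulate_prevalence,
    trigger_count_distribution,
)
from oncotrigger.prevalence_analysis import (
    ANY_TRIGGER,
    PrevalenceCell,
    cells_to_frame,
)


def _flag_frame(n, numerator, trigger="blood_transfusion", cancer="lung", met=True):
    """Cohort of n patients, `numerator` of them with one event each."""
    pids = [f"p{i}" for i in range(n)]
    cohort = pd.DataFrame(
        {"patient_id": pids, "cancer_type": cancer, "metastatic": met}
    )
    flags = pd.DataFrame(
        {"patient_id": pids, "trigger_id": trigger, "exposed": True}
    )
    events = pd.DataFrame(
        {
            "patient_id": pids[:numerator],
            "trigger_id": trigger,
            "event_date": pd.Timestamp("2010-06-01"),
        }
    )
    return events, flags, cohort


class TestTabulatePrevalence:
    def test_rate_and_display_match_fraction(self):
        events, flags, cohort = _flag_frame(30169, 15157)
        cells = tabulate_prevalence(events, flags, cohort)
        any_cell = next(
            c for c in cells
            if c.trigger_id == ANY_TRIGGER and c.cancer_type == "lung"
            and c.metastatic == "yes"
        )
        assert (any_cell.numerator, any_cell.denominator) == (15157, 30169)
        assert round(100 * any_cell.rate, 1) == 50.2

    def test_zero_numerator_is_zero_pct(self):
        events, flags, cohort = _flag_frame(100, 0)
        cells = tabulate_prevalence(events, flags, cohort)
        cell = next(c for c in cells if c.trigger_id == "blood_transfusion"
                    and c.cancer_type == "lung" and c.metastatic == "yes")
        assert cell.numerator == 0 and cell.rate == 0.0

    def test_unexposed_patients_not_in_trigger_denominator(self):
        events, flags, cohort = _flag_frame(10, 2)
        flags.loc[5:, "exposed"] = False
        cells = tabulate_prevalence(events, flags, cohort)
        cell = next(c for c in cells if c.trigger_id == "blood_transfusion"
                    and c.cancer_type == "lung" and c.metastatic == "yes")
        assert cell.denominator == 5
        any_cell = next(c for c in cells if c.trigger_id == ANY_TRIGGER
                        and c.cancer_type == "lung" and c.metastatic == "yes")
        assert any_cell.denominator == 10  # full stratum

    def test_cells_equal_brute_force_recount_on_synthetic_run(self, analyzed500):
        res = analyzed500
        cells = tabulate_prevalence(
            res["events_df"], res["flags_df"], res["included_df"]
        )
        included = res["included_df"]
        events = res["events_df"]
        flags = res["flags_df"]
        for cell in cells:
            ids = set(included["patient_id"])
            if cell.cancer_type != "ALL":
                ids &= set(
                    included.loc[included.cancer_type == cell.cancer_type,
                                 "patient_id"]
                )
            if cell.metastatic != "ALL":
                ids &= set(
                    included.loc[
                        included.metastatic == (cell.metastatic == "yes"),
                        "patient_id",
                    ]
                )
            if cell.trigger_id == ANY_TRIGGER:
                denom = ids
                num = ids & set(events["patient_id"])
            else:
                denom = ids & set(
                    flags.loc[
                        (flags.trigger_id == cell.trigger_id) & flags.exposed,
                        "patient_id",
                    ]
                )
                num = denom & set(
                    events.loc[events.trigger_id == cell.trigger_id, "patient_id"]
                )
            assert (cell.numerator, cell.denominator) == (len(num), len(denom))
            assert cell.numerator <= cell.denominator


class TestSuppression:
    @pytest.mark.parametrize(
        "numerator, masked", [(0, False), (1, True), (8, True), (10, True),
                              (11, False), (50, False)]
    )
    def test_threshold_boundary(self, numerator, masked):
        cell = PrevalenceCell("lung", "yes", "nasogastric_tube", numerator, 1000)
        suppress_small_cells([cell])
        assert cell.suppressed is masked
        if masked:
            assert cell.display == "< 11 events"

    def test_raising_threshold_never_unmasks(self):
        cells = [
            PrevalenceCell("lung", "yes", "t", n, 1000) for n in range(0, 40)
        ]
        masked_low = {c.numerator for c in suppress_small_cells(cells, 11) if c.suppressed}
        masked_high = {c.numerator for c in suppress_small_cells(cells, 20) if c.suppressed}
        assert masked_low <= masked_high

    def test_threshold_one_masks_nothing(self):
        cells = [PrevalenceCell("lung", "yes", "t", n, 1000) for n in (0, 1, 5)]
        assert not any(c.suppressed for c in suppress_small_cells(cells, 1))

    def test_suppressed_cells_blank_in_export(self):
        cells = suppress_small_cells(
            [PrevalenceCell("lung", "yes", "t", 5, 1000)]
        )
        frame = cells_to_frame(cells, suppress=True)
        assert frame.loc[0, "numerator"] is None or pd.isna(frame.loc[0, "numerator"])
        assert frame.loc[0, "display"] == "< 11 events"


class TestDistribution:
    def test_all_eventless(self):
        events = pd.DataFrame(columns=["patient_id", "trigger_id", "event_date"])
        cohort = pd.DataFrame(
            {"patient_id": ["a", "b"], "cancer_type": "lung", "metastatic": False}
        )
        dist = trigger_count_distribution(events, cohort)
        row = dist[(dist.cancer_type == "ALL") & (dist.metastatic == "ALL")].iloc[0]
        assert (row.pct_zero, row.pct_one, row.pct_two_plus) == (100.0, 0.0, 0.0)

    def test_three_events_count_once_in_two_plus(self):
        events = pd.DataFrame(
            {"patient_id": ["a"] * 3, "trigger_id": ["t1", "t2", "t3"],
             "event_date": pd.Timestamp("2010-01-01")}
        )
        cohort = pd.DataFrame(
            {"patient_id": ["a", "b"], "cancer_type": "lung", "metastatic": False}
        )
        dist = trigger_count_distribution(events, cohort)
        row = dist[(dist.cancer_type == "ALL") & (dist.metastatic == "ALL")].iloc[0]
        assert row.n_two_plus == 1 and row.n_one == 0

    def test_shares_sum_to_100_in_every_stratum(self, analyzed500):
        dist = trigger_count_distribution(
            analyzed500["events_df"], analyzed500["included_df"]
        )
        nonempty = dist[dist.n > 0]
        total = nonempty.pct_zero + nonempty.pct_one + nonempty.pct_two_plus
        assert ((total - 100).abs() <= 0.1 + 1e-9).all()
        # stratum Ns partition the cohort
        per_type = dist[(dist.metastatic == "ALL") & (dist.cancer_type != "ALL")]
        assert per_type.n.sum() == len(analyzed500["included_df"])


class TestPpvAdjust:
    def _events(self, counts):
        rows = []
        for tid, k in counts.items():
            for i in range(k):
                rows.append({"patient_id": f"{tid}_{i}", "trigger_id": tid,
                             "event_date": pd.Timestamp("2010-01-01")})
        return pd.DataFrame(rows, columns=["patient_id", "trigger_id", "event_date"])

    def test_100_events_at_overall_ppv_gives_48_expected(self):
        burden = ppv_adjust(self._events({"t": 100}), n_patients=1000)
        assert burden.expected_aes == pytest.approx(48.0)
        assert burden.expected_preventable == pytest.approx(18.0)

    def test_zero_ppv_zero_expected(self):
        burden = ppv_adjust(
            self._events({"t": 50}), 1000, ppv_table={"t": (0.0, 0.0)}
        )
        assert burden.expected_aes == 0.0

    def test_linear_sum_over_triggers(self):
        burden = ppv_adjust(
            self._events({"a": 10, "b": 20}), 1000,
            ppv_table={"a": (0.5, 0.1), "b": (0.25, 0.05)},
        )
        assert burden.expected_aes == pytest.approx(10.0)

    def test_preventable_never_exceeds_total(self, analyzed500):
        burden = analyzed500["burden"]
        assert burden.expected_preventable <= burden.expected_aes

    def test_ppv_outside_unit_interval_fatal(self):
        with pytest.raises(ValueError):
            ppv_adjust(self._events({"t": 1}), 10, ppv_table={"t": (1.2, 0.1)})


class TestCompareGroups:
    def test_independent_2x2_statistic_zero(self):
        df = pd.DataFrame(
            {"g": [True] * 20 + [False] * 20, "x": (["a"] * 10 + ["b"] * 10) * 2}
        )
        out = compare_groups(df, group_col="g", categorical=["x"])
        assert out.loc[0, "statistic"] == pytest.approx(0.0)

    def test_2x2_matches_closed_form(self):
        # table (20,10 / 10,20): chi2 = sum (O-E)^2/E = 6.667
        g = [True] * 30 + [False] * 30
        x = ["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20
        out = compare_groups(pd.DataFrame({"g": g, "x": x}),
                             group_col="g", categorical=["x"])
        assert out.loc[0, "statistic"] == pytest.approx(6.667, abs=1e-3)

    def test_identical_samples_rank_sum_p_near_one(self):
        df = pd.DataFrame(
            {"g": [True] * 50 + [False] * 50, "y": list(range(50)) * 2}
        )
        out = compare_groups(df, group_col="g", continuous=["y"])
        assert out.loc[0, "p_value"] > 0.9

    def test_degenerate_table_skipped_with_note(self):
        df = pd.DataFrame({"g": [True] * 5 + [False] * 5, "x": ["a"] * 10})
        out = compare_groups(df, group_col="g", categorical=["x"])
        assert np.isnan(out.loc[0, "statistic"])
        assert "skipped" in out.loc[0, "note"]
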