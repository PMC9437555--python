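"""Telemetry event processing: daily statuses, first-week rule, monthly rollup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adheremon import (
    aggregate_monthly,
    apply_first_week_exclusion,
    derive_daily_status,
    events_to_monthly,
    parse_event_log,
)
from adheremon.events import (
    CATEGORY_GOOD,
    CATEGORY_POOR,
    CATEGORY_UNOBSERVED,
    STATUS_MISSED,
    STATUS_MISSING,
    STATUS_TAKEN,
    EventLogError,
)


class TestParseEventLog:
    def test_maps_fields_directly(self, events_csv_factory):
        df = parse_event_log(events_csv_factory([("P001", "2014-03-02T08:15:00", "intake")]))
        assert list(df.columns) == ["participant_id", "timestamp", "signal"]
        assert df.loc[0, "participant_id"] == "P001"
        assert df.loc[0, "timestamp"] == pd.Timestamp("2014-03-02 08:15:00")
        assert df.loc[0, "signal"] == "intake"

    def test_header_only_gives_empty_frame(self, events_csv_factory):
        df = parse_event_log(events_csv_factory([]))
        assert len(df) == 0
        assert df["timestamp"].dtype.kind == "M"

    def test_duplicate_rows_are_retained(self, events_csv_factory):
        rows = [("P1", "2014-01-01T08:00:00", "intake")] * 2
        assert len(parse_event_log(events_csv_factory(rows))) == 2

    def test_sorts_by_participant_then_time(self, events_csv_factory):
        rows = [("P2", "2014-01-01T09:00:00", "intake"),
                ("P1", "2014-01-02T08:00:00", "heartbeat"),
                ("P1", "2014-01-01T08:00:00", "intake")]
        df = parse_event_log(events_csv_factory(rows))
        assert list(df["participant_id"]) == ["P1", "P1", "P2"]
        assert df["timestamp"].iloc[0] < df["timestamp"].iloc[1]

    @pytest.mark.parametrize(
        "row, match",
        [(("P1", "2014-01-01T08:00:00", "opened"), "unknown signal"),
         (("P1", "not-a-time", "intake"), "malformed timestamp")],
    )
    def test_bad_rows_rejected_with_row_number(self, events_csv_factory, row, match):
        with pytest.raises(EventLogError, match=f"{match}.*row 1"):
            parse_event_log(events_csv_factory([row]))


def _day_events(signals, pid="P1", day="2014-01-01"):
    return parse_event_log(
        "participant_id,timestamp,signal\n"
        + "".join(f"{pid},{day}T{8 + i:02d}:00:00,{s}\n" for i, s in enumerate(signals))
    )


class TestDeriveDailyStatus:
    @pytest.mark.parametrize(
        "signals, expected",
        [(["intake", "intake", "intake"], STATUS_TAKEN),   # only first opening counts
         (["heartbeat"], STATUS_MISSED),
         (["none"], STATUS_MISSING),
         (["heartbeat", "intake"], STATUS_TAKEN),
         (["none", "intake"], STATUS_TAKEN),
         (["heartbeat", "none"], STATUS_MISSED),
         ([], STATUS_MISSING)],
    )
    def test_signal_combinations(self, signals, expected):
        """Intake dominates heartbeat dominates none/absence, matching a
        brute-force evaluation of the coding rules over all signal subsets."""
        daily = derive_daily_status(_day_events(signals), "2014-01-01", span_days=1)
        assert daily.loc[0, "status"] == expected

    def test_brute_force_over_all_subsets(self):
        for mask in range(8):
            signals = [s for bit, s in enumerate(["intake", "heartbeat", "none"])
                       if mask >> bit & 1]
            expected = (STATUS_TAKEN if "intake" in signals
                        else STATUS_MISSED if "heartbeat" in signals
                        else STATUS_MISSING)
            daily = derive_daily_status(_day_events(signals), "2014-01-01", 1)
            assert daily.loc[0, "status"] == expected

    def test_one_record_per_day_in_span(self):
        daily = derive_daily_status(_day_events(["intake"]), "2014-01-01", span_days=5)
        assert list(daily["day_index"]) == [1, 2, 3, 4, 5]
        assert list(daily["status"]) == [STATUS_TAKEN] + [STATUS_MISSING] * 4

    def test_event_before_issue_date_rejected(self):
        with pytest.raises(ValueError, match="precedes issue date"):
            derive_daily_status(_day_events(["intake"]), "2014-01-02", 5)


class TestFirstWeekExclusion:
    def _daily(self, n, status=STATUS_TAKEN):
        return pd.DataFrame({"participant_id": "P1",
                             "day_index": np.arange(1, n + 1),
                             "status": status})

    def test_reindexes_from_day_eight(self):
        out = apply_first_week_exclusion(self._daily(37))
        assert len(out) == 30
        assert list(out["day_index"]) == list(range(1, 31))

    def test_exactly_seven_days_becomes_empty(self):
        assert len(apply_first_week_exclusion(self._daily(7))) == 0

    def test_eighth_day_survives_with_status(self):
        daily = self._daily(8, status=STATUS_MISSING)
        daily.loc[7, "status"] = STATUS_TAKEN
        out = apply_first_week_exclusion(daily)
        assert len(out) == 1
        assert out.loc[0, "day_index"] == 1
        assert out.loc[0, "status"] == STATUS_TAKEN

    def test_double_exclusion_equals_fortnight_exclusion(self):
        daily = self._daily(45)
        twice = apply_first_week_exclusion(apply_first_week_exclusion(daily))
        once = apply_first_week_exclusion(daily, excluded_days=14)
        pd.testing.assert_frame_equal(twice, once)


class TestAggregateMonthly:
    def _daily(self, statuses):
        return pd.DataFrame({"participant_id": "P1",
                             "day_index": np.arange(1, len(statuses) + 1),
                             "status": statuses})

    @pytest.mark.parametrize(
        "n_missed, n_missing, min_obs, expected",
        [(4, 0, 15, CATEGORY_GOOD),      # 4 missed days is still good
         (5, 0, 15, CATEGORY_POOR),      # >4 missed days is poor
         (0, 30, 15, CATEGORY_UNOBSERVED),
         (5, 10, 15, CATEGORY_POOR)],    # 20 observed >= 15, 5 missed > 4
    )
    def test_dichotomization_boundaries(self, n_missed, n_missing, min_obs, expected):
        statuses = ([STATUS_MISSED] * n_missed + [STATUS_MISSING] * n_missing
                    + [STATUS_TAKEN] * (30 - n_missed - n_missing))
        out = aggregate_monthly(self._daily(statuses), min_observed_days=min_obs)
        assert len(out) == 1
        assert out.loc[0, "category"] == expected
        assert out.loc[0, "days_missed"] == n_missed
        assert out.loc[0, "days_observed"] == 30 - n_missing

    def test_partial_trailing_window_dropped(self):
        out = aggregate_monthly(self._daily([STATUS_TAKEN] * 45))
        assert list(out["month_index"]) == [1]

    def test_conservation_observed_plus_missing(self):
        statuses = [STATUS_TAKEN] * 10 + [STATUS_MISSING] * 12 + [STATUS_MISSED] * 8
        out = aggregate_monthly(self._daily(statuses))
        assert int(out.loc[0, "days_observed"]) + 12 == 30


@st.composite
def event_streams(draw):
    """Random per-day signal multisets over spans of up to 60 days."""
    span = draw(st.integers(min_value=8, max_value=60))
    days = draw(st.lists(
        st.lists(st.sampled_from(["intake", "heartbeat", "none"]), max_size=3),
        min_size=span, max_size=span))
    return span, days


@given(event_streams())
def test_monthly_counts_match_bruteforce_recount(stream):
    """Pipeline monthly missed/observed counts equal a day-by-day recount."""
    span, days = stream
    rows = []
    for d, signals in enumerate(days):
        for i, s in enumerate(signals):
            rows.append(("P1", f"2014-01-{1:02d}T08:00:00", s))
            rows[-1] = ("P1",
                        (pd.Timestamp("2014-01-01") + pd.Timedelta(days=d, hours=8 + i)
                         ).isoformat(), s)
    csv = "participant_id,timestamp,signal\n" + "".join(
        f"{p},{t},{s}\n" for p, t, s in rows)
    events = parse_event_log(csv)
    roster = pd.DataFrame({"participant_id": ["P1"], "issue_date": ["2014-01-01"]})
    monthly = events_to_monthly(events, roster, span)

    # independent oracle: re-derive statuses directly from the day lists
    def status_of(signals):
        if "intake" in signals:
            return STATUS_TAKEN
        if "heartbeat" in signals:
            return STATUS_MISSED
        return STATUS_MISSING

    statuses = [status_of(s) for s in days][7:]
    n_months = len(statuses) // 30
    assert len(monthly) == n_months
    for m in range(n_months):
        window = statuses[m * 30:(m + 1) * 30]
        assert monthly.loc[m, "days_missed"] == window.count(STATUS_MISSED)
        assert monthly.loc[m, "days_observed"] == 30 - window.count(STATUS_MISSING)


@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=59))
def test_repeat_intakes_do_not_change_monthly_summary(factor, taken_day):
    """Multiplying the intake signals on a taken day leaves the rollup unchanged."""
    span = 67
    base_rows = [("P1", (pd.Timestamp("2014-01-01")
                         + pd.Timedelta(days=d, hours=9)).isoformat(), "intake")
                 for d in range(span) if d % 3 != 0]

    def monthly_from(rows):
        csv = "participant_id,timestamp,signal\n" + "".join(
            f"{p},{t},{s}\n" for p, t, s in rows)
        roster = pd.DataFrame({"participant_id": ["P1"], "issue_date": ["2014-01-01"]})
        return events_to_monthly(parse_event_log(csv), roster, span)

    dup_rows = base_rows + [
        ("P1", (pd.Timestamp("2014-01-01")
                + pd.Timedelta(days=taken_day, hours=10 + k)).isoformat(), "intake")
        for k in range(factor) if taken_day % 3 != 0]
    pd.testing.assert_frame_equal(monthly_from(base_rows), monthly_from(dup_rows))
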