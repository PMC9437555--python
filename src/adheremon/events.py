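"""Electronic-monitoring (pill-box) event processing.

Instrumented pill containers transmit one of three signals: ``intake`` when
the box is opened (a proxy for a dose taken), ``heartbeat`` when the device
is alive but was not opened, and ``none`` when the device is malfunctioning.
This module converts a raw event stream into daily dose-taken indicators and
then into dichotomized monthly adherence (good vs. poor at the >4
missed-days-per-month guideline cut-off), applying the standard cleaning
rules for this kind of telemetry:

* the first week after device issue is excluded (novelty period with
  unreliable repeated openings);
* on any later day, only the first opening counts — repeat openings are
  ignored;
* malfunction days ("none" signal, or no signal at all) are missing data.

Months are consecutive, non-overlapping 30-day windows counted from the day
after the excluded first week; a window with fewer than ``min_observed_days``
classifiable days is labelled ``unobserved``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

SIGNAL_INTAKE = "intake"
SIGNAL_HEARTBEAT = "heartbeat"
SIGNAL_NONE = "none"
VALID_SIGNALS = frozenset({SIGNAL_INTAKE, SIGNAL_HEARTBEAT, SIGNAL_NONE})

STATUS_TAKEN = "taken"
STATUS_MISSED = "missed"
STATUS_MISSING = "missing"

CATEGORY_GOOD = "good"
CATEGORY_POOR = "poor"
CATEGORY_UNOBSERVED = "unobserved"

#: columns of a parsed event frame
EVENT_COLUMNS = ["participant_id", "timestamp", "signal"]
#: columns of a daily-status frame
DAILY_COLUMNS = ["participant_id", "day_index", "status"]
#: columns of a monthly-adherence frame
MONTHLY_COLUMNS = ["participant_id", "month_index", "days_observed", "days_missed", "category"]


class EventLogError(ValueError):
    """Raised for malformed rows in a device event log."""


def parse_event_log(source) -> pd.DataFrame:
    """Read a delimited device event log into a validated event frame.

    Parameters
    ----------
    source
        Path, file object or string buffer holding CSV text with a header
        row and columns ``participant_id,timestamp,signal`` (ISO-8601
        timestamps; signal one of ``intake``/``heartbeat``/``none``).

    Returns
    -------
    pandas.DataFrame
        Columns ``participant_id`` (str), ``timestamp`` (datetime64),
        ``signal`` (str), sorted by (participant_id, timestamp).  Duplicate
        signals are retained — de-duplication to one opening per day happens
        in :func:`derive_daily_status`.

    Raises
    ------
    EventLogError
        If a required column is absent, a timestamp does not parse, or a
        signal label is unknown.  The error names the offending data row
        (1-based, excluding the header).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    missing_cols = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise EventLogError(f"event log missing required column(s): {missing_cols}")
    df = df[EVENT_COLUMNS].copy()
    if df.empty:
        out = df.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"])
        return out.reset_index(drop=True)

    bad_signal = ~df["signal"].isin(VALID_SIGNALS)
    if bad_signal.any():
        row = int(np.flatnonzero(bad_signal.to_numpy())[0]) + 1
        raise EventLogError(
            f"unknown signal {df['signal'].iloc[row - 1]!r} at data row {row}; "
            f"expected one of {sorted(VALID_SIGNALS)}"
        )
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 1
        raise EventLogError(
            f"malformed timestamp {df['timestamp'].iloc[row - 1]!r} at data row {row}"
        )
    df["timestamp"] = ts
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    return df.reset_index(drop=True)


def derive_daily_status(
    events: pd.DataFrame, issue_date, span_days: int
) -> pd.DataFrame:
    """Collapse one participant's events into one status per day.

    A day is ``taken`` if it carries at least one ``intake`` signal (only
    the first opening counts, so repeats are irrelevant); ``missed`` if it
    has a ``heartbeat`` but no intake (the device was alive and unopened);
    ``missing`` otherwise — i.e. the day only has a malfunction ("none")
    signal, or no signal of any kind.  A day with both a heartbeat and a
    "none" signal counts as ``missed``: the device was demonstrably alive
    and unopened at some point that day.

    Parameters
    ----------
    events
        Parsed events for a single participant (may be empty).
    issue_date
        Date the device was issued; day 1 of the observation span.
    span_days
        Number of days to cover; exactly one record per day is emitted.
    """
    if span_days < 1:
        raise ValueError("span_days must be >= 1")
    issue = pd.Timestamp(issue_date).normalize()
    if events.empty:
        pid = None
    else:
        ids = events["participant_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"events must belong to one participant, got {list(ids)}")
        pid = ids[0]
        day_index = (events["timestamp"].dt.normalize() - issue).dt.days + 1
        if (day_index < 1).any():
            first = events.loc[day_index < 1, "timestamp"].iloc[0]
            raise ValueError(f"event at {first} precedes issue date {issue.date()}")

    status = np.full(span_days, STATUS_MISSING, dtype=object)
    if pid is not None:
        in_span = day_index <= span_days
        sig = events.loc[in_span, "signal"].to_numpy()
        day = day_index[in_span].to_numpy() - 1
        has_heartbeat = np.zeros(span_days, dtype=bool)
        has_intake = np.zeros(span_days, dtype=bool)
        has_intake[day[sig == SIGNAL_INTAKE]] = True
        has_heartbeat[day[sig == SIGNAL_HEARTBEAT]] = True
        status[has_heartbeat] = STATUS_MISSED
        status[has_intake] = STATUS_TAKEN

    return pd.DataFrame(
        {
            "participant_id": pid if pid is not None else pd.NA,
            "day_index": np.arange(1, span_days + 1),
            "status": status,
        }
    )


def derive_daily_cohort(
    events: pd.DataFrame, roster: pd.DataFrame, span_days: int
) -> pd.DataFrame:
    """Per-participant :func:`derive_daily_status` over a roster.

    ``roster`` needs columns ``participant_id`` and ``issue_date``.  Roster
    participants with no events at all get an all-``missing`` span.
    """
    frames = []
    grouped = dict(iter(events.groupby("participant_id", sort=False))) if not events.empty else {}
    for _, row in roster.iterrows():
        pid = row["participant_id"]
        ev = grouped.get(pid)
        daily = derive_daily_status(
            ev if ev is not None else events.iloc[0:0], row["issue_date"], span_days
        )
        daily["participant_id"] = pid
        frames.append(daily)
    return pd.concat(frames, ignore_index=True)


def apply_first_week_exclusion(daily: pd.DataFrame, excluded_days: int = 7) -> pd.DataFrame:
    """Drop the first ``excluded_days`` days and re-index from day 1.

    The week after device issue carries unreliable repeated openings, so its
    data are removed; remaining days are renumbered so that month 1 starts
    on the first retained day.
    """
    out = daily[daily["day_index"] > excluded_days].copy()
    out["day_index"] = out["day_index"] - excluded_days
    return out.reset_index(drop=True)


def aggregate_monthly(
    daily: pd.DataFrame,
    window_days: int = 30,
    missed_threshold: int = 4,
    min_observed_days: int = 15,
) -> pd.DataFrame:
    """Aggregate daily statuses into dichotomized monthly adherence.

    Consecutive, non-overlapping windows of ``window_days`` days become
    months; only complete windows are emitted.  ``days_missed`` counts
    ``missed`` days, ``days_observed`` counts non-``missing`` days.  A month
    is ``unobserved`` when fewer than ``min_observed_days`` days are
    observed, ``poor`` when more than ``missed_threshold`` days were missed,
    and ``good`` otherwise.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    records = []
    for pid, grp in daily.groupby("participant_id", sort=False):
        span = int(grp["day_index"].max()) if len(grp) else 0
        n_months = span // window_days
        day = grp["day_index"].to_numpy()
        st = grp["status"].to_numpy()
        for m in range(1, n_months + 1):
            in_win = (day > (m - 1) * window_days) & (day <= m * window_days)
            w = st[in_win]
            observed = int(np.sum(w != STATUS_MISSING))
            missed = int(np.sum(w == STATUS_MISSED))
            if observed < min_observed_days:
                cat = CATEGORY_UNOBSERVED
            elif missed > missed_threshold:
                cat = CATEGORY_POOR
            else:
                cat = CATEGORY_GOOD
            records.append((pid, m, observed, missed, cat))
    return pd.DataFrame(records, columns=MONTHLY_COLUMNS)


@dataclass(frozen=True)
class EmPipelineConfig:
    """Knobs for the end-to-end event -> monthly derivation."""

    excluded_days: int = 7
    window_days: int = 30
    missed_threshold: int = 4
    min_observed_days: int = 15


def events_to_monthly(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    span_days: int,
    config: EmPipelineConfig = EmPipelineConfig(),
) -> pd.DataFrame:
    """Full pipeline: daily derivation, first-week exclusion, monthly rollup."""
    daily = derive_daily_cohort(events, roster, span_days)
    daily = apply_first_week_exclusion(daily, config.excluded_days)
    return aggregate_monthly(
        daily,
        window_days=config.window_days,
        missed_threshold=config.missed_threshold,
        min_observed_days=config.min_observed_days,
    )
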