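"""Derive monthly adherence from a pill-box event stream.

Builds a 67-day event log for one participant (7-day novelty run-in, then
a 30-day month with 5 missed days and one with 2), runs the cleaning rules
(first-week exclusion, first-opening-only, malfunction-as-missing) and
prints the dichotomized months.
"""

import pandas as pd

from adheremon import events_to_monthly, parse_event_log

rows = ["participant_id,timestamp,signal"]
for day in range(67):
    stamp = (pd.Timestamp("2014-03-01") + pd.Timedelta(days=day, hours=8)).isoformat()
    if day < 7:  # novelty period: several openings a day
        for h in range(3):
            rows.append(f"P001,{stamp[:11]}{8 + h:02d}:00:00,intake")
    elif 10 <= day < 15 and day != 12:  # four missed days in month 1
        rows.append(f"P001,{stamp},heartbeat")
    elif day == 20:  # device malfunction: missing, not missed
        rows.append(f"P001,{stamp},none")
    elif day == 12 or day == 40 or day == 41:  # more missed days
        rows.append(f"P001,{stamp},heartbeat")
    else:
        rows.append(f"P001,{stamp},intake")

events = parse_event_log("\n".join(rows) + "\n")
roster = pd.DataFrame({"participant_id": ["P001"], "issue_date": ["2014-03-01"]})
monthly = events_to_monthly(events, roster, span_days=67)
print(monthly.to_string(index=False))
print()
print("Month 1 has 5 missed days (>4) -> poor; its malfunction day counts as")
print("missing, not missed. Month 2 has 2 missed days -> good.")
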