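#!/usr/bin/env python
"""Call LH surges, patterns, ovulation days and fertile windows.

For each cycle and channel: find the peak maximum, estimate the baseline
from the two days before and after it, call elevated days (>30% of peak
amplitude and >2x baseline), classify the pattern, and — on the urine
channel — set ovulation day (day after the last elevated day) and the
6-day fertile window.

Reads results/normalized.csv, writes results/calls.csv.
"""

from pathlib import Path

from lhsurge import io
from lhsurge.preprocess import frame_to_series
from lhsurge.surge import call_cohort, calls_to_frame
from lhsurge.types import NONE, URINE

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series = frame_to_series(io.read_series_csv(RESULTS / "normalized.csv"))
    calls = call_cohort(series)
    frame = calls_to_frame(calls)
    frame.to_csv(RESULTS / "calls.csv", index=False)

    for channel, grp in frame.groupby("channel"):
        print(f"{channel}: pattern counts")
        print(grp["pattern"].value_counts().to_string())
    excluded = frame[frame["pattern"] == NONE]
    for row in excluded.itertuples(index=False):
        print(f"  excluded {row.participant_id}/{row.cycle_id} "
              f"[{row.channel}]: {row.flags or 'no surge'}")
    urine = frame[frame["channel"] == URINE].dropna(subset=["ovulation_day"])
    print(f"ovulation day called in {len(urine)} cycles "
          f"(median day {urine['ovulation_day'].median():.0f})")


if __name__ == "__main__":
    main()
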