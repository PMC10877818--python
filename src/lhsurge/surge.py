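"""Surge calling: baseline, elevated days, pattern, ovulation, fertile window.

The rules operate on raw normalized values with no smoothing or model
fitting:

* peak maximum — the observed day with the largest value (ties break to the
  earliest day);
* baseline — the mean over whichever of the four days {peak-2, peak-1,
  peak+1, peak+2} are observed (the peak day itself is excluded; at least
  one flank is required, otherwise the cycle is uncallable);
* a day is elevated iff its excess over baseline is greater than 30% of the
  peak amplitude AND its value is greater than twice the baseline, both
  comparisons strict;
* pattern — sharp single (one elevated day), broad single (one contiguous
  elevated run of >= 2 days), multiple (>= 2 runs separated by an observed
  non-elevated day), or none;
* ovulation day (urine channel) — the day after the last elevated day;
* fertile window — the 5 days before ovulation plus the ovulation day;
* first surge day — the earliest elevated day (the first day a home test
  would read positive).

"Peak amplitude" is read as the peak's excess over baseline
(``amplitude_convention='excess'``); the alternative reading, 30% of the
raw maximum value, is available as ``'raw'``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    BROAD_SINGLE,
    BaselineUndeterminedError,
    CycleSeries,
    EmptySeriesError,
    MULTIPLE,
    NONE,
    SHARP_SINGLE,
    SurgeCall,
    URINE,
)

FERTILE_WINDOW_DAYS = 6  # 5 days before ovulation + ovulation day

AMPLITUDE_CONVENTIONS = ("excess", "raw")


def find_peak_maximum(series: CycleSeries) -> int:
    """Observed day with the maximum value; ties break to the earliest day."""
    days, values = series.observed_days, series.observed_values
    if days.size == 0:
        raise EmptySeriesError(
            f"{series.participant_id}/{series.cycle_id}: no observed days"
        )
    return int(days[int(np.argmax(values))])


def estimate_baseline(series: CycleSeries, peak_day: int) -> tuple[float, int]:
    """Mean over the observed flanking days {peak-2, peak-1, peak+1, peak+2}.

    Returns (baseline, number of flank days used).
    """
    flanks = (peak_day - 2, peak_day - 1, peak_day + 1, peak_day + 2)
    vals = [series.value_on(d) for d in flanks if series.is_observed(d)]
    if not vals:
        raise BaselineUndeterminedError(
            f"{series.participant_id}/{series.cycle_id}: none of the four "
            f"days flanking the peak (day {peak_day}) is observed"
        )
    return float(np.mean(vals)), len(vals)


def detect_elevated_days(
    series: CycleSeries,
    baseline: float,
    peak_day: int,
    amplitude_convention: str = "excess",
) -> list[int]:
    """Days passing both surge conditions (strict comparisons)."""
    if amplitude_convention not in AMPLITUDE_CONVENTIONS:
        raise ValueError(f"unknown amplitude convention {amplitude_convention!r}")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    days, values = series.observed_days, series.observed_values
    peak_value = series.value_on(peak_day)
    if amplitude_convention == "excess":
        cond_amp = (values - baseline) > 0.30 * (peak_value - baseline)
    else:
        cond_amp = values > 0.30 * peak_value
    cond_base = values > 2.0 * baseline
    return [int(d) for d in days[cond_amp & cond_base]]


def classify_pattern(elevated_days, observed_days) -> str:
    """Pattern class from the run structure of the elevated-day set.

    Runs are contiguous in the sequence of *observed* days, so elevated
    days bridged only by missing days belong to the same run; 'multiple'
    requires an observed non-elevated day between runs.
    """
    elevated = sorted(elevated_days)
    if not elevated:
        return NONE
    index = {int(d): i for i, d in enumerate(sorted(observed_days))}
    runs = 1
    for a, b in zip(elevated, elevated[1:]):
        if index[b] - index[a] > 1:
            runs += 1
    if runs >= 2:
        return MULTIPLE
    return SHARP_SINGLE if len(elevated) == 1 else BROAD_SINGLE


def determine_ovulation_day(elevated_days, pattern: str) -> int | None:
    """The day after the last elevated day; absent when there is no surge."""
    if pattern == NONE or not elevated_days:
        return None
    return max(elevated_days) + 1


def fertile_window(ovulation_day: int) -> tuple[int, int]:
    """Inclusive 6-day range ending on the ovulation day."""
    return (ovulation_day - (FERTILE_WINDOW_DAYS - 1), ovulation_day)


def call_cycle(
    series: CycleSeries, amplitude_convention: str = "excess"
) -> SurgeCall:
    """Run the full calling procedure on one cycle series.

    Uncallable cycles (no observed days, baseline undetermined, no day
    passing both rules) come back as pattern 'none' with an explanatory
    flag; the cohort is never aborted.
    """
    flags: list[str] = []

    def _none_call(baseline=None, peak_day=None, n_flanks=0):
        return SurgeCall(
            participant_id=series.participant_id,
            cycle_id=series.cycle_id,
            channel=series.channel,
            baseline=baseline,
            peak_day=peak_day,
            elevated_days=(),
            pattern=NONE,
            first_surge_day=None,
            ovulation_day=None,
            fertile_window=None,
            n_baseline_days=n_flanks,
            flags=tuple(flags),
        )

    try:
        peak_day = find_peak_maximum(series)
    except EmptySeriesError:
        flags.append("no_observed_days")
        return _none_call()
    try:
        baseline, n_flanks = estimate_baseline(series, peak_day)
    except BaselineUndeterminedError:
        flags.append("baseline_undetermined")
        return _none_call(peak_day=peak_day)

    elevated = detect_elevated_days(series, baseline, peak_day,
                                    amplitude_convention)
    pattern = classify_pattern(elevated, series.observed_days)
    if pattern == NONE:
        flags.append("no_peak")
        return _none_call(baseline=baseline, peak_day=peak_day,
                          n_flanks=n_flanks)

    first_surge = min(elevated)
    ovulation = window = None
    if series.channel == URINE:
        ovulation = determine_ovulation_day(elevated, pattern)
        window = fertile_window(ovulation)
        if ovulation > int(series.days.max()):
            flags.append("ovulation_beyond_window")

    return SurgeCall(
        participant_id=series.participant_id,
        cycle_id=series.cycle_id,
        channel=series.channel,
        baseline=baseline,
        peak_day=peak_day,
        elevated_days=tuple(elevated),
        pattern=pattern,
        first_surge_day=first_surge,
        ovulation_day=ovulation,
        fertile_window=window,
        n_baseline_days=n_flanks,
        flags=tuple(flags),
    )


def call_cohort(
    series: dict[tuple[str, str, str], CycleSeries],
    amplitude_convention: str = "excess",
) -> dict[tuple[str, str, str], SurgeCall]:
    """Call every cycle series; keys are (participant, cycle, channel)."""
    return {
        key: call_cycle(s, amplitude_convention)
        for key, s in sorted(series.items())
    }


def calls_to_frame(calls: dict[tuple[str, str, str], SurgeCall]) -> pd.DataFrame:
    """One row per (cycle, channel) call, CSV-ready."""
    rows = []
    for (pid, cid, channel), c in sorted(calls.items()):
        rows.append(
            {
                "participant_id": pid,
                "cycle_id": cid,
                "channel": channel,
                "baseline": c.baseline,
                "peak_day": c.peak_day,
                "elevated_days": ";".join(map(str, c.elevated_days)),
                "pattern": c.pattern,
                "first_surge_day": c.first_surge_day,
                "ovulation_day": c.ovulation_day,
                "fertile_window_start": c.fertile_window[0] if c.fertile_window else None,
                "fertile_window_end": c.fertile_window[1] if c.fertile_window else None,
                "n_baseline_days": c.n_baseline_days,
                "flags": ";".join(c.flags),
            }
        )
    cols = ["participant_id", "cycle_id", "channel", "baseline", "peak_day",
            "elevated_days", "pattern", "first_surge_day", "ovulation_day",
            "fertile_window_start", "fertile_window_end", "n_baseline_days",
            "flags"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_calls(frame: pd.DataFrame) -> dict[tuple[str, str, str], SurgeCall]:
    """Inverse of :func:`calls_to_frame`."""

    def _opt_int(x):
        return None if pd.isna(x) else int(x)

    out: dict[tuple[str, str, str], SurgeCall] = {}
    for row in frame.itertuples(index=False):
        key = (row.participant_id, row.cycle_id, row.channel)
        elevated = tuple(
            int(d) for d in str(row.elevated_days).split(";")
            if d not in ("", "nan")
        ) if not pd.isna(row.elevated_days) else ()
        fw_start = _opt_int(row.fertile_window_start)
        fw_end = _opt_int(row.fertile_window_end)
        flags = tuple(
            f for f in str(row.flags).split(";") if f and f != "nan"
        ) if not pd.isna(row.flags) else ()
        out[key] = SurgeCall(
            participant_id=row.participant_id,
            cycle_id=row.cycle_id,
            channel=row.channel,
            baseline=None if pd.isna(row.baseline) else float(row.baseline),
            peak_day=_opt_int(row.peak_day),
            elevated_days=elevated,
            pattern=row.pattern,
            first_surge_day=_opt_int(row.first_surge_day),
            ovulation_day=_opt_int(row.ovulation_day),
            fertile_window=(fw_start, fw_end) if fw_start is not None else None,
            n_baseline_days=int(row.n_baseline_days),
            flags=flags,
        )
    return out
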