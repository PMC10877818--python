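"""Raw assay records -> normalized, QC-filtered cycle series.

The limit of detection (LOD) of each assay is the blank mean + 3 sigma;
measurements below it are replaced by the LOD itself.  A day on which both
the analyte and its normalizer read below their LODs is a failed collection
and is treated as missing downstream; missing days are never imputed.
Urinary LH is normalized by creatinine (uLH/Cr) and vaginal-discharge LH by
total extract protein (vLH/Pro), both in mIU per mg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import (
    CHANNELS,
    CycleSeries,
    DailySample,
    InsufficientDataError,
    QC_COLLECTION_FAILED,
    QC_MISSING,
    QC_OK,
    URINE,
    VAGINAL_DISCHARGE,
    ZeroNormalizerError,
)

# raw CSV column pairs (analyte, normalizer) per channel
CHANNEL_COLUMNS = {
    URINE: ("ulh", "creatinine"),
    VAGINAL_DISCHARGE: ("vlh", "total_protein"),
}


@dataclass(frozen=True)
class LodConfig:
    """Per-assay limits of detection on the raw concentration scale."""

    ulh: float = 0.0
    creatinine: float = 0.0
    vlh: float = 0.0
    total_protein: float = 0.0

    def for_channel(self, channel: str) -> tuple[float, float]:
        if channel == URINE:
            return self.ulh, self.creatinine
        if channel == VAGINAL_DISCHARGE:
            return self.vlh, self.total_protein
        raise ValueError(f"unknown channel {channel!r}")


def compute_lod(blank_measurements) -> float:
    """LOD by the 3-sigma method: blank mean + 3 x sample SD (n-1)."""
    arr = np.asarray(list(blank_measurements), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 blank measurements, got {arr.size}"
        )
    if np.any(arr < 0):
        raise ValueError("blank measurements must be nonnegative")
    return float(arr.mean() + 3.0 * arr.std(ddof=1))


def censor_below_lod(value: float, lod: float) -> tuple[float, bool]:
    """Substitute the LOD for a value strictly below it.

    Returns (value, substituted).  Values equal to the LOD pass unchanged:
    "lower than" is read strictly.
    """
    if value < 0:
        raise ValueError(f"negative measurement {value}")
    if lod < 0:
        raise ValueError(f"negative LOD {lod}")
    if value < lod:
        return lod, True
    return value, False


def qc_daily_sample(sample: DailySample) -> DailySample:
    """Mark a sample 'collection_failed' iff both assays read below LOD."""
    if sample.qc_status == QC_MISSING:
        return sample
    status = (
        QC_COLLECTION_FAILED
        if sample.analyte_below_lod and sample.normalizer_below_lod
        else QC_OK
    )
    return replace(sample, qc_status=status)


def normalize_cycle(samples: list[DailySample], channel: str) -> CycleSeries:
    """Normalized LH ratio per day; failed and missing days are unobserved.

    Samples must already be LOD-censored and QC'd, all from one cycle.
    """
    if not samples:
        raise InsufficientDataError("no samples for cycle")
    ids = {(s.participant_id, s.cycle_id) for s in samples}
    if len(ids) != 1:
        raise ValueError("samples span multiple cycles")
    ordered = sorted(samples, key=lambda s: s.day)
    days, values, observed = [], [], []
    for s in ordered:
        days.append(s.day)
        if s.qc_status != QC_OK:
            values.append(np.nan)
            observed.append(False)
            continue
        if s.normalizer_value == 0:
            raise ZeroNormalizerError(
                f"normalizer is zero on day {s.day} "
                f"({s.participant_id}/{s.cycle_id}); LOD substitution with a "
                "positive LOD prevents this"
            )
        values.append(s.analyte_value / s.normalizer_value)
        observed.append(True)
    pid, cid = next(iter(ids))
    return CycleSeries(
        participant_id=pid,
        cycle_id=cid,
        channel=channel,
        days=np.array(days),
        values=np.array(values),
        observed=np.array(observed),
    )


def samples_from_raw(
    group: pd.DataFrame, channel: str, lods: LodConfig
) -> list[DailySample]:
    """Build censored + QC'd DailySamples for one cycle and channel."""
    a_col, n_col = CHANNEL_COLUMNS[channel]
    lod_a, lod_n = lods.for_channel(channel)
    samples = []
    for row in group.itertuples(index=False):
        pid, cid, day = row.participant_id, row.cycle_id, int(row.day)
        a_raw = getattr(row, a_col)
        n_raw = getattr(row, n_col)
        if pd.isna(a_raw) or pd.isna(n_raw):
            samples.append(
                DailySample(pid, cid, day, np.nan, np.nan, False, False,
                            qc_status=QC_MISSING)
            )
            continue
        a_val, a_flag = censor_below_lod(float(a_raw), lod_a)
        n_val, n_flag = censor_below_lod(float(n_raw), lod_n)
        samples.append(
            qc_daily_sample(
                DailySample(pid, cid, day, a_val, n_val, a_flag, n_flag)
            )
        )
    return samples


def preprocess_cohort(
    raw: pd.DataFrame, lods: LodConfig
) -> dict[tuple[str, str, str], CycleSeries]:
    """Raw per-day frame -> {(participant, cycle, channel): CycleSeries}."""
    series: dict[tuple[str, str, str], CycleSeries] = {}
    for (pid, cid), group in raw.groupby(
        ["participant_id", "cycle_id"], sort=True
    ):
        for channel in CHANNELS:
            samples = samples_from_raw(group, channel, lods)
            series[(pid, cid, channel)] = normalize_cycle(samples, channel)
    return series


def series_to_frame(series: dict[tuple[str, str, str], CycleSeries]) -> pd.DataFrame:
    """Tidy export: participant_id, cycle_id, channel, day, value, observed."""
    rows = []
    for (pid, cid, channel), s in sorted(series.items()):
        for day, value, obs in zip(s.days, s.values, s.observed):
            rows.append(
                {
                    "participant_id": pid,
                    "cycle_id": cid,
                    "channel": channel,
                    "day": int(day),
                    "value": float(value) if obs else None,
                    "observed": bool(obs),
                }
            )
    cols = ["participant_id", "cycle_id", "channel", "day", "value", "observed"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_series(frame: pd.DataFrame) -> dict[tuple[str, str, str], CycleSeries]:
    """Inverse of :func:`series_to_frame`."""
    out: dict[tuple[str, str, str], CycleSeries] = {}
    for (pid, cid, channel), group in frame.groupby(
        ["participant_id", "cycle_id", "channel"], sort=True
    ):
        group = group.sort_values("day")
        observed = group["observed"].astype(bool).to_numpy()
        values = group["value"].to_numpy(dtype=float)
        values = np.where(observed, values, np.nan)
        out[(pid, cid, channel)] = CycleSeries(
            participant_id=pid,
            cycle_id=cid,
            channel=channel,
            days=group["day"].to_numpy(dtype=int),
            values=values,
            observed=observed,
        )
    return out
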