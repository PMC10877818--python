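#!/usr/bin/env python
"""Censor below-LOD values, apply QC, normalize to LH ratios.

Measurements below their assay's limit of detection are replaced by the
LOD; a day on which both the analyte and its normalizer fall below LOD is a
failed collection and becomes missing.  Urinary LH is divided by creatinine
(uLH/Cr) and VD LH by total extract protein (vLH/Pro), both mIU/mg.

Reads results/raw.csv, writes results/normalized.csv.
"""

from pathlib import Path

from lhsurge import io
from lhsurge.preprocess import LodConfig, preprocess_cohort, series_to_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    raw = io.read_raw_csv(RESULTS / "raw.csv")
    cfg = io.read_config_yaml(RESULTS / "config.yaml")
    lods = LodConfig(ulh=cfg.lod_ulh, creatinine=cfg.lod_creatinine,
                     vlh=cfg.lod_vlh, total_protein=cfg.lod_protein)
    series = preprocess_cohort(raw, lods)
    frame = series_to_frame(series)
    io.write_series_csv(frame, RESULTS / "normalized.csv")

    n_days = len(frame)
    n_obs = int(frame["observed"].sum())
    print(f"normalized {len(series)} cycle series "
          f"({n_obs}/{n_days} day-channel records observed)")
    for channel, grp in frame.groupby("channel"):
        lost = int((~grp["observed"]).sum())
        print(f"  {channel}: {lost} day(s) missing or failed collection")


if __name__ == "__main__":
    main()
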