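"""CSV / YAML / JSON readers and writers for the pipeline stages.

Everything is plain text: raw cohorts and normalized series as CSV, configs
as YAML, reports as JSON.  Day columns are 1-based cycle days.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .simulate import Cohort, GeneratorConfig
from .types import CohortReport

RAW_COLUMNS = ["participant_id", "cycle_id", "day", "ulh", "creatinine",
               "vlh", "total_protein"]
_RAW_NUMERIC = ["ulh", "creatinine", "vlh", "total_protein"]

SERIES_COLUMNS = ["participant_id", "cycle_id", "channel", "day", "value",
                  "observed"]


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_raw_csv(cohort: Cohort, path) -> None:
    cohort.raw_frame().to_csv(path, index=False)


def read_raw_csv(path) -> pd.DataFrame:
    """Read a per-day raw cohort CSV, reporting malformed cells by line."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def _parse(col: str, caster, required: bool) -> list:
        out = []
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                if required:
                    raise ValueError(
                        f"{path}: line {i + 2}: empty required column '{col}'"
                    )
                out.append(None)
                continue
            try:
                out.append(caster(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {i + 2}: cannot parse '{cell}' in "
                    f"column '{col}'"
                ) from None
        return out

    parsed = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "cycle_id": df["cycle_id"],
            "day": _parse("day", int, required=True),
        }
    )
    for col in _RAW_NUMERIC:
        parsed[col] = pd.array(_parse(col, float, required=False),
                               dtype="float64")
    return parsed


def write_truth_csv(cohort: Cohort, path) -> None:
    cohort.manifest().to_csv(path, index=False)


def write_series_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_series_csv(path) -> pd.DataFrame:
    # round_trip: the default float parser can be off by 1 ulp, which breaks
    # byte-identical reproducibility between staged and all-in-one runs
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_config_yaml(config: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


def read_config_yaml(path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    for key in ("collection_window", "cycle_length_bounds", "baseline_level",
                "peak_amplitude", "vlh_baseline_level", "vlh_peak_amplitude",
                "peak_day_range", "extra_peak_rel_amplitude",
                "extra_peak_gap_days", "normalizer_level",
                "vlh_normalizer_level"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "vlh_lag_probs" in data:
        data["vlh_lag_probs"] = {int(k): v
                                 for k, v in data["vlh_lag_probs"].items()}
    cfg = GeneratorConfig(**data)
    cfg.validate()
    return cfg


def concordance_frame(report: CohortReport) -> pd.DataFrame:
    t = report.concordance
    rows = [
        {"timing_of_vlh_surge": str(k), "n_cycles": t.counts[k],
         "ratio_pct": t.percentages[str(k)]}
        for k in t.WINDOW_OFFSETS
    ]
    rows.append({"timing_of_vlh_surge": "others", "n_cycles": t.others,
                 "ratio_pct": t.percentages["others"]})
    rows.append({"timing_of_vlh_surge": "total", "n_cycles": t.total,
                 "ratio_pct": 100})
    return pd.DataFrame(rows)


def metrics_dict(report: CohortReport) -> dict:
    d = report.diagnostic
    return {
        "funnel": report.funnel,
        "within_window_pct": report.concordance.within_window_pct,
        "t_statistic": d.t_statistic,
        "degrees_of_freedom": d.degrees_of_freedom,
        "p_value": d.p_value,
        "auc": d.auc,
        "optimal_cutoff": d.optimal_cutoff,
        "sensitivity": d.sensitivity,
        "specificity": d.specificity,
        "ppv": d.ppv,
        "npv": d.npv,
        "accuracy": d.accuracy,
        "confusion": {"tp": d.confusion.tp, "fn": d.confusion.fn,
                      "tn": d.confusion.tn, "fp": d.confusion.fp},
        "warnings": list(d.warnings),
        "n_exclusions": len(report.exclusions),
    }


def write_metrics_json(report: CohortReport, path) -> None:
    Path(path).write_text(json.dumps(metrics_dict(report), indent=2,
                                     sort_keys=True) + "\n")


def write_roc_csv(report: CohortReport, path) -> None:
    d = report.diagnostic
    pd.DataFrame(
        {
            "threshold": d.thresholds,
            "fpr": [p[0] for p in d.roc_points],
            "tpr": [p[1] for p in d.roc_points],
        }
    ).to_csv(path, index=False)
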