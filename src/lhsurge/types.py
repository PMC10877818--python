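"""Core domain containers shared across the pipeline stages.

Day indices are 1-based cycle days counted from the first day of
menstruation; offsets relative to ovulation are signed integers with
negative meaning "before ovulation".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Channels
URINE = "urine"
VAGINAL_DISCHARGE = "vaginal_discharge"
CHANNELS = (URINE, VAGINAL_DISCHARGE)

# Surge morphologies
SHARP_SINGLE = "sharp_single"
BROAD_SINGLE = "broad_single"
MULTIPLE = "multiple"
NONE = "none"
PATTERNS = (SHARP_SINGLE, BROAD_SINGLE, MULTIPLE, NONE)

# QC states for a daily sample
QC_OK = "ok"
QC_COLLECTION_FAILED = "collection_failed"
QC_MISSING = "missing"


class ConfigError(ValueError):
    """A generator or pipeline configuration field is invalid."""


class InsufficientDataError(ValueError):
    """Too few measurements to compute the requested quantity."""


class EmptySeriesError(ValueError):
    """A cycle series has no observed days."""


class BaselineUndeterminedError(ValueError):
    """None of the four flanking days of the peak maximum is observed."""


class ZeroNormalizerError(ZeroDivisionError):
    """A normalizer value is zero after LOD substitution (only possible with LOD=0)."""


class InsufficientCohortError(ValueError):
    """Fewer than two cycles survive the exclusion funnel."""


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """Integer percentage with ties rounded up (2.5% -> 3%), as in the
    source tables this package reproduces.  Denominator of zero maps to 0."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class DailySample:
    """One day's raw assay record on one channel (analyte + its normalizer)."""

    participant_id: str
    cycle_id: str
    day: int
    analyte_value: float
    normalizer_value: float
    analyte_below_lod: bool = False
    normalizer_below_lod: bool = False
    qc_status: str = QC_OK


@dataclass
class CycleSeries:
    """One cycle's normalized LH-ratio trajectory (mIU per mg normalizer).

    ``days`` covers every day with a record (observed or not); unobserved
    days carry NaN values and ``observed=False``.
    """

    participant_id: str
    cycle_id: str
    channel: str
    days: np.ndarray
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.days) == len(self.values) == len(self.observed)):
            raise ValueError("days, values and observed must have equal length")
        if len(self.days) > 1 and not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def observed_days(self) -> np.ndarray:
        return self.days[self.observed]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.observed]

    def is_observed(self, day: int) -> bool:
        idx = np.where(self.days == day)[0]
        return bool(idx.size and self.observed[idx[0]])

    def value_on(self, day: int) -> float:
        idx = np.where(self.days == day)[0]
        if not idx.size or not self.observed[idx[0]]:
            raise KeyError(f"day {day} is not observed")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class CycleTruth:
    """Ground truth attached to a simulated cycle (normalized scale)."""

    participant_id: str
    cycle_id: str
    true_pattern: str
    true_elevated_days_u: tuple[int, ...]
    true_ovulation_day: int | None
    true_elevated_days_v: tuple[int, ...]
    true_first_surge_day_v: int | None
    vlh_lag: int
    cycle_length: int
    truncated_v: bool


@dataclass(frozen=True)
class SurgeCall:
    """Per-cycle, per-channel output of the surge-calling rules."""

    participant_id: str
    cycle_id: str
    channel: str
    baseline: float | None
    peak_day: int | None
    elevated_days: tuple[int, ...]
    pattern: str
    first_surge_day: int | None
    ovulation_day: int | None
    fertile_window: tuple[int, int] | None
    n_baseline_days: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConcordanceTable:
    """Distribution of vLH first-surge offsets relative to the uLH-derived
    ovulation day: one row per offset in -5..0 plus an 'others' bucket."""

    counts: dict[int, int]
    others: int
    total: int

    WINDOW_OFFSETS = tuple(range(-5, 1))

    @classmethod
    def from_offsets(cls, offsets) -> "ConcordanceTable":
        offsets = list(offsets)
        if not offsets:
            raise InsufficientDataError("no offsets to tabulate")
        counts = {k: 0 for k in cls.WINDOW_OFFSETS}
        others = 0
        for off in offsets:
            if off in counts:
                counts[off] += 1
            else:
                others += 1
        return cls(counts=counts, others=others, total=len(offsets))

    @property
    def within_window_count(self) -> int:
        return sum(self.counts.values())

    @property
    def within_window_pct(self) -> int:
        return round_half_up_pct(self.within_window_count, self.total)

    @property
    def percentages(self) -> dict[str, int]:
        out = {str(k): round_half_up_pct(v, self.total) for k, v in self.counts.items()}
        out["others"] = round_half_up_pct(self.others, self.total)
        return out


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion matrix with diagnostic metrics as rounded percentages.

    A single matrix is the source of truth for all five metrics; exact
    fractions are exposed alongside the rounded values.  An undefined metric
    (zero denominator) is reported as 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    @property
    def sensitivity_exact(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity_exact(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv_exact(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv_exact(self) -> float:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def accuracy_exact(self) -> float:
        return self._pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> int:
        return round_half_up_pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> int:
        return round_half_up_pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> int:
        return round_half_up_pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> int:
        return round_half_up_pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> int:
        return round_half_up_pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    def as_dict(self) -> dict[str, int]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


@dataclass
class DiagnosticResult:
    """t-test, ROC and Youden-cutoff evaluation of per-cycle baseline vs
    first-surge vLH values."""

    baseline_group: np.ndarray
    surge_group: np.ndarray
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    roc_points: list[tuple[float, float]]
    thresholds: np.ndarray
    auc: float
    optimal_cutoff: float
    confusion: ConfusionMetrics
    warnings: tuple[str, ...] = ()

    @property
    def sensitivity(self) -> int:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> int:
        return self.confusion.specificity

    @property
    def ppv(self) -> int:
        return self.confusion.ppv

    @property
    def npv(self) -> int:
        return self.confusion.npv

    @property
    def accuracy(self) -> int:
        return self.confusion.accuracy


@dataclass
class CohortReport:
    """Full evaluation bundle: concordance + diagnostics + exclusion funnel."""

    concordance: ConcordanceTable
    diagnostic: DiagnosticResult
    funnel: dict[str, int]
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)
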