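"""Synthetic cohorts of paired urinary / vaginal-discharge LH daily series.

Each ovulatory cycle carries one urinary LH surge drawn from one of three
morphologies (sharp single peak, broad single peak, multiple peaks) on a
flat baseline, and a vaginal-discharge surge that is the same template
shifted by an integer lag of up to a few days either way.  Values are
reported as raw (analyte, normalizer) concentration pairs so the
normalization stage downstream is genuinely exercised; multiplicative
lognormal noise, below-LOD values, failed collections and missing days
emulate the defects of at-home daily sampling.

Ground truth (true elevated days, ovulation day, pattern class) is recorded
on the normalized scale.  Peak templates are built so that, at zero noise,
the downstream surge-calling rules recover the truth exactly (see
docs/methods.md for why the broad plateau defaults to two days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    BROAD_SINGLE,
    ConfigError,
    CycleTruth,
    MULTIPLE,
    NONE,
    SHARP_SINGLE,
)

# Drawn-pattern order is fixed so that rng consumption is reproducible.
_PATTERN_ORDER = (SHARP_SINGLE, BROAD_SINGLE, MULTIPLE)

DEFAULT_PATTERN_PROBS = {SHARP_SINGLE: 0.6, BROAD_SINGLE: 0.2, MULTIPLE: 0.2}

# Illustrative lag distribution on [-4, +4] days (vLH relative to uLH),
# weighted toward the vLH surge leading; the motivating data show lags of
# up to 4 days either way.
DEFAULT_VLH_LAG_PROBS = {
    -4: 0.24, -3: 0.14, -2: 0.07, -1: 0.28, 0: 0.10,
    1: 0.07, 2: 0.04, 3: 0.03, 4: 0.03,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings.

    Distribution-valued fields are (mean, cv) pairs of a lognormal draw;
    cv=0 degenerates to the mean.  All LH levels are illustrative — the
    motivating study reports no distributional parameters — but cohort
    scale (35 participants, 55 cycles, cycle length 30 +/- 2.4 days,
    collection on cycle days 10-19) matches it.
    """

    n_participants: int = 35
    cycles_per_participant: int = 1
    total_cycles: int | None = 55
    cycle_length_mean: float = 30.0
    cycle_length_sd: float = 2.4
    cycle_length_bounds: tuple[int, int] = (25, 38)
    collection_window: tuple[int, int] = (10, 19)
    # normalized uLH/Cr scale (mIU/mg)
    baseline_level: tuple[float, float] = (1.0, 0.2)
    peak_amplitude: tuple[float, float] = (8.0, 0.25)
    # normalized vLH/Pro scale (mIU/mg); roughly 20-40x lower than urine
    vlh_baseline_level: tuple[float, float] = (0.05, 0.3)
    vlh_peak_amplitude: tuple[float, float] = (0.4, 0.3)
    # every surge is at least this many times its own baseline, so that the
    # weakest secondary peak (40% relative amplitude) still clears the
    # 2x-baseline rule: 0.4 * 5.5 = 2.2 > 2
    min_amplitude_fold: float = 5.5
    pattern_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_PROBS)
    )
    peak_day_range: tuple[int, int] = (12, 17)
    broad_width_days: int = 2
    n_extra_peaks: int = 1
    extra_peak_rel_amplitude: tuple[float, float] = (0.4, 0.8)
    extra_peak_gap_days: tuple[int, int] = (2, 4)
    vlh_lag_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VLH_LAG_PROBS)
    )
    # per-day multiplicative assay noise
    noise_cv: float = 0.1
    # normalizer concentrations: urinary creatinine, VD total protein (mg/mL)
    normalizer_level: tuple[float, float] = (1.0, 0.3)
    vlh_normalizer_level: tuple[float, float] = (0.5, 0.3)
    # limits of detection on the raw concentration scale
    lod_ulh: float = 0.05
    lod_creatinine: float = 0.01
    lod_vlh: float = 0.005
    lod_protein: float = 0.02
    p_missing_day: float = 0.02
    p_collection_fail: float = 0.02
    seed: int = 0

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        def _positive_dist(name: str, dist) -> None:
            mean, cv = dist
            if mean <= 0:
                raise ConfigError(f"{name}: mean must be > 0")
            if cv < 0:
                raise ConfigError(f"{name}: cv must be >= 0")

        def _prob(name: str, p: float) -> None:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")

        if self.n_participants < 0:
            raise ConfigError("n_participants: must be >= 0")
        if self.cycles_per_participant < 1:
            raise ConfigError("cycles_per_participant: must be >= 1")
        if self.total_cycles is not None and self.total_cycles < 0:
            raise ConfigError("total_cycles: must be >= 0")
        lo, hi = self.collection_window
        if lo < 1 or hi < lo:
            raise ConfigError(
                "collection_window: must be a nonempty 1-based day range"
            )
        if self.cycle_length_sd < 0:
            raise ConfigError("cycle_length_sd: must be >= 0")
        blo, bhi = self.cycle_length_bounds
        if blo > bhi:
            raise ConfigError("cycle_length_bounds: lower bound exceeds upper")
        _positive_dist("baseline_level", self.baseline_level)
        _positive_dist("peak_amplitude", self.peak_amplitude)
        _positive_dist("vlh_baseline_level", self.vlh_baseline_level)
        _positive_dist("vlh_peak_amplitude", self.vlh_peak_amplitude)
        _positive_dist("normalizer_level", self.normalizer_level)
        _positive_dist("vlh_normalizer_level", self.vlh_normalizer_level)
        if set(self.pattern_probs) - set(_PATTERN_ORDER):
            raise ConfigError("pattern_probs: unknown pattern name")
        for name, p in self.pattern_probs.items():
            _prob(f"pattern_probs[{name}]", p)
        if abs(sum(self.pattern_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("pattern_probs: probabilities must sum to 1")
        plo, phi = self.peak_day_range
        if plo < lo or phi > hi or plo > phi:
            raise ConfigError("peak_day_range: must lie inside collection_window")
        if self.broad_width_days < 2:
            raise ConfigError("broad_width_days: must be >= 2")
        if phi + self.broad_width_days - 1 > hi:
            raise ConfigError(
                "peak_day_range: broad plateau would overrun the collection window"
            )
        if self.n_extra_peaks < 1:
            raise ConfigError("n_extra_peaks: must be >= 1")
        flo, fhi = self.extra_peak_rel_amplitude
        if not (0.0 < flo <= fhi <= 1.0):
            raise ConfigError("extra_peak_rel_amplitude: need 0 < lo <= hi <= 1")
        glo, ghi = self.extra_peak_gap_days
        if glo < 2 or ghi < glo:
            raise ConfigError("extra_peak_gap_days: need hi >= lo >= 2")
        for k, p in self.vlh_lag_probs.items():
            if int(k) != k:
                raise ConfigError("vlh_lag_probs: lags must be integers")
            _prob(f"vlh_lag_probs[{k}]", p)
        if abs(sum(self.vlh_lag_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("vlh_lag_probs: probabilities must sum to 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv: must be >= 0")
        if self.min_amplitude_fold < 0:
            raise ConfigError("min_amplitude_fold: must be >= 0")
        for name in ("lod_ulh", "lod_creatinine", "lod_vlh", "lod_protein"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        _prob("p_missing_day", self.p_missing_day)
        _prob("p_collection_fail", self.p_collection_fail)


@dataclass
class RawDay:
    """One calendar day's raw record; None marks an empty CSV cell."""

    day: int
    ulh: float | None
    creatinine: float | None
    vlh: float | None
    total_protein: float | None


@dataclass
class SimulatedCycle:
    participant_id: str
    cycle_id: str
    days: list[RawDay]
    truth: CycleTruth


@dataclass
class Cohort:
    cycles: list[SimulatedCycle]
    config: GeneratorConfig

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def raw_frame(self) -> pd.DataFrame:
        rows = []
        for cyc in self.cycles:
            for d in cyc.days:
                rows.append(
                    {
                        "participant_id": cyc.participant_id,
                        "cycle_id": cyc.cycle_id,
                        "day": d.day,
                        "ulh": d.ulh,
                        "creatinine": d.creatinine,
                        "vlh": d.vlh,
                        "total_protein": d.total_protein,
                    }
                )
        cols = ["participant_id", "cycle_id", "day", "ulh", "creatinine",
                "vlh", "total_protein"]
        return pd.DataFrame(rows, columns=cols)

    def manifest(self) -> pd.DataFrame:
        """One row per cycle with its full truth record."""
        rows = []
        for cyc in self.cycles:
            t = cyc.truth
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "cycle_id": t.cycle_id,
                    "true_pattern": t.true_pattern,
                    "true_elevated_days_u": ";".join(map(str, t.true_elevated_days_u)),
                    "true_ovulation_day": t.true_ovulation_day,
                    "true_elevated_days_v": ";".join(map(str, t.true_elevated_days_v)),
                    "true_first_surge_day_v": t.true_first_surge_day_v,
                    "vlh_lag": t.vlh_lag,
                    "cycle_length": t.cycle_length,
                    "truncated_v": t.truncated_v,
                }
            )
        cols = ["participant_id", "cycle_id", "true_pattern",
                "true_elevated_days_u", "true_ovulation_day",
                "true_elevated_days_v", "true_first_surge_day_v",
                "vlh_lag", "cycle_length", "truncated_v"]
        return pd.DataFrame(rows, columns=cols)


# -- draw helpers -------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0:
        return float(mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _noise(rng: np.random.Generator, cv: float) -> float:
    return _lognormal(rng, 1.0, cv)


def _choice(rng: np.random.Generator, items, probs) -> object:
    return items[int(rng.choice(len(items), p=np.asarray(probs, dtype=float)))]


def _classify_template(days: list[int]) -> str:
    """Realized pattern class of a template's elevated-day set."""
    if not days:
        return NONE
    days = sorted(days)
    runs = 1
    for a, b in zip(days, days[1:]):
        if b - a > 1:
            runs += 1
    if runs >= 2:
        return MULTIPLE
    return SHARP_SINGLE if len(days) == 1 else BROAD_SINGLE


def _recoverable_days(
    shape: dict[int, float], baseline: float, amplitude: float,
    lo: int, hi: int,
) -> list[int]:
    """Elevated days the calling rules find on the noise-free template."""
    from .surge import call_cycle  # local import; surge depends only on types
    from .types import CycleSeries, VAGINAL_DISCHARGE

    days = np.arange(lo, hi + 1)
    values = np.array(
        [baseline + amplitude * shape.get(int(d), 0.0) for d in days]
    )
    series = CycleSeries(
        participant_id="_", cycle_id="_", channel=VAGINAL_DISCHARGE,
        days=days, values=values, observed=np.ones(days.size, dtype=bool),
    )
    return list(call_cycle(series).elevated_days)


# -- generation ---------------------------------------------------------

def generate_cycle(
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_id: str = "P001",
    cycle_id: str = "C1",
) -> SimulatedCycle:
    """Generate one cycle's raw daily records plus its ground truth."""
    config.validate()
    lo, hi = config.collection_window

    cycle_length = int(
        np.clip(
            round(rng.normal(config.cycle_length_mean, config.cycle_length_sd)),
            *config.cycle_length_bounds,
        )
    )
    probs = [config.pattern_probs.get(p, 0.0) for p in _PATTERN_ORDER]
    pattern_drawn = _choice(rng, _PATTERN_ORDER, probs)

    b_u = _lognormal(rng, *config.baseline_level)
    a_u = max(_lognormal(rng, *config.peak_amplitude),
              config.min_amplitude_fold * b_u)
    b_v = _lognormal(rng, *config.vlh_baseline_level)
    a_v = max(_lognormal(rng, *config.vlh_peak_amplitude),
              config.min_amplitude_fold * b_v)

    plo, phi = config.peak_day_range
    peak = int(rng.integers(plo, phi + 1))

    # relative template: day -> fraction of full amplitude
    shape: dict[int, float] = {}
    if pattern_drawn == SHARP_SINGLE:
        shape[peak] = 1.0
    elif pattern_drawn == BROAD_SINGLE:
        # plateau with a 0.1% per-day downward tilt: an exact tie would
        # leave the peak-maximum day (and with it recoverability at the
        # window edge) to float rounding in the normalization round-trip
        for k, d in enumerate(range(peak, peak + config.broad_width_days)):
            shape[d] = 1.0 - 0.001 * k
    else:  # multiple: weak secondary peaks precede the primary
        shape[peak] = 1.0
        cursor = peak
        glo, ghi = config.extra_peak_gap_days
        flo, fhi = config.extra_peak_rel_amplitude
        for _ in range(config.n_extra_peaks):
            max_gap = min(ghi, cursor - lo)
            if max_gap < glo:
                break
            gap = int(rng.integers(glo, max_gap + 1))
            frac = float(rng.uniform(flo, fhi))
            cursor -= gap
            shape[cursor] = frac

    elevated_u = sorted(shape)
    ovulation = max(elevated_u) + 1

    lags = sorted(config.vlh_lag_probs)
    lag = int(_choice(rng, lags, [config.vlh_lag_probs[k] for k in lags]))
    shape_v = {d + lag: s for d, s in shape.items() if lo <= d + lag <= hi}
    # vLH truth is what the calling rules recover from the noise-free
    # shifted template: a lag can push surge days out of the collection
    # window, and a run pressed against the window edge can leave too few
    # clean flanking days to establish a baseline.  Both yield realistic
    # partially- or wholly-unrecoverable vLH cycles.
    elevated_v = _recoverable_days(shape_v, b_v, a_v, lo, hi)
    truncated_v = len(elevated_v) < len(shape)

    truth = CycleTruth(
        participant_id=participant_id,
        cycle_id=cycle_id,
        true_pattern=_classify_template(elevated_u),
        true_elevated_days_u=tuple(elevated_u),
        true_ovulation_day=ovulation,
        true_elevated_days_v=tuple(elevated_v),
        true_first_surge_day_v=min(elevated_v) if elevated_v else None,
        vlh_lag=lag,
        cycle_length=cycle_length,
        truncated_v=truncated_v,
    )

    rows: list[RawDay] = []
    for day in range(lo, hi + 1):
        if rng.random() < config.p_missing_day:
            rows.append(RawDay(day, None, None, None, None))
            continue
        u_norm = (b_u + a_u * shape.get(day, 0.0)) * _noise(rng, config.noise_cv)
        cr = _lognormal(rng, *config.normalizer_level)
        v_norm = (b_v + a_v * shape_v.get(day, 0.0)) * _noise(rng, config.noise_cv)
        pro = _lognormal(rng, *config.vlh_normalizer_level)
        ulh, creat = u_norm * cr, cr
        vlh, prot = v_norm * pro, pro
        if rng.random() < config.p_collection_fail:
            # urine collection failed: both assays read below their LODs
            ulh = float(rng.uniform(0.0, 0.9 * config.lod_ulh))
            creat = float(rng.uniform(0.0, 0.9 * config.lod_creatinine))
        if rng.random() < config.p_collection_fail:
            vlh = float(rng.uniform(0.0, 0.9 * config.lod_vlh))
            prot = float(rng.uniform(0.0, 0.9 * config.lod_protein))
        rows.append(RawDay(day, ulh, creat, vlh, prot))

    return SimulatedCycle(participant_id, cycle_id, rows, truth)


def _cycles_per_participant(config: GeneratorConfig) -> list[int]:
    n = config.n_participants
    if n == 0:
        return []
    if config.total_cycles is None:
        return [config.cycles_per_participant] * n
    base, extra = divmod(config.total_cycles, n)
    return [base + 1 if i < extra else base for i in range(n)]


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the full cohort reproducibly from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cycles: list[SimulatedCycle] = []
    for i, k in enumerate(_cycles_per_participant(config)):
        pid = f"P{i + 1:03d}"
        for j in range(k):
            cycles.append(generate_cycle(config, rng, pid, f"C{j + 1}"))
    return Cohort(cycles=cycles, config=config)


def engineer_funnel_cohort(
    config: GeneratorConfig,
    n_no_ulh: int = 6,
    n_no_vd: int = 15,
    n_no_vlh: int = 5,
) -> Cohort:
    """Cohort with engineered exclusion strata for funnel bookkeeping tests.

    The first ``n_no_ulh`` cycles get a flat urinary series (no discernible
    peak), the next ``n_no_vd`` lose their vaginal-discharge records
    entirely, and the next ``n_no_vlh`` get a flat vaginal-discharge series.
    Remaining cycles are untouched.  Use a config whose untouched cycles
    call cleanly (low noise, no missing days, lag that cannot truncate the
    vLH template out of the window).
    """
    cohort = generate_cohort(config)
    need = n_no_ulh + n_no_vd + n_no_vlh
    if cohort.n_cycles < need:
        raise ConfigError(
            f"cohort has {cohort.n_cycles} cycles, fewer than the "
            f"{need} engineered exclusions"
        )
    for idx, cyc in enumerate(cohort.cycles):
        if idx < n_no_ulh:
            for d in cyc.days:
                if d.creatinine is not None:
                    d.ulh = d.creatinine * 1.0  # flat uLH/Cr == 1
            cyc.truth = replace(
                cyc.truth, true_pattern=NONE, true_elevated_days_u=(),
                true_ovulation_day=None,
            )
        elif idx < n_no_ulh + n_no_vd:
            for d in cyc.days:
                d.vlh = None
                d.total_protein = None
            cyc.truth = replace(
                cyc.truth, true_elevated_days_v=(), true_first_surge_day_v=None,
            )
        elif idx < need:
            for d in cyc.days:
                if d.total_protein is not None:
                    d.vlh = d.total_protein * 0.05  # flat vLH/Pro
            cyc.truth = replace(
                cyc.truth, true_elevated_days_v=(), true_first_surge_day_v=None,
            )
    return cohort
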