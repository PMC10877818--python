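"""Evaluation of vaginal-discharge LH against urine-derived ovulation.

Two complementary views of performance:

* timing — the offset of each cycle's first vLH surge day relative to the
  uLH-derived ovulation day, tabulated over the fertile-window offsets
  -5..0 plus an "others" bucket;
* strength — per-cycle baseline vs first-surge vLH values compared by a
  pooled-variance Student's t-test and by ROC analysis, with the operating
  cutoff chosen to maximize the Youden index J = sensitivity +
  specificity - 1 (ties resolved toward the lower cutoff, i.e. higher
  sensitivity).  A case is test-positive when its value >= cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .types import (
    CohortReport,
    ConcordanceTable,
    ConfusionMetrics,
    CycleSeries,
    DiagnosticResult,
    InsufficientCohortError,
    InsufficientDataError,
    NONE,
    SurgeCall,
    URINE,
    VAGINAL_DISCHARGE,
)


def compute_offsets(pairs) -> ConcordanceTable:
    """Tabulate first-surge offsets from (urine call, VD call) pairs.

    ``pairs`` is an iterable of (urine SurgeCall, vd SurgeCall); each pair
    must carry an ovulation_day and a first_surge_day respectively.
    """
    offsets = []
    for u_call, v_call in pairs:
        if u_call.ovulation_day is None or v_call.first_surge_day is None:
            raise ValueError(
                f"{u_call.participant_id}/{u_call.cycle_id}: pair lacks "
                "ovulation_day or first_surge_day; exclude such cycles first"
            )
        offsets.append(v_call.first_surge_day - u_call.ovulation_day)
    if not offsets:
        raise InsufficientDataError("no cycle pairs to tabulate")
    return ConcordanceTable.from_offsets(offsets)


def students_t_test(group_a, group_b, welch: bool = False):
    """Two-sample t-test; pooled variance (classical Student) by default.

    Returns (t, df, two-sided p).  Degenerate zero-variance input maps to
    t=0, p=1 for equal means and +/-inf, p=0 (with a warning) otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    df = a.size + b.size - 2 if not welch else None
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if not welch and pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        warnings.warn("zero pooled variance with unequal means; p -> 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def roc_analysis(positives, negatives):
    """ROC over all observed values (test-positive when value >= threshold).

    Returns (fpr, tpr, thresholds, auc) with thresholds descending and the
    curve anchored at (0,0) and (1,1); AUC by the trapezoid rule, which on
    this construction equals the Mann-Whitney exceedance probability.
    """
    pos = np.asarray(list(positives), dtype=float)
    neg = np.asarray(list(negatives), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def confusion_at_cutoff(positives, negatives, cutoff: float) -> ConfusionMetrics:
    """2x2 matrix at a cutoff with >= positivity."""
    pos = np.asarray(list(positives), dtype=float)
    neg = np.asarray(list(negatives), dtype=float)
    tp = int(np.sum(pos >= cutoff))
    fp = int(np.sum(neg >= cutoff))
    return ConfusionMetrics(tp=tp, fn=pos.size - tp, tn=neg.size - fp, fp=fp)


def youden_cutoff(positives, negatives):
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate cutoffs are the observed values; ties in J resolve to the
    lowest cutoff (highest sensitivity).  Returns
    (cutoff, ConfusionMetrics, warnings).
    """
    fpr, tpr, thresholds, _ = roc_analysis(positives, negatives)
    j = tpr - fpr
    finite = np.isfinite(thresholds)
    j_max = float(j[finite].max())
    warns: list[str] = []
    if j_max <= 0.0:
        warns.append("degenerate_roc: J <= 0 at every cutoff")
    # among maximizers, the lowest threshold; thresholds are descending
    maximizers = np.where(finite & (j >= j_max - 1e-12))[0]
    cutoff = float(thresholds[maximizers[-1]])
    cm = confusion_at_cutoff(positives, negatives, cutoff)
    if min(cm.tn + cm.fn, cm.tp + cm.fp) == 0:
        warns.append("undefined_predictive_value")
    return cutoff, cm, warns


def diagnostic_analysis(
    baseline_group, surge_group, welch: bool = False
) -> DiagnosticResult:
    """Full strength evaluation: t-test + ROC + Youden cutoff metrics."""
    baseline = np.asarray(list(baseline_group), dtype=float)
    surge = np.asarray(list(surge_group), dtype=float)
    t, df, p = students_t_test(baseline, surge, welch=welch)
    fpr, tpr, thresholds, auc = roc_analysis(surge, baseline)
    cutoff, cm, warns = youden_cutoff(surge, baseline)
    return DiagnosticResult(
        baseline_group=baseline,
        surge_group=surge,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        thresholds=thresholds,
        auc=auc,
        optimal_cutoff=cutoff,
        confusion=cm,
        warnings=tuple(warns),
    )


def evaluate_cohort(
    calls: dict[tuple[str, str, str], SurgeCall],
    series: dict[tuple[str, str, str], CycleSeries],
    welch: bool = False,
) -> CohortReport:
    """Assemble the per-cycle groups, run the evaluation, log exclusions.

    The exclusion funnel mirrors the study design: cycles without a uLH
    surge drop first, then cycles without usable VD data, then cycles whose
    VD series shows no surge.  Eligible cycles contribute one baseline
    value and one first-surge vLH value each.
    """
    cycle_keys = sorted(
        {(p, c) for (p, c, ch) in calls if ch == URINE}
    )
    funnel = {
        "cycles_total": len(cycle_keys),
        "ulh_surge": 0,
        "vd_available": 0,
        "vlh_surge": 0,
    }
    exclusions: list[tuple[str, str, str]] = []
    pairs: list[tuple[SurgeCall, SurgeCall]] = []
    baseline_group: list[float] = []
    surge_group: list[float] = []

    for pid, cid in cycle_keys:
        u_call = calls[(pid, cid, URINE)]
        if u_call.pattern == NONE or u_call.ovulation_day is None:
            exclusions.append((pid, cid, "no_ulh_surge"))
            continue
        funnel["ulh_surge"] += 1
        v_series = series.get((pid, cid, VAGINAL_DISCHARGE))
        if v_series is None or v_series.observed_days.size == 0:
            exclusions.append((pid, cid, "no_vd_data"))
            continue
        funnel["vd_available"] += 1
        v_call = calls.get((pid, cid, VAGINAL_DISCHARGE))
        if v_call is None or v_call.pattern == NONE:
            exclusions.append((pid, cid, "no_vlh_surge"))
            continue
        funnel["vlh_surge"] += 1
        pairs.append((u_call, v_call))
        baseline_group.append(float(v_call.baseline))
        surge_group.append(v_series.value_on(v_call.first_surge_day))

    if funnel["vlh_surge"] < 2:
        raise InsufficientCohortError(
            f"only {funnel['vlh_surge']} eligible cycles survive the funnel; "
            "need at least 2"
        )

    concordance = compute_offsets(pairs)
    diagnostic = diagnostic_analysis(baseline_group, surge_group, welch=welch)
    return CohortReport(
        concordance=concordance,
        diagnostic=diagnostic,
        funnel=funnel,
        exclusions=exclusions,
    )


# -- optional plotting --------------------------------------------------

def plot_diagnostics(report: CohortReport, path) -> None:
    """Box plot of baseline vs surge values plus the ROC curve (one PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = report.diagnostic
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.boxplot([d.baseline_group, d.surge_group],
                tick_labels=["Baseline", "Surge"])
    ax1.set_ylabel("vLH/Pro (mIU/mg)")
    ax1.set_title(f"t-test p = {d.p_value:.2e}")
    fpr = [p[0] for p in d.roc_points]
    tpr = [p[1] for p in d.roc_points]
    ax2.plot(fpr, tpr, marker="o", ms=3)
    ax2.plot([0, 1], [0, 1], ls="--", color="grey")
    ax2.set_xlabel("1 - specificity")
    ax2.set_ylabel("sensitivity")
    ax2.set_title(f"ROC, AUC = {d.auc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
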