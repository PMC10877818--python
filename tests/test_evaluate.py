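"""Concordance table, t-test, ROC/AUC, Youden cutoff, cohort evaluation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lhsurge as lh
from lhsurge.evaluate import (
    compute_offsets,
    confusion_at_cutoff,
    diagnostic_analysis,
    evaluate_cohort,
    roc_analysis,
    students_t_test,
    youden_cutoff,
)
from lhsurge.preprocess import LodConfig, preprocess_cohort
from lhsurge.types import (
    ConcordanceTable,
    ConfusionMetrics,
    InsufficientCohortError,
    InsufficientDataError,
    SurgeCall,
)


def _pair(offset, pid="P1", cid="C1", ovulation=15):
    """A (urine, vd) call pair realizing a given first-surge offset."""
    u = SurgeCall(pid, cid, lh.URINE, 1.0, ovulation - 1, (ovulation - 1,),
                  lh.SHARP_SINGLE, ovulation - 1, ovulation,
                  (ovulation - 5, ovulation), 4)
    v = SurgeCall(pid, cid, lh.VAGINAL_DISCHARGE, 0.05, ovulation + offset,
                  (ovulation + offset,), lh.SHARP_SINGLE, ovulation + offset,
                  None, None, 4)
    return u, v


class TestComputeOffsets:
    def test_single_cycle_on_ovulation_day(self):
        table = compute_offsets([_pair(0)])
        assert table.counts[0] == 1
        assert table.within_window_pct == 100

    def test_offset_minus_six_lands_in_others(self):
        table = compute_offsets([_pair(-6)])
        assert table.others == 1
        assert table.within_window_count == 0

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_offsets([])

    def test_counts_sum_to_total_and_percentages_round(self):
        offsets = [-5] * 3 + [-1] * 3 + [2]
        pairs = [_pair(o, pid=f"P{i}") for i, o in enumerate(offsets)]
        table = compute_offsets(pairs)
        assert sum(table.counts.values()) + table.others == table.total == 7
        # 3/7 = 42.857 -> 43 under round-half-up
        assert table.percentages["-5"] == 43
        assert table.percentages["others"] == 14
        # rounding keeps the row sum within one unit per row
        total_pct = sum(table.percentages.values())
        assert abs(total_pct - 100) <= len(table.percentages)


class TestStudentsTTest:
    def test_identical_groups(self):
        t, df, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_three_point_hand_computation(self):
        # pooled SD 1, SE sqrt(2/3): t = -3/sqrt(2/3) = -3.6742, df 4
        t, df, p = students_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-9)
        assert df == 4
        expected_p = 0.021311641128756713  # frozen: 2*sf(3.6742, df=4)
        assert p == pytest.approx(expected_p, abs=1e-9)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning):
            t, df, p = students_t_test([1, 1], [2, 2])
        assert t == -np.inf
        assert p == 0.0

    def test_group_of_one_rejected(self):
        with pytest.raises(InsufficientDataError):
            students_t_test([1.0], [1.0, 2.0])

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0]
        b = [2.0, 4.0, 0.5, 3.5]
        _, df_s, _ = students_t_test(a, b)
        _, df_w, _ = students_t_test(a, b, welch=True)
        assert df_s == 6
        assert df_w < df_s


class TestRocAnalysis:
    def test_perfect_separation(self):
        *_, auc = roc_analysis([0.9, 0.8], [0.1, 0.2])
        assert auc == pytest.approx(1.0)

    def test_partial_overlap_three_of_four_pairs(self):
        *_, auc = roc_analysis([0.6, 0.4], [0.5, 0.3])
        assert auc == pytest.approx(0.75)

    def test_identical_groups_give_half(self):
        *_, auc = roc_analysis([0.3, 0.7], [0.3, 0.7])
        assert auc == pytest.approx(0.5)

    def test_curve_is_monotone_and_anchored(self):
        rng = np.random.default_rng(0)
        fpr, tpr, _, _ = roc_analysis(rng.normal(1, 1, 20),
                                      rng.normal(0, 1, 15))
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=12),
        st.lists(st.integers(0, 20), min_size=1, max_size=12),
    )
    def test_auc_equals_mann_whitney_exceedance(self, pos, neg):
        """Trapezoid AUC == (#{pos>neg} + 0.5 #{pos==neg}) / (n_p n_n).
        Integer scores force plenty of ties."""
        *_, auc = roc_analysis(pos, neg)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)


def _exhaustive_youden(pos, neg):
    """Independent scan: J over every observed value as a >= cutoff."""
    best_j, best_cut = -np.inf, None
    for cut in sorted(set(pos) | set(neg)):  # ascending: low cutoffs first
        tp = sum(p >= cut for p in pos)
        fp = sum(n >= cut for n in neg)
        sens = tp / len(pos)
        spec = 1 - fp / len(neg)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return best_cut, best_j


class TestYoudenCutoff:
    def test_perfect_separation_picks_lowest_positive_value(self):
        cutoff, cm, _ = youden_cutoff([0.9, 0.8], [0.1, 0.2])
        assert cutoff == pytest.approx(0.8)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 0, 2, 0)

    def test_all_identical_values_degenerate_with_warning(self):
        cutoff, cm, warns = youden_cutoff([1.0, 1.0], [1.0, 1.0])
        assert cutoff == pytest.approx(1.0)
        assert any("degenerate" in w for w in warns)
        for metric in (cm.sensitivity, cm.specificity, cm.ppv, cm.npv,
                       cm.accuracy):
            assert 0 <= metric <= 100

    @given(
        st.lists(st.integers(0, 15), min_size=2, max_size=10),
        st.lists(st.integers(0, 15), min_size=2, max_size=10),
    )
    def test_matches_exhaustive_scan(self, pos, neg):
        cutoff, cm, _ = youden_cutoff(pos, neg)
        expected_cut, expected_j = _exhaustive_youden(pos, neg)
        j = cm.sensitivity_exact / 100 + cm.specificity_exact / 100 - 1
        assert j == pytest.approx(expected_j, abs=1e-9)
        assert cutoff == pytest.approx(expected_cut)


class TestConfusionMetrics:
    def test_derived_study_matrix(self):
        """TP=25 FN=4 TN=24 FP=5 -> 86/83/83/86 under round-half-up."""
        cm = ConfusionMetrics(tp=25, fn=4, tn=24, fp=5)
        assert cm.as_dict() == {
            "sensitivity": 86, "specificity": 83, "ppv": 83, "npv": 86,
            "accuracy": 84,
        }

    def test_accuracy_and_rates_share_one_matrix(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 30)
        cutoff, cm, _ = youden_cutoff(pos, neg)
        cm2 = confusion_at_cutoff(pos, neg, cutoff)
        assert cm == cm2
        assert cm.accuracy_exact == pytest.approx(
            100 * (cm.tp + cm.tn) / (cm.tp + cm.tn + cm.fp + cm.fn)
        )


class TestEvaluateCohort:
    @staticmethod
    def _run(cfg):
        cohort = lh.generate_cohort(cfg)
        series = preprocess_cohort(cohort.raw_frame(), LodConfig(0, 0, 0, 0))
        calls = lh.call_cohort(series)
        return evaluate_cohort(calls, series)

    def test_well_separated_zero_noise_cohort_has_auc_one(self):
        cfg = dataclasses.replace(
            lh.GeneratorConfig(), seed=21, noise_cv=0.0, p_missing_day=0.0,
            p_collection_fail=0.0, vlh_baseline_level=(0.05, 0.0),
            vlh_lag_probs={0: 1.0},
        )
        report = self._run(cfg)
        assert report.diagnostic.auc == pytest.approx(1.0)
        assert report.diagnostic.p_value < 1e-6

    def test_lag_spread_inside_window_gives_full_concordance(self):
        # sharp-only surges with lag in {-4..0}: offsets land on -5..-1
        cfg = dataclasses.replace(
            lh.GeneratorConfig(), seed=22, noise_cv=0.0, p_missing_day=0.0,
            p_collection_fail=0.0,
            pattern_probs={lh.SHARP_SINGLE: 1.0},
            vlh_lag_probs={k: 0.2 for k in range(-4, 1)},
        )
        report = self._run(cfg)
        assert report.concordance.within_window_pct == 100
        assert report.concordance.others == 0

    def test_large_lead_puts_every_cycle_in_others(self):
        # lag -6 with late peaks: first surge 7 days before ovulation
        cfg = dataclasses.replace(
            lh.GeneratorConfig(), seed=23, noise_cv=0.0, p_missing_day=0.0,
            p_collection_fail=0.0,
            pattern_probs={lh.SHARP_SINGLE: 1.0},
            peak_day_range=(16, 17), vlh_lag_probs={-6: 1.0},
        )
        report = self._run(cfg)
        assert report.concordance.within_window_count == 0
        assert report.concordance.others == report.concordance.total

    def test_insufficient_cohort_raises(self):
        cfg = dataclasses.replace(
            lh.GeneratorConfig(), seed=24, n_participants=3, total_cycles=None,
            noise_cv=0.0, p_missing_day=0.0, p_collection_fail=0.0,
            peak_day_range=(17, 17),
            pattern_probs={lh.SHARP_SINGLE: 1.0},
            vlh_lag_probs={4: 1.0},  # every vLH surge truncated out
        )
        with pytest.raises(InsufficientCohortError):
            self._run(cfg)

    def test_funnel_counts_engineered_cohort(self):
        cfg = dataclasses.replace(
            lh.GeneratorConfig(), seed=25, noise_cv=0.0, p_missing_day=0.0,
            p_collection_fail=0.0, vlh_lag_probs={0: 1.0},
        )
        cohort = lh.engineer_funnel_cohort(cfg, 6, 15, 5)
        series = preprocess_cohort(cohort.raw_frame(), LodConfig(0, 0, 0, 0))
        calls = lh.call_cohort(series)
        report = evaluate_cohort(calls, series)
        assert report.funnel == {
            "cycles_total": 55, "ulh_surge": 49, "vd_available": 34,
            "vlh_surge": 29,
        }
        assert len(report.diagnostic.baseline_group) == 29
        assert len(report.diagnostic.surge_group) == 29


def test_diagnostic_analysis_is_internally_consistent():
    rng = np.random.default_rng(11)
    baseline = rng.lognormal(-3, 0.4, 30)
    surge = rng.lognormal(-1.8, 0.5, 30)
    d = diagnostic_analysis(baseline, surge)
    assert 0 <= d.auc <= 1
    cm = confusion_at_cutoff(surge, baseline, d.optimal_cutoff)
    assert cm == d.confusion
    assert d.degrees_of_freedom == 58
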