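import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from appscore.cohort import Cohort
from appscore.evaluation import (
    ConfusionMatrix,
    cohen_kappa,
    cohort_summary,
    compare_systems,
    confusion,
    duration_table,
    metrics,
    pct,
    roc_analysis,
)

from conftest import all_positive_record, make_record


def auc_pair_counting(scores, truths) -> float:
    """Exhaustive ordered-pair oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        pred = [True] * 50 + [False] * 50
        cm = confusion(pred, pred)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (50, 0, 0, 50)

    def test_perfect_disagreement(self):
        truth = [True] * 30 + [False] * 30
        cm = confusion([not t for t in truth], truth)
        assert cm.tp == cm.tn == 0

    def test_hand_enumerated_fixture(self):
        pred = [True, True, True, False, False, False]
        truth = [True, True, False, True, False, False]
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 2)
        assert cm.n == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([True], [True, False])


class TestMetrics:
    def test_published_pas_counts(self):
        m = metrics(ConfusionMatrix(tp=192, fp=46, fn=156, tn=564))
        assert pct(m.sensitivity) == 55.2
        assert pct(m.specificity) == 92.5
        assert pct(m.npv) == 78.3
        assert pct(m.ppv) == 80.7  # 192/238 = 80.67%

    def test_perfect_two_patient_case(self):
        m = metrics(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_symmetric_matrix_gives_half(self):
        m = metrics(ConfusionMatrix(tp=25, fp=25, fn=25, tn=25))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (0.5, 0.5, 0.5, 0.5)

    def test_undefined_denominators_reported_as_none(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None  # no true positives or false negatives
        assert m.ppv is None
        assert m.specificity == 1.0

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tn=st.integers(0, 500),
    )
    def test_brute_force_formulas(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp, fp, fn, tn)
        m = metrics(cm)
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m.npv == pytest.approx(tn / (tn + fn))


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(tp=40, fp=0, fn=0, tn=60)) == 1.0

    def test_independent_margins(self):
        assert cohen_kappa(ConfusionMatrix(tp=25, fp=25, fn=25, tn=25)) == 0.0

    def test_published_counts(self):
        pas = cohen_kappa(ConfusionMatrix(tp=192, fp=46, fn=156, tn=564))
        ass = cohen_kappa(ConfusionMatrix(tp=271, fp=188, fn=77, tn=422))
        nss = cohen_kappa(ConfusionMatrix(tp=336, fp=101, fn=12, tn=509))
        assert pas == pytest.approx(0.5110, abs=5e-4)
        assert ass == pytest.approx(0.4404, abs=5e-4)
        assert nss > pas > ass

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        fn=st.integers(0, 200), tn=st.integers(0, 200),
    )
    def test_transpose_invariance_and_float_formula(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        cm = ConfusionMatrix(tp, fp, fn, tn)
        n = cm.n
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        if pe == 1.0:
            with pytest.raises(ValueError):
                cohen_kappa(cm)
            return
        k = cohen_kappa(cm)
        assert k == pytest.approx((po - pe) / (1 - pe), rel=1e-12, abs=1e-12)
        # swapping prediction and truth swaps fp and fn only
        assert k == pytest.approx(cohen_kappa(ConfusionMatrix(tp, fn, fp, tn)))

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa(ConfusionMatrix(tp=10, fp=0, fn=0, tn=0))


class TestROC:
    def test_scores_equal_truth_indicator(self):
        truth = [True] * 10 + [False] * 15
        res = roc_analysis([1.0 * t for t in truth], truth)
        assert res.auc == 1.0

    def test_constant_scores_uninformative(self):
        truth = [True] * 10 + [False] * 10
        res = roc_analysis([3.0] * 20, truth)
        assert res.auc == 0.5

    def test_one_class_is_error(self):
        with pytest.raises(ValueError, match="class"):
            roc_analysis([1.0, 2.0], [True, True])

    def test_pair_counting_oracle_random_cohorts(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = rng.integers(0, 15, size=n).astype(float)  # integer scores force ties
            res = roc_analysis(scores, truth)
            assert res.auc == pytest.approx(auc_pair_counting(scores, truth), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        truth = rng.random(150) < 0.35
        scores = rng.normal(size=150) + truth
        a1 = roc_analysis(scores, truth).auc
        a2 = roc_analysis(np.exp(scores), truth).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestDurationTable:
    def test_hand_fixture_half_false_positive_per_bin(self):
        # two patients per stratum: one true positive, one false positive
        durations, preds, truths = [], [], []
        for d in (6.0, 18.0, 36.0, 72.0):
            durations += [d, d]
            preds += [True, True]
            truths += [True, False]
        table = duration_table(durations, preds, truths)
        strata = table[table.duration != "Total"]
        assert (strata.n == 2).all()
        assert (strata.fp_share == 0.5).all()
        assert (strata.tp_share == 0.5).all()

    def test_bins_partition_and_totals_match_overall(self):
        rng = np.random.default_rng(5)
        n = 500
        durations = np.maximum(rng.lognormal(3.2, 0.9, n), 1.0)
        truths = rng.random(n) < 0.4
        preds = rng.random(n) < 0.5
        table = duration_table(durations, preds, truths)
        strata = table[table.duration != "Total"]
        total = table[table.duration == "Total"].iloc[0]
        assert strata.n.sum() == n == total.n
        shares = strata[["tn_share", "fp_share", "fn_share", "tp_share"]].sum(axis=1)
        assert np.allclose(shares[strata.n > 0], 1.0)
        cm = confusion(preds, truths)
        assert (total.tp, total.fp, total.fn, total.tn) == (cm.tp, cm.fp, cm.fn, cm.tn)

    def test_single_bin_perfect_predictions(self):
        table = duration_table([5.0, 6.0], [True, False], [True, False])
        first = table.iloc[0]
        assert first.n == 2 and first.tp == 1 and first.tn == 1
        assert (table[table.duration != "Total"].iloc[1:].n == 0).all()

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            duration_table([0.0], [True], [True])


def _accounting_cohort(n_op_pos: int, n_op_neg: int, n_unop: int) -> Cohort:
    records = []
    i = 0
    for _ in range(n_op_pos):
        records.append(make_record(patient_id=f"P{i}", operated=True, histopathology_positive=True)); i += 1
    for _ in range(n_op_neg):
        records.append(make_record(patient_id=f"P{i}", operated=True, histopathology_positive=False)); i += 1
    for _ in range(n_unop):
        records.append(make_record(patient_id=f"P{i}")); i += 1
    return Cohort.from_records(records)


class TestCohortSummary:
    def test_study_accounting(self):
        s = cohort_summary(_accounting_cohort(355, 45, 558))
        assert s.n_total == 958
        assert s.n_operated == 400
        assert s.n_histopathology_positive == 355
        assert s.negative_appendectomy_rate_pct == 11.3

    def test_all_operated_positive(self):
        s = cohort_summary(_accounting_cohort(10, 0, 0))
        assert s.negative_appendectomy_rate_pct == 0.0

    def test_half_negative(self):
        s = cohort_summary(_accounting_cohort(5, 5, 0))
        assert s.negative_appendectomy_rate_pct == 50.0

    def test_no_operations_rate_undefined(self):
        s = cohort_summary(_accounting_cohort(0, 0, 5))
        assert s.negative_appendectomy_rate is None
        assert s.negative_appendectomy_rate_pct is None


class TestCompareSystems:
    def test_two_patient_extremes(self):
        pos = all_positive_record(patient_id="A1")
        neg = make_record(patient_id="N1")
        reports = compare_systems(Cohort.from_records([pos, neg]))
        for rep in reports.values():
            assert (rep.cm.tp, rep.cm.fp, rep.cm.fn, rep.cm.tn) == (1, 0, 0, 1)
            assert rep.metrics.kappa == 1.0

    def test_totals_equal_cohort_size(self, default_cohort):
        for rep in compare_systems(default_cohort).values():
            assert rep.cm.n == len(default_cohort)

    def test_nss_dominates_on_default_cohort(self, default_cohort):
        reports = compare_systems(default_cohort)
        assert reports["nss"].metrics.kappa > reports["pas"].metrics.kappa
        assert reports["nss"].metrics.kappa > reports["ass"].metrics.kappa
        assert reports["nss"].metrics.auc > max(
            reports["pas"].metrics.auc, reports["ass"].metrics.auc
        )


def test_pct_rounds_half_away_from_zero():
    assert pct(0.1125) == 11.3
    assert pct(0.55172) == 55.2
    assert pct(45 / 400) == 11.3
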