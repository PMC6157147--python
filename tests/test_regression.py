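import dataclasses
import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm

from appscore.cohort import (
    CLINICAL_BIOCHEMICAL_PREDICTORS,
    RADIOLOGICAL_PREDICTORS,
    Cohort,
)
from appscore.regression import (
    DURATION_CANDIDATE,
    SUBGROUP_CANDIDATES,
    classification_metrics,
    forward_stepwise,
    multivariable_lr,
    or_from_counts,
    subgroup_analyses,
    univariable_or,
)
from appscore.simulate import default_config, generate_cohort

from conftest import make_record


class TestUnivariableOR:
    def test_matches_statsmodels_logit_oracle(self, default_cohort):
        # closed-form 2x2 estimate == single-predictor logistic MLE
        y = default_cohort.group_a_mask.to_numpy(dtype=float)
        for predictor in ("heel_drop_positive", "guarding", "appendicolith", "male"):
            rec = univariable_or(default_cohort, predictor)
            x = default_cohort.df[predictor].astype(float).to_numpy()
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            assert rec.odds_ratio == pytest.approx(math.exp(fit.params[1]), rel=1e-6)
            se = fit.bse[1]
            assert rec.ci_low == pytest.approx(math.exp(fit.params[1] - 1.959964 * se), rel=1e-4)

    def test_heel_drop_counts_reproduce_published_or(self):
        # 233/122 positive/negative with appendicitis, 36/567 without
        rec = or_from_counts(233, 122, 36, 567, predictor="heel_drop_positive")
        assert rec.odds_ratio == pytest.approx(30.195, rel=0.02)

    def test_anorexia_counts_reproduce_published_or(self):
        rec = or_from_counts(274, 81, 329, 274, predictor="anorexia")
        assert rec.odds_ratio == pytest.approx(2.853, rel=0.02)

    def test_balanced_predictor_is_null(self):
        rec = or_from_counts(50, 50, 50, 50)
        assert rec.odds_ratio == pytest.approx(1.0)
        assert rec.ci_low < 1.0 < rec.ci_high

    def test_zero_cell_gets_haldane_correction(self):
        rec = or_from_counts(10, 5, 0, 20, predictor="rare")
        assert rec.flagged
        assert math.isfinite(rec.odds_ratio)
        assert "Haldane" in rec.note
        # +0.5 on every cell
        assert rec.odds_ratio == pytest.approx((10.5 * 20.5) / (5.5 * 0.5))

    def test_constant_predictor_is_error(self):
        records = [
            make_record(patient_id=f"P{i}", operated=i < 2,
                        histopathology_positive=True if i < 2 else None)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="vary"):
            univariable_or(Cohort.from_records(records), "guarding")


class TestMultivariableLR:
    def test_intercept_only_predicts_prevalence(self, default_cohort):
        records, model = multivariable_lr(default_cohort, [])
        probs = model.predict_proba(default_cohort)
        assert np.allclose(probs, 355 / 958, atol=1e-6)
        assert records == []

    def test_degenerate_columns_detected(self, default_cohort):
        df = default_cohort.df.copy()
        df["rlq_tenderness"] = True
        cohort = Cohort(df)
        records, model = multivariable_lr(cohort, ["guarding", "rlq_tenderness"])
        assert model.dropped == ["rlq_tenderness"]
        assert [r.predictor for r in records] == ["guarding"]

    def test_recovers_known_logistic_process(self):
        # outcome simulated directly from a logistic model over two findings
        rng = np.random.default_rng(3)
        n = 12000
        x1 = rng.random(n) < 0.4
        x2 = rng.random(n) < 0.3
        logit = -1.2 + 1.1 * x1 + 0.7 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        base = make_record()
        rows = {
            k: np.zeros(n, dtype=bool) for k in base.indicators
        }
        rows["guarding"], rows["rebound"] = x1, x2
        df_cols = {
            "patient_id": [f"P{i}" for i in range(n)],
            "age_years": np.full(n, 10.0),
            "duration_hours": np.full(n, 24.0),
            "male": np.zeros(n, dtype=bool),
            **rows,
            "operated": y,
            "histopathology_positive": [True if v else None for v in y],
        }
        import pandas as pd

        cohort = Cohort(pd.DataFrame(df_cols))
        records, _ = multivariable_lr(cohort, ["guarding", "rebound"])
        by_name = {r.predictor: r for r in records}
        assert by_name["guarding"].ci_low <= math.exp(1.1) <= by_name["guarding"].ci_high
        assert by_name["rebound"].ci_low <= math.exp(0.7) <= by_name["rebound"].ci_high

    def test_too_few_observations_rejected(self):
        records = [
            make_record(patient_id=f"P{i}", operated=i == 0,
                        histopathology_positive=True if i == 0 else None)
            for i in range(2)
        ]
        cohort = Cohort.from_records(records)
        with pytest.raises(ValueError, match="observations"):
            multivariable_lr(cohort, ["guarding", "rebound", "pyrexia"])


def _signal_config(seed: int, n: int = 4000):
    base = default_config()
    prev = {k: (0.3, 0.3) for k in base.prevalence}
    for s in ("continuous_pain", "guarding", "neutrophilia"):
        prev[s] = (0.2, 1.25 / 2.25)  # odds 0.25 vs 1.25 -> true OR 5
    return dataclasses.replace(
        base,
        prevalence=prev,
        n_appendicitis=n // 2,
        n_non_appendicitis=n // 2,
        correlation_strength=0.0,
        seed=seed,
    )


class TestForwardStepwise:
    SIGNALS = ["continuous_pain", "guarding", "neutrophilia"]
    NULLS = ["heel_drop_positive", "gurgling", "pyrexia"]

    def test_signal_recovery(self):
        cohort = generate_cohort(_signal_config(seed=21, n=8000))
        res = forward_stepwise(cohort, self.SIGNALS + self.NULLS, entry_p=0.01, removal_p=0.05)
        assert set(self.SIGNALS) <= set(res.retained)
        assert len(res.retained) <= 4

    def test_determinism(self):
        cohort = generate_cohort(_signal_config(seed=22))
        cands = self.SIGNALS + self.NULLS
        r1 = forward_stepwise(cohort, cands)
        r2 = forward_stepwise(cohort, cands)
        assert r1.retained == r2.retained
        assert r1.coefficients == r2.coefficients

    def test_empty_candidates_give_intercept_only(self, default_cohort):
        res = forward_stepwise(default_cohort, [])
        assert res.retained == []
        assert set(res.coefficients) == {"const"}

    def test_null_candidate_entry_rate(self):
        # a single null predictor should enter in about entry_p of replicates
        entered = 0
        for seed in range(60):
            base = default_config()
            prev = {k: (0.3, 0.3) for k in base.prevalence}
            cfg = dataclasses.replace(
                base, prevalence=prev, n_appendicitis=600, n_non_appendicitis=600,
                correlation_strength=0.0, seed=3000 + seed,
            )
            cohort = generate_cohort(cfg)
            res = forward_stepwise(cohort, ["guarding"], entry_p=0.05)
            entered += bool(res.retained)
        assert entered / 60 <= 0.15


class TestSubgroupAnalyses:
    def test_candidate_sets_partition(self):
        clin = set(SUBGROUP_CANDIDATES["clinical_biochemical"])
        rad = set(SUBGROUP_CANDIDATES["radiological"])
        assert clin & rad == set()
        assert set(SUBGROUP_CANDIDATES["combined"]) == clin | rad
        assert DURATION_CANDIDATE in clin

    def test_combined_dominates_subgroups(self, default_cohort):
        results = subgroup_analyses(default_cohort)
        combined = results["combined"]
        assert combined.auc >= results["radiological"].auc
        assert combined.auc >= results["clinical_biochemical"].auc
        # radiological findings alone miss more true appendicitis
        assert results["radiological"].sensitivity <= combined.sensitivity

    def test_metrics_attached(self, default_cohort):
        for res in subgroup_analyses(default_cohort).values():
            assert 0.0 <= res.sensitivity <= 1.0
            assert 0.0 <= res.specificity <= 1.0
            assert 0.5 <= res.auc <= 1.0
            assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]


class TestClassificationMetrics:
    def test_intercept_only_model_is_uninformative(self, default_cohort):
        _, model = multivariable_lr(default_cohort, [])
        m = classification_metrics(model, default_cohort, threshold=0.5)
        # constant probability 355/958 < 0.5: nobody classified positive
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.auc == pytest.approx(0.5)

    def test_strong_model_near_perfect(self):
        cohort = generate_cohort(_signal_config(seed=30, n=6000))
        res = forward_stepwise(cohort, TestForwardStepwise.SIGNALS)
        m = classification_metrics(res.model, cohort)
        assert m.auc > 0.7
        assert m.auc_ci[0] < m.auc < m.auc_ci[1]

    def test_one_class_cohort_is_error(self):
        records = [
            make_record(patient_id=f"P{i}", operated=True, histopathology_positive=True)
            for i in range(5)
        ]
        cohort = Cohort.from_records(records)
        _, model = multivariable_lr(cohort, [])
        with pytest.raises(ValueError, match="class"):
            classification_metrics(model, cohort)
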