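"""Odds-ratio estimation and forward stepwise logistic regression.

The outcome throughout is histopathologically proven appendicitis (Group A).
Three layers:

* :func:`univariable_or` — per-predictor odds ratio.  For a single binary
  predictor the logistic-regression MLE coincides with the 2x2
  cross-product ratio ad/bc, so the estimate is computed in closed form
  from the table with a Wald CI on the log scale.  Zero cells get the
  Haldane-Anscombe +0.5 correction (applied to all four cells, flagged).
* :func:`multivariable_lr` — maximum-likelihood logistic fit of the outcome
  on several predictors at once (statsmodels), with adjusted ORs and Wald
  CIs.  Degenerate (constant) columns are detected, dropped and reported.
* :func:`forward_stepwise` — classic forward selection: at each step the
  candidate with the smallest Rao score-test p-value enters if it clears
  ``entry_p`` (ties broken by candidate order), then included terms whose
  Wald p exceeds ``removal_p`` are removed, until nothing changes.  The
  procedure is deterministic given the cohort and candidate order.

``duration_gt24h`` (symptom duration above 24 hours) is accepted as a
candidate anywhere a predictor name is; it is derived on the fly from
``duration_hours``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import (
    CLINICAL_BIOCHEMICAL_PREDICTORS,
    NSS_PREDICTORS,
    RADIOLOGICAL_PREDICTORS,
    Cohort,
)
from .evaluation import ROCResult, confusion, metrics, roc_analysis

__all__ = [
    "ORRecord",
    "or_from_counts",
    "univariable_or",
    "univariable_or_table",
    "FittedLogit",
    "multivariable_lr",
    "forward_stepwise",
    "StepwiseResult",
    "subgroup_analyses",
    "classification_metrics",
    "ClassificationMetrics",
    "DURATION_CANDIDATE",
]

Z975 = stats.norm.ppf(0.975)

#: derived stepwise candidate: symptom duration above 24 hours
DURATION_CANDIDATE = "duration_gt24h"


@dataclass(frozen=True)
class ORRecord:
    """A predictor's odds ratio with 95% CI and Wald p-value."""

    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.predictor}: odds ratio must be positive")


def or_from_counts(a: int, b: int, c: int, d: int, predictor: str = "") -> ORRecord:
    """Odds ratio from a 2x2 table.

    ``a``/``b`` are predictor-positive/negative counts in the appendicitis
    group, ``c``/``d`` the same in the non-appendicitis group; OR = ad/bc.
    With any zero cell, 0.5 is added to all four cells (Haldane-Anscombe)
    and the record is flagged.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    flagged = 0 in (a, b, c, d)
    note = "Haldane-Anscombe +0.5 applied (zero cell)" if flagged else ""
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if flagged else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return ORRecord(
        predictor=predictor,
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=float(p),
        flagged=flagged,
        note=note,
    )


def _predictor_column(cohort: Cohort, name: str) -> np.ndarray:
    if name == DURATION_CANDIDATE:
        return (cohort.df["duration_hours"].to_numpy(dtype=float) > 24.0).astype(float)
    if name not in cohort.df.columns:
        raise KeyError(f"unknown predictor {name!r}")
    return cohort.df[name].astype(bool).to_numpy(dtype=float)


def univariable_or(cohort: Cohort, predictor: str) -> ORRecord:
    """Single-predictor odds ratio of Group A membership.

    Equals the single-binary-predictor logistic MLE exp(beta); verified
    against a statsmodels fit in the test suite.
    """
    x = _predictor_column(cohort, predictor).astype(bool)
    y = cohort.group_a_mask.to_numpy()
    if x.all() or (~x).all():
        raise ValueError(f"{predictor!r} does not vary within the cohort")
    a = int((x & y).sum())
    b = int((~x & y).sum())
    c = int((x & ~y).sum())
    d = int((~x & ~y).sum())
    return or_from_counts(a, b, c, d, predictor=predictor)


def univariable_or_table(
    cohort: Cohort,
    predictors: Sequence[str] = NSS_PREDICTORS,
    skip_degenerate: bool = False,
) -> list[ORRecord]:
    """One :func:`univariable_or` per predictor, in the given order.

    With ``skip_degenerate``, predictors that do not vary in the cohort are
    silently omitted instead of raising (useful on tiny fixtures).
    """
    out = []
    for p in predictors:
        try:
            out.append(univariable_or(cohort, p))
        except ValueError:
            if not skip_degenerate:
                raise
    return out


@dataclass
class FittedLogit:
    """A fitted logistic model bound to the predictor names it was built on."""

    predictors: list[str]
    result: object  # statsmodels BinaryResultsWrapper
    dropped: list[str] = field(default_factory=list)
    converged: bool = True

    def predict_proba(self, cohort: Cohort) -> np.ndarray:
        X = _design(cohort, self.predictors)
        return np.asarray(self.result.predict(X))

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(["const"] + self.predictors, np.asarray(self.result.params)))


def _design(cohort: Cohort, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    cols += [_predictor_column(cohort, p) for p in predictors]
    return np.column_stack(cols)


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[object, bool]:
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=100)
        return res, bool(res.mle_retvals.get("converged", True))
    except Exception:
        # quasi/complete separation or other Newton failure: regularized fallback
        res = model.fit_regularized(alpha=1e-8, disp=0, maxiter=500)
        return res, False


def multivariable_lr(
    cohort: Cohort, predictors: Sequence[str]
) -> tuple[list[ORRecord], FittedLogit]:
    """Adjusted odds ratios from a joint logistic fit.

    Constant (degenerate) columns are dropped before fitting and listed in
    ``FittedLogit.dropped``.  Non-convergence or separation yields flagged
    records rather than a crash.
    """
    y = cohort.group_a_mask.to_numpy(dtype=float)
    if len(cohort) <= len(predictors):
        raise ValueError("need more observations than predictors")
    kept, dropped = [], []
    for p in predictors:
        col = _predictor_column(cohort, p)
        (kept if col.std() > 0 else dropped).append(p)
    X = _design(cohort, kept)
    res, converged = _fit_logit(y, X)
    params = np.asarray(res.params)
    try:
        se = np.asarray(res.bse)
    except Exception:
        se = np.full_like(params, np.nan)
    records = []
    for i, name in enumerate(kept, start=1):
        beta, s = params[i], se[i]
        huge = not np.isfinite(s) or s > 50 or abs(beta) > 15
        ci_low = math.exp(beta - Z975 * s) if np.isfinite(s) else 0.0
        ci_high = math.exp(beta + Z975 * s) if np.isfinite(s) else math.inf
        p = 2.0 * stats.norm.sf(abs(beta) / s) if np.isfinite(s) and s > 0 else float("nan")
        records.append(
            ORRecord(
                predictor=name,
                odds_ratio=math.exp(beta),
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=float(p),
                flagged=huge or not converged,
                note="possible separation or non-convergence" if (huge or not converged) else "",
            )
        )
    return records, FittedLogit(predictors=kept, result=res, dropped=dropped, converged=converged)


def _score_test_p(y: np.ndarray, X: np.ndarray, probs: np.ndarray, x_new: np.ndarray) -> float:
    """Rao score test p-value for adding ``x_new`` to the fitted model (X, probs)."""
    if x_new.std() == 0:
        return 1.0
    w = probs * (1.0 - probs)
    u = float(x_new @ (y - probs))
    xwx = float((x_new * w) @ x_new)
    XtWx = X.T @ (w * x_new)
    XtWX = X.T @ (w[:, None] * X)
    try:
        v = xwx - float(XtWx @ np.linalg.solve(XtWX, XtWx))
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, df=1))


@dataclass
class StepwiseResult:
    candidate_set: str
    candidates: list[str]
    retained: list[str]  # in entry order
    model: FittedLogit
    entry_p: float
    removal_p: float
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None

    @property
    def coefficients(self) -> dict[str, float]:
        return self.model.params


def forward_stepwise(
    cohort: Cohort,
    candidates: Sequence[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    name: str = "custom",
) -> StepwiseResult:
    """Forward stepwise logistic selection with score-test entry / Wald removal."""
    if not (0 < entry_p < 1) or not (0 < removal_p < 1):
        raise ValueError("entry_p and removal_p must be in (0,1)")
    y = cohort.group_a_mask.to_numpy(dtype=float)
    candidates = list(candidates)
    included: list[str] = []
    seen: set[frozenset] = {frozenset()}  # guard against enter/remove cycles

    while True:
        X = _design(cohort, included)
        res, _ = _fit_logit(y, X)
        probs = np.asarray(res.predict(X))
        changed = False

        remaining = [c for c in candidates if c not in included]
        best_p, best_c = None, None
        for c in remaining:
            p = _score_test_p(y, X, probs, _predictor_column(cohort, c))
            if best_p is None or p < best_p:  # strict <: ties keep list order
                best_p, best_c = p, c
        if best_c is not None and best_p < entry_p:
            included.append(best_c)
            changed = True
            X = _design(cohort, included)
            res, _ = _fit_logit(y, X)

        # backward pass: drop the worst included term above removal_p
        if included:
            try:
                se = np.asarray(res.bse)
            except Exception:  # regularized fallback without a covariance
                se = None
            params = np.asarray(res.params)
            if se is None or not np.all(np.isfinite(se[1:])) or np.any(se[1:] <= 0):
                if not changed:
                    break
                continue
            wald_p = 2.0 * stats.norm.sf(np.abs(params[1:]) / se[1:])
            worst = int(np.argmax(wald_p))
            if wald_p[worst] > removal_p:
                included.pop(worst)
                changed = True

        if not changed:
            break
        state = frozenset(included)
        if state in seen:  # a term is oscillating in and out; stop here
            break
        seen.add(state)

    X = _design(cohort, included)
    res, converged = _fit_logit(y, X)
    model = FittedLogit(predictors=included, result=res, converged=converged)
    return StepwiseResult(
        candidate_set=name,
        candidates=candidates,
        retained=list(included),
        model=model,
        entry_p=entry_p,
        removal_p=removal_p,
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    auc: float
    auc_ci: tuple[float, float]
    threshold: float


def classification_metrics(
    model: FittedLogit, cohort: Cohort, threshold: float = 0.5
) -> ClassificationMetrics:
    """In-sample sensitivity/specificity at a probability threshold, plus ROC AUC.

    The AUC uses the rank (Mann-Whitney) construction over the fitted
    probabilities with a Hanley-McNeil normal-approximation CI.
    """
    truth = cohort.group_a_mask.to_numpy()
    if truth.all() or (~truth).all():
        raise ValueError("both outcome classes must be present")
    probs = model.predict_proba(cohort)
    cm = confusion(probs >= threshold, truth)
    m = metrics(cm)
    roc = roc_analysis(probs, truth)
    return ClassificationMetrics(
        sensitivity=m.sensitivity if m.sensitivity is not None else float("nan"),
        specificity=m.specificity if m.specificity is not None else float("nan"),
        auc=roc.auc,
        auc_ci=(roc.ci_low, roc.ci_high),
        threshold=threshold,
    )


#: Candidate sets for the three subgroup analyses.  Symptom duration >24 h is
#: a candidate wherever clinical history enters (it was retained in both the
#: clinical/biochemical and the combined published analyses).
SUBGROUP_CANDIDATES: dict[str, tuple[str, ...]] = {
    "clinical_biochemical": CLINICAL_BIOCHEMICAL_PREDICTORS + (DURATION_CANDIDATE,),
    "radiological": RADIOLOGICAL_PREDICTORS,
    "combined": NSS_PREDICTORS + (DURATION_CANDIDATE,),
}


def subgroup_analyses(
    cohort: Cohort,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    threshold: float = 0.5,
) -> dict[str, StepwiseResult]:
    """Forward stepwise selection within each predictor subgroup.

    Runs the clinical/biochemical, radiological-only, and combined candidate
    sets and attaches in-sample sensitivity, specificity and AUC (at the
    given probability threshold) to each result.
    """
    out: dict[str, StepwiseResult] = {}
    for name, cands in SUBGROUP_CANDIDATES.items():
        result = forward_stepwise(cohort, cands, entry_p, removal_p, name=name)
        cmets = classification_metrics(result.model, cohort, threshold)
        result.sensitivity = cmets.sensitivity
        result.specificity = cmets.specificity
        result.auc = cmets.auc
        result.auc_ci = cmets.auc_ci
        out[name] = result
    return out
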