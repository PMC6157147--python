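"""Diagnostic-performance evaluation: confusion matrices, sensitivity /
specificity / predictive values, Cohen's kappa, ROC curves, symptom-duration
strata, and cohort accounting.

The reclassification comparison relabels every patient strictly by each
score's cutoff (ASS >= 7, PAS >= 8, NSS >= 12) and tabulates the resulting
2x2 tables against histopathological truth (Group A).  Percentages are
reported at one decimal with round-half-away-from-zero, matching clinical
reporting convention; the raw fractions are always kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .cohort import Cohort
from .scorers import PointTable, default_point_table, score_cohort

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "confusion",
    "metrics",
    "cohen_kappa",
    "ROCResult",
    "roc_analysis",
    "duration_table",
    "DURATION_BIN_EDGES",
    "cohort_summary",
    "CohortSummary",
    "compare_systems",
    "SystemReport",
    "pct",
]


def pct(fraction: Optional[float], decimals: int = 1) -> Optional[float]:
    """Percentage at fixed decimals, round-half-away-from-zero (so 11.25 -> 11.3).

    ``None`` (an undefined metric) passes through unchanged.
    """
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predictions: Sequence[bool], truths: Sequence[bool]) -> ConfusionMatrix:
    """Cross-tabulate predicted positives against true (Group A) status."""
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportions are fractions in [0,1]; None where the denominator is zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    kappa: Optional[float] = None
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV from a 2x2 table.

    A metric whose denominator is empty (e.g. PPV with no predicted
    positives) is reported as None — undefined, never silently zero.
    """
    return DiagnosticMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between classification and truth.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = (TP+TN)/n and expected agreement p_e from the marginal products.
    Computed in exact rational arithmetic and converted to float at the end,
    so boundary cases (perfect agreement, independent margins) are exact.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = Fraction(cm.tp + cm.tn, n)
    pred_pos = Fraction(cm.tp + cm.fp, n)
    truth_pos = Fraction(cm.tp + cm.fn, n)
    pe = pred_pos * truth_pos + (1 - pred_pos) * (1 - truth_pos)
    if pe == 1:
        raise ValueError("degenerate margins: expected agreement is 1, kappa undefined")
    return float((po - pe) / (1 - pe))


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    # Hanley & McNeil (1982) normal-approximation standard error of the AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(scores: Sequence[float], truths: Sequence[bool]) -> ROCResult:
    """ROC sweep over observed score values; AUC by the rank construction.

    The AUC equals the probability that a random appendicitis patient
    outscores a random non-appendicitis patient (ties count half); the 95%
    CI uses the Hanley-McNeil normal approximation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truths, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = _sk_roc_curve(y, s)
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    z = stats.norm.ppf(0.975)
    return ROCResult(
        auc=auc,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
    )


#: Symptom-duration strata in hours: (0,12], (12,24], (24,48], (48,inf).
DURATION_BIN_EDGES: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, float("inf"))
_BIN_LABELS = ("<=12 h", "12-24 h", "24-48 h", ">48 h")


def duration_table(
    durations: Sequence[float],
    predictions: Sequence[bool],
    truths: Sequence[bool],
) -> pd.DataFrame:
    """Accuracy of a classification stratified by symptom duration.

    Bins are half-open (low, high] so the four strata partition (0, inf).
    Per stratum: n and the shares of TN / FP / FN / TP among that stratum's
    patients (they sum to 1); a final "Total" row pools all strata and
    reproduces the overall confusion matrix.
    """
    d = np.asarray(durations, dtype=float)
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if not (d > 0).all():
        raise ValueError("durations must be positive")
    if not (d.shape == pred.shape == truth.shape):
        raise ValueError("length mismatch")

    cells = {
        "tn": ~pred & ~truth,
        "fp": pred & ~truth,
        "fn": ~pred & truth,
        "tp": pred & truth,
    }
    rows = []
    edges = DURATION_BIN_EDGES
    for i, label in enumerate(_BIN_LABELS):
        in_bin = (d > edges[i]) & (d <= edges[i + 1])
        n = int(in_bin.sum())
        row: dict[str, object] = {"duration": label, "n": n}
        for cell, mask in cells.items():
            count = int((mask & in_bin).sum())
            row[cell] = count
            row[f"{cell}_share"] = count / n if n else float("nan")
        rows.append(row)
    total: dict[str, object] = {"duration": "Total", "n": int(d.size)}
    for cell, mask in cells.items():
        count = int(mask.sum())
        total[cell] = count
        total[f"{cell}_share"] = count / d.size
    rows.append(total)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_operated: int
    n_histopathology_positive: int
    negative_appendectomy_rate: Optional[float]

    @property
    def negative_appendectomy_rate_pct(self) -> Optional[float]:
        if self.negative_appendectomy_rate is None:
            return None
        return pct(self.negative_appendectomy_rate)


def cohort_summary(cohort: Cohort) -> CohortSummary:
    """Patient accounting: totals, operations, and the negative-appendectomy rate."""
    operated = cohort.df["operated"].astype(bool)
    n_op = int(operated.sum())
    n_pos = int(cohort.df["histopathology_positive"].eq(True).sum())
    rate = None if n_op == 0 else (n_op - n_pos) / n_op
    return CohortSummary(
        n_total=len(cohort),
        n_operated=n_op,
        n_histopathology_positive=n_pos,
        negative_appendectomy_rate=rate,
    )


@dataclass(frozen=True)
class SystemReport:
    """One scoring system's reclassification result on a cohort."""

    system: str
    cutoff: float
    cm: ConfusionMatrix
    metrics: DiagnosticMetrics


def compare_systems(
    cohort: Cohort,
    score_results: pd.DataFrame | None = None,
    table: PointTable | None = None,
) -> dict[str, SystemReport]:
    """Side-by-side reclassification of ASS, PAS and NSS on one cohort.

    Every patient is relabeled strictly by each score's cutoff; each system
    gets its confusion matrix, the four predictive metrics, Cohen's kappa
    against histopathological truth, and the ROC AUC of the underlying
    continuous score.
    """
    table = table or default_point_table()
    if score_results is None:
        score_results = score_cohort(cohort, table)
    truth = cohort.group_a_mask.to_numpy()
    from .scorers import ASS_CUTOFF, PAS_CUTOFF  # local to avoid re-export noise

    out: dict[str, SystemReport] = {}
    for system, cutoff in (("ass", ASS_CUTOFF), ("pas", PAS_CUTOFF), ("nss", table.cutoff)):
        pred = score_results[f"{system}_positive"].to_numpy()
        cm = confusion(pred, truth)
        base = metrics(cm)
        roc = roc_analysis(score_results[system].to_numpy(), truth)
        out[system] = SystemReport(
            system=system,
            cutoff=float(cutoff),
            cm=cm,
            metrics=DiagnosticMetrics(
                sensitivity=base.sensitivity,
                specificity=base.specificity,
                ppv=base.ppv,
                npv=base.npv,
                kappa=cohen_kappa(cm),
                auc=roc.auc,
                auc_ci=(roc.ci_low, roc.ci_high),
            ),
        )
    return out
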