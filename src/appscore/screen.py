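"""Univariate group comparison: every recorded variable tested between the
appendicitis and non-appendicitis groups.

Binary variables use the Pearson chi-square test on the 2x2 group-by-variable
table (no Yates continuity correction by default — a flag restores it);
continuous variables use the unpaired two-sample t-test (pooled variance by
default, Welch behind a flag).  Raw per-variable p-values are reported with
no multiple-testing adjustment, mirroring how such screens are reported
clinically; treat the 0.05 flags accordingly when 26 variables are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BINARY_VARIABLES, Cohort

__all__ = [
    "GroupComparison",
    "compare_binary",
    "compare_binary_counts",
    "compare_continuous",
    "screen_all",
    "TABLE_VARIABLES",
    "format_p",
]

ALPHA = 0.05

#: Screen order: (variable, kind).  Gender leads, then the two continuous
#: variables, then the findings in recording order.
TABLE_VARIABLES: tuple[tuple[str, str], ...] = (
    ("male", "binary"),
    ("age_years", "continuous"),
    ("duration_hours", "continuous"),
    ("continuous_pain", "binary"),
    ("migration_of_pain", "binary"),
    ("nausea", "binary"),
    ("anorexia", "binary"),
    ("bilious_vomiting", "binary"),
    ("pyrexia", "binary"),
    ("rlq_tenderness", "binary"),
    ("guarding", "binary"),
    ("rebound", "binary"),
    ("heel_drop_positive", "binary"),
    ("gi_motility_change", "binary"),
    ("gurgling", "binary"),
    ("leukocytosis", "binary"),
    ("neutrophilia", "binary"),
    ("crp_elevated", "binary"),
    ("negative_urinalysis", "binary"),
    ("scoliosis_right", "binary"),
    ("air_fluid_level", "binary"),
    ("gas_deposition", "binary"),
    ("appendicolith", "binary"),
    ("appendix_diameter_gt7mm", "binary"),
    ("appendix_wall_thickened", "binary"),
    ("periappendiceal_fluid", "binary"),
)


def format_p(p: float) -> str:
    """Clinical-table style p-value string."""
    if np.isnan(p):
        return "n/a"
    if p <= 0.001:
        return "<=0.001"
    if p >= ALPHA:
        return ">0.05"
    return f"{p:.3f}"


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # "binary" | "continuous"
    summary_na: tuple[float, ...]  # (proportion,) or (mean, sd)
    summary_a: tuple[float, ...]
    test_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)  # NaN (degenerate table) -> False

    @property
    def p_coded(self) -> str:
        return format_p(self.p_value)


def compare_binary_counts(
    pos_na: int, n_na: int, pos_a: int, n_a: int, variable: str = "", correction: bool = False
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table given per-group positive counts."""
    table = np.array([[pos_na, n_na - pos_na], [pos_a, n_a - pos_a]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"{variable or 'table'}: zero margin, chi-square undefined")
    if (table == table[0]).all():
        # identical rows: scipy returns p=1 anyway, but make stat exactly 0
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return GroupComparison(
        variable=variable,
        kind="binary",
        summary_na=(pos_na / n_na,),
        summary_a=(pos_a / n_a,),
        test_statistic=float(chi2),
        p_value=float(p),
    )


def _split(cohort: Cohort, column: str) -> tuple[np.ndarray, np.ndarray]:
    mask_a = cohort.group_a_mask.to_numpy()
    v = cohort.df[column].to_numpy()
    return v[~mask_a], v[mask_a]


def compare_binary(cohort: Cohort, variable: str, correction: bool = False) -> GroupComparison:
    if variable not in BINARY_VARIABLES:
        raise KeyError(f"unknown binary variable {variable!r}")
    na, a = _split(cohort, variable)
    if len(na) == 0 or len(a) == 0:
        raise ValueError("both groups must be non-empty")
    return compare_binary_counts(
        int(na.astype(bool).sum()), len(na), int(a.astype(bool).sum()), len(a),
        variable=variable, correction=correction,
    )


def compare_continuous(cohort: Cohort, variable: str, welch: bool = False) -> GroupComparison:
    if variable not in ("age_years", "duration_hours"):
        raise KeyError(f"unknown continuous variable {variable!r}")
    na, a = (x.astype(float) for x in _split(cohort, variable))
    if len(na) < 2 or len(a) < 2:
        raise ValueError("both groups need at least two values for a t-test")
    t, p = stats.ttest_ind(na, a, equal_var=not welch)
    return GroupComparison(
        variable=variable,
        kind="continuous",
        summary_na=(float(na.mean()), float(na.std(ddof=1))),
        summary_a=(float(a.mean()), float(a.std(ddof=1))),
        test_statistic=float(t),
        p_value=float(p),
    )


def screen_all(
    cohort: Cohort,
    welch: bool = False,
    correction: bool = False,
    on_degenerate: str = "nan",
) -> list[GroupComparison]:
    """The full group-comparison table, in the fixed screen order.

    A variable whose 2x2 table has a zero margin (e.g. a rare finding absent
    from a small cohort) gets a NaN statistic and p-value instead of
    aborting the whole screen; pass ``on_degenerate="raise"`` to make it
    fatal.
    """
    out = []
    for variable, kind in TABLE_VARIABLES:
        if kind == "binary":
            try:
                out.append(compare_binary(cohort, variable, correction=correction))
            except ValueError:
                if on_degenerate == "raise":
                    raise
                na, a = _split(cohort, variable)
                out.append(
                    GroupComparison(
                        variable=variable,
                        kind="binary",
                        summary_na=(float(na.astype(bool).mean()),),
                        summary_a=(float(a.astype(bool).mean()),),
                        test_statistic=float("nan"),
                        p_value=float("nan"),
                    )
                )
        else:
            out.append(compare_continuous(cohort, variable, welch=welch))
    return out


def screen_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular view of a screen (CSV-ready)."""
    rows = []
    for c in comparisons:
        if c.kind == "binary":
            s_na = f"{c.summary_na[0] * 100:.1f}%"
            s_a = f"{c.summary_a[0] * 100:.1f}%"
        else:
            s_na = f"{c.summary_na[0]:.2f}±{c.summary_na[1]:.2f}"
            s_a = f"{c.summary_a[0]:.2f}±{c.summary_a[1]:.2f}"
        rows.append(
            {
                "variable": c.variable,
                "kind": c.kind,
                "group_na": s_na,
                "group_a": s_a,
                "statistic": c.test_statistic,
                "p_value": c.p_value,
                "p_coded": c.p_coded,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)
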