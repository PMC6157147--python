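"""Turning fitted odds ratios into a point-based score.

The defining step of the NSS: each predictor's univariable odds ratio is
binned to a point value —

    OR in (0, 3)   -> 0.5 points
    OR in [3, 6)   -> 1 point
    OR in [6, 9)   -> 2 points
    OR in [9, inf) -> 3 points

The published rule writes the bins as "<3", "3-6", "6-9", ">9", which is
ambiguous at 3, 6 and 9; since no published OR lands exactly on a boundary,
this module adopts lower-closed bins ([3,6), [6,9), [9,inf)) and that
convention reproduces every published point value except one: leukocytosis
(OR 5.809) is printed with 2 points where the rule gives 1.  No boundary
convention rescues that cell, so :func:`build_point_table` reports it as a
structured discrepancy rather than silently picking a side.

Odds ratios <= 1 (protective predictors) were never assigned points in the
published sheet; they map to 0.5 with a warning by default, or can be
excluded with ``protective="exclude"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

from . import published
from .regression import ORRecord
from .scorers import PointTable

__all__ = [
    "assign_points",
    "build_point_table",
    "max_score",
    "rule_point_table",
    "published_point_table",
    "PointDiscrepancy",
    "compare_to_published",
]

_BIN_EDGES = (3.0, 6.0, 9.0)
_BIN_POINTS = (0.5, 1.0, 2.0, 3.0)


def assign_points(odds_ratio: float) -> float:
    """Map a positive odds ratio to its point value in {0.5, 1, 2, 3}."""
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if odds_ratio <= 1.0:
        warnings.warn(
            f"odds ratio {odds_ratio} <= 1 (protective); assigning the minimum 0.5 points",
            stacklevel=2,
        )
    for edge, pts in zip(_BIN_EDGES, _BIN_POINTS):
        if odds_ratio < edge:
            return pts
    return _BIN_POINTS[-1]


@dataclass(frozen=True)
class PointDiscrepancy:
    """One cell where a point table disagrees with the published sheet."""

    predictor: str
    odds_ratio: float
    rule_points: float
    published_points: float

    def __str__(self) -> str:
        return (
            f"{self.predictor}: OR {self.odds_ratio} -> {self.rule_points} points "
            f"by the binning rule, but the published sheet prints {self.published_points}"
        )


def build_point_table(
    or_records: Iterable[ORRecord],
    cutoff: float = published.NSS_CUTOFF,
    protective: Literal["include", "exclude"] = "include",
) -> PointTable:
    """Apply the binning rule to one OR per predictor and assemble the table."""
    points: dict[str, float] = {}
    for rec in or_records:
        if rec.predictor in points:
            raise ValueError(f"duplicate predictor {rec.predictor!r}")
        if rec.odds_ratio <= 1.0 and protective == "exclude":
            continue
        points[rec.predictor] = assign_points(rec.odds_ratio)
    return PointTable(points=points, cutoff=cutoff)


def max_score(table: PointTable) -> float:
    """Highest achievable score: sum of all point values."""
    if not table.points:
        raise ValueError("empty point table has no maximum score")
    return table.max_score


def published_point_table() -> PointTable:
    """The point column exactly as published (leukocytosis = 2; maximum 34)."""
    return PointTable(points=dict(published.PUBLISHED_POINTS))


def rule_point_table() -> tuple[PointTable, list[PointDiscrepancy]]:
    """Binning rule applied to the published ORs, plus the discrepancy report.

    Returns the rule-faithful table (leukocytosis = 1; maximum 33) together
    with the list of cells where it departs from the published sheet.
    """
    records = [
        ORRecord(predictor=name, odds_ratio=vals[0], ci_low=vals[1], ci_high=vals[2], p_value=float("nan"))
        for name, vals in published.PUBLISHED_OR_TABLE.items()
    ]
    table = build_point_table(records)
    return table, compare_to_published(table)


def compare_to_published(table: PointTable) -> list[PointDiscrepancy]:
    """Cells of ``table`` that differ from the published point column."""
    out = []
    for name, pts in table.points.items():
        pub = published.PUBLISHED_POINTS.get(name)
        if pub is not None and pts != pub:
            out.append(
                PointDiscrepancy(
                    predictor=name,
                    odds_ratio=published.PUBLISHED_OR_TABLE[name][0],
                    rule_points=pts,
                    published_points=pub,
                )
            )
    return out
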