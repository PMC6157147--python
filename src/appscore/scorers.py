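"""Per-patient clinical scores: Alvarado (ASS), Pediatric Appendicitis Score
(PAS), and the odds-ratio-derived New Scoring System (NSS).

The NSS is a weighted checklist: each of 21 predictors carries 0.5, 1, 2 or
3 points (maximum 34 with the published table) and a patient is classified
appendicitis-positive at >= 12 points.  ASS and PAS are the two established
10-point scores, classified positive at >= 7 and >= 8 respectively — the
cutoffs the derivation study used for its reclassification comparison.

The study's variables do not name ASS/PAS items one-for-one, so this module
fixes an explicit mapping (module convention, configurable):

* "nausea or vomiting" (ASS and PAS)  := nausea OR bilious_vomiting
* ASS "elevated temperature" / PAS "fever" := pyrexia
* ASS "left shift of neutrophils" := neutrophilia
* PAS "cough/percussion/hopping tenderness" := heel_drop_positive
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import published
from .cohort import NSS_PREDICTORS, Cohort, PatientRecord

__all__ = [
    "PointTable",
    "ScoreResult",
    "nss_score",
    "alvarado_score",
    "pas_score",
    "score_record",
    "score_cohort",
    "ASS_CUTOFF",
    "PAS_CUTOFF",
]

ASS_CUTOFF: int = published.ASS_CUTOFF
PAS_CUTOFF: int = published.PAS_CUTOFF

ALLOWED_POINTS = frozenset({0.5, 1.0, 2.0, 3.0})


@dataclass(frozen=True)
class PointTable:
    """Predictor -> points mapping plus the positivity cutoff.

    ``points`` values come from the 4-level binning of odds ratios
    ({0.5, 1, 2, 3}); every key must be one of the 21 NSS predictors.
    """

    points: dict[str, float]
    cutoff: float = published.NSS_CUTOFF

    def __post_init__(self) -> None:
        unknown = set(self.points) - set(NSS_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors in point table: {sorted(unknown)}")
        bad = {k: v for k, v in self.points.items() if v not in ALLOWED_POINTS}
        if bad:
            raise ValueError(f"point values outside {{0.5,1,2,3}}: {bad}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    @property
    def max_score(self) -> float:
        return float(sum(self.points.values()))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"predictor": list(self.points), "points": list(self.points.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cutoff: float = published.NSS_CUTOFF) -> "PointTable":
        df = pd.read_csv(path)
        return cls(points=dict(zip(df["predictor"], df["points"].astype(float))), cutoff=cutoff)


def default_point_table() -> PointTable:
    """The published score sheet's point column, cutoff 12 (maximum 34).

    Transcribed verbatim, including the leukocytosis = 2 entry that the
    stated OR-binning rule would set to 1; see
    :func:`appscore.construction.rule_point_table` for the rule-faithful
    variant.
    """
    return PointTable(points=dict(published.PUBLISHED_POINTS))


@dataclass(frozen=True)
class ScoreResult:
    patient_id: str
    ass: int
    pas: int
    nss: float
    ass_positive: bool
    pas_positive: bool
    nss_positive: bool


def nss_score(record: PatientRecord, table: PointTable) -> float:
    """Sum of table points over the record's positive predictors."""
    missing = set(NSS_PREDICTORS) - set(table.points)
    if missing:
        raise ValueError(f"point table missing predictors: {sorted(missing)}")
    return float(
        sum(pts for name, pts in table.points.items() if record.predictor(name))
    )


def alvarado_score(record: PatientRecord) -> int:
    """Alvarado (MANTRELS) score, 0-10."""
    r = record.predictor
    return (
        1 * r("migration_of_pain")
        + 1 * r("anorexia")
        + 1 * (r("nausea") or r("bilious_vomiting"))
        + 2 * r("rlq_tenderness")
        + 1 * r("rebound")
        + 1 * r("pyrexia")
        + 2 * r("leukocytosis")
        + 1 * r("neutrophilia")
    )


def pas_score(record: PatientRecord) -> int:
    """Pediatric Appendicitis Score (Samuel), 0-10."""
    r = record.predictor
    return (
        1 * r("anorexia")
        + 1 * (r("nausea") or r("bilious_vomiting"))
        + 1 * r("migration_of_pain")
        + 1 * r("pyrexia")
        + 2 * r("heel_drop_positive")
        + 2 * r("rlq_tenderness")
        + 1 * r("leukocytosis")
        + 1 * r("neutrophilia")
    )


def score_record(record: PatientRecord, table: PointTable | None = None) -> ScoreResult:
    table = table or default_point_table()
    ass = alvarado_score(record)
    pas = pas_score(record)
    nss = nss_score(record, table)
    return ScoreResult(
        patient_id=record.patient_id,
        ass=ass,
        pas=pas,
        nss=nss,
        ass_positive=ass >= ASS_CUTOFF,
        pas_positive=pas >= PAS_CUTOFF,
        nss_positive=nss >= table.cutoff,
    )


def score_cohort(cohort: Cohort, table: PointTable | None = None) -> pd.DataFrame:
    """All three scores and their dichotomous classifications, one row per patient.

    Vectorised over the cohort frame; columns: patient_id, ass, pas, nss,
    ass_positive, pas_positive, nss_positive.
    """
    table = table or default_point_table()
    missing = set(NSS_PREDICTORS) - set(table.points)
    if missing:
        raise ValueError(f"point table missing predictors: {sorted(missing)}")
    df = cohort.df
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})

    def b(col: str) -> pd.Series:
        return df[col].astype(bool).astype(int)

    nausea_or_vomit = (df["nausea"].astype(bool) | df["bilious_vomiting"].astype(bool)).astype(int)
    out["ass"] = (
        b("migration_of_pain") + b("anorexia") + nausea_or_vomit
        + 2 * b("rlq_tenderness") + b("rebound") + b("pyrexia")
        + 2 * b("leukocytosis") + b("neutrophilia")
    )
    out["pas"] = (
        b("anorexia") + nausea_or_vomit + b("migration_of_pain") + b("pyrexia")
        + 2 * b("heel_drop_positive") + 2 * b("rlq_tenderness")
        + b("leukocytosis") + b("neutrophilia")
    )
    nss = sum(pts * b(name) for name, pts in table.points.items())
    out["nss"] = 0.0 if len(df) == 0 else nss.astype(float)
    out["ass_positive"] = out["ass"] >= ASS_CUTOFF
    out["pas_positive"] = out["pas"] >= PAS_CUTOFF
    out["nss_positive"] = out["nss"] >= table.cutoff
    return out
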