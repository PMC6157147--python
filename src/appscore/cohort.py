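"""Patient records and cohorts for a pediatric suspected-appendicitis study.

A cohort is one row per child admitted with suspected acute appendicitis
(AA).  Each record carries demographics, symptom duration, a fixed set of
dichotomized clinical / laboratory / radiological findings, whether the
child was operated, and — for operated children only — the histopathology
result.  The diagnostic ground truth ("Group A" = appendicitis) is *derived*
from the operated flag and histopathology, never stored: children discharged
without surgery and children with a negative appendectomy together form
"Group NA".

All thresholds behind the binary indicators (leukocytosis >10,500/mm^3,
neutrophilia >75%, appendix diameter >7 mm, ...) are applied upstream; the
record stores only the resulting booleans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "NSS_PREDICTORS",
    "EXTRA_VARIABLES",
    "BINARY_VARIABLES",
    "COLUMN_ORDER",
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortParseError",
    "CohortConsistencyError",
    "group_label",
    "read_cohort",
    "write_cohort",
]

#: The 21 predictors of the new scoring system (NSS), in the order the
#: score's point table lists them.  ``male`` is a predictor; the other 20
#: are dichotomized findings.
NSS_PREDICTORS: tuple[str, ...] = (
    "male",
    "continuous_pain",
    "migration_of_pain",
    "anorexia",
    "bilious_vomiting",
    "pyrexia",
    "rlq_tenderness",
    "guarding",
    "rebound",
    "heel_drop_positive",
    "gurgling",
    "leukocytosis",
    "neutrophilia",
    "crp_elevated",
    "scoliosis_right",
    "air_fluid_level",
    "gas_deposition",
    "appendicolith",
    "appendix_diameter_gt7mm",
    "appendix_wall_thickened",
    "periappendiceal_fluid",
)

#: Variables recorded and screened but not retained as NSS predictors.
#: ``nausea`` is still needed for the Alvarado / PAS "nausea or vomiting"
#: item; the other two only enter the univariate screen.
EXTRA_VARIABLES: tuple[str, ...] = ("nausea", "gi_motility_change", "negative_urinalysis")

#: All 24 binary variables of the group-comparison table.
BINARY_VARIABLES: tuple[str, ...] = NSS_PREDICTORS + EXTRA_VARIABLES

#: Fixed CSV column order (deterministic I/O).
COLUMN_ORDER: tuple[str, ...] = (
    ("patient_id", "age_years", "duration_hours")
    + BINARY_VARIABLES
    + ("operated", "histopathology_positive")
)

RADIOLOGICAL_PREDICTORS: tuple[str, ...] = (
    "scoliosis_right",
    "air_fluid_level",
    "gas_deposition",
    "appendicolith",
    "appendix_diameter_gt7mm",
    "appendix_wall_thickened",
    "periappendiceal_fluid",
)

CLINICAL_BIOCHEMICAL_PREDICTORS: tuple[str, ...] = tuple(
    p for p in NSS_PREDICTORS if p not in RADIOLOGICAL_PREDICTORS
)


class CohortSchemaError(ValueError):
    """A required column is missing or mis-typed."""


class CohortParseError(ValueError):
    """A cell could not be parsed (reported with its row number)."""


class CohortConsistencyError(ValueError):
    """A record violates a cross-field invariant (corrupt input)."""


@dataclass(frozen=True)
class PatientRecord:
    """One child with suspected appendicitis.

    ``histopathology_positive`` is present iff ``operated`` — histopathology
    exists only for removed appendices.  ``indicators`` maps the 20 finding
    names plus the three screened-only variables to booleans; ``male`` lives
    in its own field and is exposed through :meth:`predictor`.
    """

    patient_id: str
    age_years: float
    male: bool
    duration_hours: float
    indicators: dict[str, bool]
    operated: bool
    histopathology_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortConsistencyError("patient_id must be non-empty")
        if not (1.0 <= self.age_years <= 18.0):
            raise CohortConsistencyError(
                f"{self.patient_id}: age_years={self.age_years} outside the 1-18 y inclusion range"
            )
        if not (self.duration_hours > 0 and math.isfinite(self.duration_hours)):
            raise CohortConsistencyError(
                f"{self.patient_id}: duration_hours must be positive and finite"
            )
        if self.operated and self.histopathology_positive is None:
            raise CohortConsistencyError(
                f"{self.patient_id}: operated record lacks histopathology result"
            )
        if not self.operated and self.histopathology_positive is not None:
            raise CohortConsistencyError(
                f"{self.patient_id}: histopathology present on a non-operated record"
            )
        expected = set(BINARY_VARIABLES) - {"male"}
        missing = expected - set(self.indicators)
        if missing:
            raise CohortSchemaError(
                f"{self.patient_id}: missing indicators {sorted(missing)}"
            )
        extra = set(self.indicators) - expected
        if extra:
            raise CohortSchemaError(
                f"{self.patient_id}: unknown indicators {sorted(extra)}"
            )

    def predictor(self, name: str) -> bool:
        """Value of a named binary variable; ``male`` resolves to the gender field."""
        if name == "male":
            return self.male
        try:
            return self.indicators[name]
        except KeyError:
            raise KeyError(f"unknown predictor {name!r}") from None


def group_label(record: PatientRecord) -> str:
    """``"A"`` (appendicitis) iff operated with positive histopathology, else ``"NA"``.

    Children discharged without exploration and negative appendectomies both
    label NA — absence of surgery counts as absence of proven appendicitis.
    """
    if record.operated and record.histopathology_positive:
        return "A"
    return "NA"


class Cohort:
    """An ordered collection of validated patient records.

    Backed by a :class:`pandas.DataFrame` in the fixed :data:`COLUMN_ORDER`
    so that vectorised operations (scoring, screening, regression design
    matrices) stay cheap for large simulated cohorts; row-wise
    :class:`PatientRecord` views are materialised on demand.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in COLUMN_ORDER if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"missing columns: {missing}")
        df = df.loc[:, list(COLUMN_ORDER)].reset_index(drop=True)
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise CohortConsistencyError(f"duplicate patient_id {dup!r}")
        self._validate(df)
        self.df = df
        self.provenance = provenance

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            return
        if (df["duration_hours"] <= 0).any():
            row = int(df.index[df["duration_hours"] <= 0][0])
            raise CohortConsistencyError(f"row {row}: non-positive duration_hours")
        if ((df["age_years"] < 1) | (df["age_years"] > 18)).any():
            row = int(df.index[(df["age_years"] < 1) | (df["age_years"] > 18)][0])
            raise CohortConsistencyError(f"row {row}: age outside 1-18 years")
        hist = df["histopathology_positive"]
        op = df["operated"].astype(bool)
        bad = op & hist.isna()
        if bad.any():
            raise CohortConsistencyError(
                f"row {int(df.index[bad][0])}: operated record lacks histopathology"
            )
        bad = ~op & hist.notna()
        if bad.any():
            raise CohortConsistencyError(
                f"row {int(df.index[bad][0])}: histopathology present on non-operated record"
            )

    @classmethod
    def from_records(cls, records: list[PatientRecord], provenance: str = "") -> "Cohort":
        rows = []
        for r in records:
            row: dict[str, object] = {
                "patient_id": r.patient_id,
                "age_years": r.age_years,
                "duration_hours": r.duration_hours,
                "male": r.male,
                "operated": r.operated,
                "histopathology_positive": r.histopathology_positive,
            }
            row.update(r.indicators)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(COLUMN_ORDER))
        if not rows:
            df = cls._empty_frame()
        return cls(df, provenance=provenance)

    @staticmethod
    def _empty_frame() -> pd.DataFrame:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMN_ORDER})
        return df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records())

    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            hist = d["histopathology_positive"]
            out.append(
                PatientRecord(
                    patient_id=str(d["patient_id"]),
                    age_years=float(d["age_years"]),
                    male=bool(d["male"]),
                    duration_hours=float(d["duration_hours"]),
                    indicators={
                        k: bool(d[k]) for k in BINARY_VARIABLES if k != "male"
                    },
                    operated=bool(d["operated"]),
                    histopathology_positive=None if pd.isna(hist) else bool(hist),
                )
            )
        return out

    @property
    def group_a_mask(self) -> pd.Series:
        """Boolean mask: operated with positive histopathology (Group A)."""
        return self.df["operated"].astype(bool) & self.df["histopathology_positive"].eq(True)

    def group_sizes(self) -> dict[str, int]:
        a = int(self.group_a_mask.sum())
        return {"A": a, "NA": len(self) - a}


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize as UTF-8 CSV: booleans as 0/1, absent histopathology empty."""
    df = cohort.df.copy()
    for col in BINARY_VARIABLES + ("operated",):
        df[col] = df[col].astype(bool).astype(int)
    hist = cohort.df["histopathology_positive"]
    df["histopathology_positive"] = [
        "" if pd.isna(v) else str(int(bool(v))) for v in hist
    ]
    df.to_csv(path, index=False)


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip()
    if v == "1":
        return True
    if v == "0":
        return False
    raise CohortParseError(f"row {row}: non-boolean value {value!r} in column {column!r}")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or shaped like one).

    Every row is validated on the way in; a record with a missing predictor,
    an unparseable boolean, or histopathology on a non-operated row is
    rejected with its row number.  The study excluded incomplete medical
    records, so nothing is imputed.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMN_ORDER if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"{path.name}: missing columns {missing}")
    if len(raw) == 0:
        return Cohort(Cohort._empty_frame(), provenance=str(path))

    data: dict[str, list] = {c: [] for c in COLUMN_ORDER}
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        d = dict(zip(raw.columns, row))
        try:
            data["patient_id"].append(d["patient_id"])
            data["age_years"].append(float(d["age_years"]))
            data["duration_hours"].append(float(d["duration_hours"]))
        except ValueError as exc:
            raise CohortParseError(f"row {i}: {exc}") from None
        for col in BINARY_VARIABLES + ("operated",):
            if d[col].strip() == "":
                raise CohortParseError(f"row {i}: missing value in column {col!r}")
            data[col].append(_parse_bool(d[col], col, i))
        hist = d["histopathology_positive"].strip()
        data["histopathology_positive"].append(
            None if hist == "" else _parse_bool(hist, "histopathology_positive", i)
        )
    df = pd.DataFrame(data)
    return Cohort(df, provenance=str(path))
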