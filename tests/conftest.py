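import dataclasses

import pytest

from appscore.cohort import BINARY_VARIABLES, Cohort, PatientRecord
from appscore.simulate import default_config, generate_cohort


def make_record(
    patient_id: str = "P1",
    age_years: float = 10.0,
    male: bool = False,
    duration_hours: float = 24.0,
    operated: bool = False,
    histopathology_positive=None,
    **indicators: bool,
) -> PatientRecord:
    """A patient with every finding negative unless overridden by keyword."""
    base = {k: False for k in BINARY_VARIABLES if k != "male"}
    unknown = set(indicators) - set(base)
    if unknown:
        raise KeyError(f"unknown indicators {unknown}")
    base.update(indicators)
    return PatientRecord(
        patient_id=patient_id,
        age_years=age_years,
        male=male,
        duration_hours=duration_hours,
        indicators=base,
        operated=operated,
        histopathology_positive=histopathology_positive,
    )


def all_positive_record(**kw) -> PatientRecord:
    ind = {k: True for k in BINARY_VARIABLES if k != "male"}
    kw.setdefault("male", True)
    kw.setdefault("operated", True)
    kw.setdefault("histopathology_positive", True)
    return make_record(**{**ind, **kw})


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The study conditions at the study size (355 + 603), seed 0."""
    return generate_cohort(default_config())


@pytest.fixture(scope="session")
def big_cohort() -> Cohort:
    """Default calibration scaled x10 for tests that need tight sampling error."""
    cfg = dataclasses.replace(default_config(), n_appendicitis=3550, n_non_appendicitis=6030, seed=11)
    return generate_cohort(cfg)
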