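"""Published reference values of the NSS derivation study.

Two blocks of constants:

* :data:`PUBLISHED_OR_TABLE` — the per-predictor odds ratios (with 95% Wald
  CIs) the study fitted on its 958-patient cohort, together with the point
  value the published score sheet prints for each predictor.  These ORs are
  the *inputs* to the OR-to-points binning rule; the printed point column is
  the published scoring system itself.
* :data:`GROUP_PREVALENCES` — the group-conditional prevalence of every
  binary variable (non-appendicitis group vs appendicitis group), plus the
  group sizes and symptom-duration moments.  These calibrate the synthetic
  cohort generator.

Note the single internal inconsistency of the published sheet: leukocytosis
has OR 5.809, which the stated binning rule maps to 1 point, yet the sheet
prints 2.  Both variants are exposed (see :mod:`appscore.construction`).
"""

from __future__ import annotations

__all__ = [
    "PUBLISHED_OR_TABLE",
    "PUBLISHED_POINTS",
    "GROUP_PREVALENCES",
    "GROUP_SIZES",
    "DURATION_MOMENTS",
    "AGE_MOMENTS",
    "NEGATIVE_APPENDECTOMY_COUNT",
    "NSS_CUTOFF",
    "ASS_CUTOFF",
    "PAS_CUTOFF",
]

#: predictor -> (odds ratio, ci_low, ci_high, printed points)
PUBLISHED_OR_TABLE: dict[str, tuple[float, float, float, float]] = {
    "male": (1.667, 1.188, 2.339, 0.5),
    "continuous_pain": (15.022, 9.981, 22.611, 3.0),
    "migration_of_pain": (15.637, 10.187, 24.002, 3.0),
    "anorexia": (2.853, 1.964, 4.143, 0.5),
    "bilious_vomiting": (5.285, 3.383, 8.256, 1.0),
    "pyrexia": (4.110, 2.695, 6.267, 1.0),
    "rlq_tenderness": (4.090, 2.121, 7.882, 1.0),
    "guarding": (8.806, 5.585, 13.886, 2.0),
    "rebound": (7.863, 5.416, 11.417, 2.0),
    "heel_drop_positive": (30.195, 18.230, 50.011, 3.0),
    "gurgling": (6.892, 3.977, 11.944, 2.0),
    "leukocytosis": (5.809, 3.705, 9.107, 2.0),
    "neutrophilia": (6.216, 4.142, 9.3308, 2.0),
    "crp_elevated": (3.816, 2.692, 5.409, 1.0),
    "scoliosis_right": (4.432, 3.077, 6.384, 1.0),
    "air_fluid_level": (4.769, 3.327, 6.836, 1.0),
    "gas_deposition": (5.694, 3.894, 8.326, 1.0),
    "appendicolith": (12.031, 2.689, 53.825, 3.0),
    "appendix_diameter_gt7mm": (5.705, 3.768, 8.638, 1.0),
    "appendix_wall_thickened": (7.214, 4.810, 10.821, 2.0),
    "periappendiceal_fluid": (4.792, 3.316, 6.924, 1.0),
}

#: predictor -> published point value (the score sheet's NSS column).
PUBLISHED_POINTS: dict[str, float] = {
    k: v[3] for k, v in PUBLISHED_OR_TABLE.items()
}

#: variable -> (prevalence in Group NA, prevalence in Group A).
#: Nausea really is *lower* in the appendicitis group as published (10.1%
#: vs 5.9%); it is transcribed as printed.
GROUP_PREVALENCES: dict[str, tuple[float, float]] = {
    "male": (0.542, 0.603),
    "continuous_pain": (0.202, 0.792),
    "migration_of_pain": (0.106, 0.647),
    "nausea": (0.101, 0.059),
    "anorexia": (0.545, 0.773),
    "bilious_vomiting": (0.121, 0.466),
    "pyrexia": (0.111, 0.339),
    "rlq_tenderness": (0.951, 1.0),
    "guarding": (0.460, 0.882),
    "rebound": (0.230, 0.701),
    "heel_drop_positive": (0.059, 0.656),
    "gi_motility_change": (0.072, 0.104),
    "gurgling": (0.049, 0.262),
    "leukocytosis": (0.553, 0.878),
    "neutrophilia": (0.444, 0.833),
    "crp_elevated": (0.333, 0.656),
    "negative_urinalysis": (0.796, 0.859),
    "scoliosis_right": (0.194, 0.516),
    "air_fluid_level": (0.214, 0.566),
    "gas_deposition": (0.158, 0.516),
    "appendicolith": (0.005, 0.059),
    "appendix_diameter_gt7mm": (0.111, 0.416),
    "appendix_wall_thickened": (0.119, 0.493),
    "periappendiceal_fluid": (0.186, 0.525),
}

#: (Group NA, Group A) sizes of the derivation cohort.
GROUP_SIZES: tuple[int, int] = (603, 355)

#: variable-duration moments in hours: group -> (mean, sd).
DURATION_MOMENTS: dict[str, tuple[float, float]] = {
    "NA": (30.51, 30.60),
    "A": (39.84, 35.63),
}

#: age moments in years: group -> (mean, sd); support truncated to 1-18.
AGE_MOMENTS: dict[str, tuple[float, float]] = {
    "NA": (10.6, 4.6),
    "A": (10.9, 4.1),
}

#: negative appendectomies among the 603 non-appendicitis children.
NEGATIVE_APPENDECTOMY_COUNT: int = 45

NSS_CUTOFF: float = 12.0
ASS_CUTOFF: int = 7
PAS_CUTOFF: int = 8
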