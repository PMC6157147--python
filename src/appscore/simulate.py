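"""Seeded synthetic cohorts with the statistical structure of the study data.

The derivation dataset is not publicly deposited, so every downstream stage
is exercised on synthetic cohorts calibrated to the published
group-conditional summaries: group sizes 603 (non-appendicitis) / 355
(appendicitis), the per-variable prevalences of the group-comparison table,
and the symptom-duration moments (30.51±30.60 h vs 39.84±35.63 h).

Dependence model
----------------
Only marginal prevalences are published, so within-group dependence between
findings is induced by a single latent "severity" per patient: finding *f*
is positive iff

    Z_f = rho * L + sqrt(1 - rho^2) * eps_f  >  Phi^{-1}(1 - p_f)

with L, eps_f independent standard normals and rho = ``correlation_strength``.
Marginals match ``p_f`` exactly for any rho, any pair of findings has
tetrachoric correlation rho^2 >= 0 (clinically, findings co-occur), and
rho = 0 recovers full independence.  Gender is drawn independently of the
latent severity.

Durations are log-normal, moment-matched to the configured (mean, sd) and
floored at 1 hour; ages are normal truncated to the 1-18 y inclusion range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import published
from .cohort import BINARY_VARIABLES, COLUMN_ORDER, Cohort

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate_cohort",
    "empirical_prevalences",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Everything :func:`generate_cohort` needs, fully explicit and serializable.

    ``prevalence`` maps each of the 24 binary variables to
    ``(p_NA, p_A)`` — its prevalence in the non-appendicitis and
    appendicitis groups.  ``correlation_strength`` is the latent-severity
    loading rho in [0, 1); 0 means all findings independent within group.
    """

    n_appendicitis: int = published.GROUP_SIZES[1]
    n_non_appendicitis: int = published.GROUP_SIZES[0]
    prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.GROUP_PREVALENCES)
    )
    duration: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.DURATION_MOMENTS)
    )
    age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.AGE_MOMENTS)
    )
    negative_appendectomy_fraction: float = (
        published.NEGATIVE_APPENDECTOMY_COUNT / published.GROUP_SIZES[0]
    )
    correlation_strength: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_appendicitis <= 0 or self.n_non_appendicitis <= 0:
            raise ConfigError("group sizes must be positive")
        missing = set(BINARY_VARIABLES) - set(self.prevalence)
        if missing:
            raise ConfigError(f"prevalence missing for {sorted(missing)}")
        for name, (p_na, p_a) in self.prevalence.items():
            for p in (p_na, p_a):
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"{name}: prevalence {p} outside [0,1]")
        for grp in ("NA", "A"):
            mean, sd = self.duration[grp]
            if mean <= 0 or sd <= 0:
                raise ConfigError(f"duration moments for {grp} must be positive")
        if not (0.0 <= self.negative_appendectomy_fraction <= 1.0):
            raise ConfigError("negative_appendectomy_fraction outside [0,1]")
        if not (0.0 <= self.correlation_strength < 1.0):
            raise ConfigError("correlation_strength outside [0,1)")

    # -- flat text (YAML) round trip ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["prevalence"] = {k: list(v) for k, v in d["prevalence"].items()}
        d["duration"] = {k: list(v) for k, v in d["duration"].items()}
        d["age"] = {k: list(v) for k, v in d["age"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("prevalence", "duration", "age"):
            d[key] = {k: tuple(v) for k, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_config() -> GeneratorConfig:
    """The study conditions: published group sizes, prevalences and moments."""
    return GeneratorConfig()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _simulate_group(
    cfg: GeneratorConfig, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    gi = 0 if group == "NA" else 1
    rho = cfg.correlation_strength

    latent = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for name in BINARY_VARIABLES:
        p = cfg.prevalence[name][gi]
        if name == "male":
            # gender is not severity-driven
            cols[name] = rng.random(n) < p
            continue
        z = rho * latent + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        cols[name] = z > stats.norm.ppf(1.0 - p)

    mu, sigma = _lognormal_params(*cfg.duration[group])
    duration = np.maximum(rng.lognormal(mu, sigma, size=n), 1.0)

    a_mean, a_sd = cfg.age[group]
    lo, hi = (1.0 - a_mean) / a_sd, (18.0 - a_mean) / a_sd
    age = stats.truncnorm.rvs(lo, hi, loc=a_mean, scale=a_sd, size=n, random_state=rng)

    if group == "A":
        operated = np.ones(n, dtype=bool)
        hist: list[object] = [True] * n
    else:
        operated = rng.random(n) < cfg.negative_appendectomy_fraction
        hist = [False if op else None for op in operated]

    df = pd.DataFrame(
        {"age_years": age, "duration_hours": duration, **cols, "operated": operated}
    )
    df["histopathology_positive"] = hist
    return df


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the configured group-conditional model.

    Exactly ``n_appendicitis`` records are operated with positive
    histopathology; of the ``n_non_appendicitis`` others, a binomial share
    ``negative_appendectomy_fraction`` are operated with negative
    histopathology and the rest discharged unoperated.  Record order is a
    seeded shuffle of the two groups.  Identical config + seed reproduce
    the cohort bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    df_a = _simulate_group(config, "A", config.n_appendicitis, rng)
    df_na = _simulate_group(config, "NA", config.n_non_appendicitis, rng)
    df = pd.concat([df_a, df_na], ignore_index=True)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    width = len(str(len(df)))
    df.insert(0, "patient_id", [f"P{i+1:0{width}d}" for i in range(len(df))])
    df = df.loc[:, list(COLUMN_ORDER)]
    provenance = (
        f"synthetic: seed={config.seed} nA={config.n_appendicitis} "
        f"nNA={config.n_non_appendicitis} rho={config.correlation_strength}"
    )
    return Cohort(df, provenance=provenance)


def empirical_prevalences(cohort: Cohort) -> dict[str, tuple[float, float]]:
    """Per-group sample proportions of every binary variable.

    Returns ``{variable: (p_hat_NA, p_hat_A)}`` with the same key set as the
    generator's prevalence map.  Raises if either group is empty (the
    proportions would be undefined).
    """
    mask_a = cohort.group_a_mask.to_numpy()
    n_a = int(mask_a.sum())
    n_na = len(cohort) - n_a
    if n_a == 0 or n_na == 0:
        raise ValueError("both groups must be non-empty to estimate prevalences")
    out: dict[str, tuple[float, float]] = {}
    for name in BINARY_VARIABLES:
        v = cohort.df[name].astype(bool).to_numpy()
        out[name] = (float(v[~mask_a].mean()), float(v[mask_a].mean()))
    return out
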