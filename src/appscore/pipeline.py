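"""One-command end-to-end run.

simulate (or load) a cohort -> univariate screen -> per-predictor odds
ratios -> stepwise subgroup analyses -> build the NSS point tables -> score
every patient -> reclassification comparison and duration strata.  Every
stage writes a CSV artifact; a JSON metrics bundle and a manifest (config,
seed, SHA-256 checksum per artifact) make a run reproducible and
byte-comparable.  Both NSS point tables — the published sheet and the
rule-derived one — are always computed and reported side by side, so the
published sheet's single off-rule cell stays visible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import construction, published
from .cohort import Cohort, read_cohort, write_cohort
from .evaluation import (
    cohort_summary,
    compare_systems,
    duration_table,
    pct,
)
from .regression import subgroup_analyses, univariable_or_table
from .scorers import score_cohort
from .screen import screen_all, screen_to_frame
from .simulate import GeneratorConfig, default_config, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Exactly one of ``generator`` (simulate mode) or ``input_path`` (load mode)."""

    generator: Optional[GeneratorConfig] = None
    input_path: Optional[str] = None
    out_dir: str = "results"
    entry_p: float = 0.05
    removal_p: float = 0.10
    classification_threshold: float = 0.5
    seed: Optional[int] = None  # overrides generator.seed when given

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ValueError("set exactly one of generator (simulate) or input_path (load)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _or_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "predictor": [r.predictor for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "p_value": [r.p_value for r in records],
            "flagged": [r.flagged for r in records],
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the metrics bundle as a dict.

    Artifacts written to ``config.out_dir``: cohort.csv, table1.csv
    (univariate screen), table2.csv (ORs + both point columns), table3.csv
    (stepwise subgroups), table4.csv (system comparison), table5.csv
    (duration strata), metrics.json, manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    log: list[str] = []

    # -- stage 1: cohort -------------------------------------------------
    if config.generator is not None:
        gen = dataclasses.replace(config.generator)
        if config.seed is not None:
            gen.seed = config.seed
        cohort = generate_cohort(gen)
        mode = "simulate"
    else:
        cohort = read_cohort(config.input_path)
        gen = None
        mode = "load"
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path)
    artifacts.append(cohort_path)
    sizes = cohort.group_sizes()
    summary = cohort_summary(cohort)
    log.append(f"cohort: n={len(cohort)} A={sizes['A']} NA={sizes['NA']} ({mode})")

    # -- stage 2: univariate screen -------------------------------------
    screen = screen_all(cohort)
    t1 = screen_to_frame(screen)
    t1.to_csv(out / "table1.csv", index=False)
    artifacts.append(out / "table1.csv")
    log.append(f"screen: {int(t1.significant.sum())}/{len(t1)} variables significant")

    # -- stage 3: per-predictor odds ratios + point tables ---------------
    or_records = univariable_or_table(cohort, skip_degenerate=True)
    fitted_table = construction.build_point_table(or_records)
    published_table = construction.published_point_table()
    rule_table, rule_discrepancies = construction.rule_point_table()
    t2 = _or_frame(or_records)
    t2["points_fitted"] = [fitted_table.points[p] for p in t2["predictor"]]
    t2["points_published"] = [published.PUBLISHED_POINTS[p] for p in t2["predictor"]]
    t2["points_rule_on_published_or"] = [rule_table.points[p] for p in t2["predictor"]]
    t2.to_csv(out / "table2.csv", index=False)
    artifacts.append(out / "table2.csv")
    for d in rule_discrepancies:
        log.append(f"point-table discrepancy: {d}")

    # -- stage 4: stepwise subgroup analyses -----------------------------
    steps = subgroup_analyses(
        cohort, config.entry_p, config.removal_p, config.classification_threshold
    )
    t3 = pd.DataFrame(
        [
            {
                "candidate_set": s.candidate_set,
                "n_candidates": len(s.candidates),
                "retained": ";".join(s.retained),
                "n_retained": len(s.retained),
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "auc": s.auc,
                "auc_ci_low": s.auc_ci[0],
                "auc_ci_high": s.auc_ci[1],
            }
            for s in steps.values()
        ]
    )
    t3.to_csv(out / "table3.csv", index=False)
    artifacts.append(out / "table3.csv")
    log.append(
        "stepwise: "
        + ", ".join(f"{k}={len(v.retained)} retained" for k, v in steps.items())
    )

    # -- stage 5: scoring + system comparison (both NSS variants) --------
    bundles = {}
    t4_rows = []
    for label, table in (("published", published_table), ("rule_derived", rule_table)):
        scores = score_cohort(cohort, table)
        if label == "published":
            scores.to_csv(out / "scores.csv", index=False)
            artifacts.append(out / "scores.csv")
        reports = compare_systems(cohort, scores, table)
        bundles[label] = reports
        for system, rep in reports.items():
            m = rep.metrics
            t4_rows.append(
                {
                    "nss_variant": label,
                    "system": system,
                    "cutoff": rep.cutoff,
                    "tp": rep.cm.tp,
                    "fp": rep.cm.fp,
                    "fn": rep.cm.fn,
                    "tn": rep.cm.tn,
                    "sensitivity_pct": pct(m.sensitivity),
                    "specificity_pct": pct(m.specificity),
                    "ppv_pct": pct(m.ppv),
                    "npv_pct": pct(m.npv),
                    "kappa": m.kappa,
                    "auc": m.auc,
                    "auc_ci_low": m.auc_ci[0],
                    "auc_ci_high": m.auc_ci[1],
                }
            )
        if label == "published":
            # duration strata for the headline (published) NSS classification
            t5 = duration_table(
                cohort.df["duration_hours"].to_numpy(),
                scores["nss_positive"].to_numpy(),
                cohort.group_a_mask.to_numpy(),
            )
            t5.to_csv(out / "table5.csv", index=False)
            artifacts.append(out / "table5.csv")
    t4 = pd.DataFrame(t4_rows)
    t4.to_csv(out / "table4.csv", index=False)
    artifacts.append(out / "table4.csv")
    log.append(
        "compare: kappa "
        + ", ".join(
            f"{s}={bundles['published'][s].metrics.kappa:.3f}" for s in ("ass", "pas", "nss")
        )
    )

    # -- metrics bundle + manifest ---------------------------------------
    metrics_bundle = {
        "cohort": {
            "n_total": summary.n_total,
            "n_operated": summary.n_operated,
            "n_histopathology_positive": summary.n_histopathology_positive,
            "negative_appendectomy_rate_pct": summary.negative_appendectomy_rate_pct,
            "group_sizes": sizes,
        },
        "stepwise": {
            k: {
                "retained": v.retained,
                "sensitivity": v.sensitivity,
                "specificity": v.specificity,
                "auc": v.auc,
            }
            for k, v in steps.items()
        },
        "systems": {
            label: {
                s: {
                    "tp": r.cm.tp,
                    "fp": r.cm.fp,
                    "fn": r.cm.fn,
                    "tn": r.cm.tn,
                    "sensitivity_pct": pct(r.metrics.sensitivity),
                    "specificity_pct": pct(r.metrics.specificity),
                    "ppv_pct": pct(r.metrics.ppv),
                    "npv_pct": pct(r.metrics.npv),
                    "kappa": r.metrics.kappa,
                    "auc": r.metrics.auc,
                }
                for s, r in reports_.items()
            }
            for label, reports_ in bundles.items()
        },
        "point_table_discrepancies": [str(d) for d in rule_discrepancies],
        "log": log,
    }
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics_bundle, indent=2, sort_keys=True))
    artifacts.append(metrics_path)

    manifest = {
        "mode": mode,
        "seed": gen.seed if gen is not None else None,
        "generator": (
            None
            if gen is None
            else {
                **{k: v for k, v in dataclasses.asdict(gen).items() if k != "prevalence"},
                "prevalence": {k: list(v) for k, v in gen.prevalence.items()},
            }
        ),
        "input_path": config.input_path,
        "entry_p": config.entry_p,
        "removal_p": config.removal_p,
        "classification_threshold": config.classification_threshold,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return metrics_bundle
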