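#!/usr/bin/env python
"""Score every patient and compare the three systems by reclassification.

Applies Alvarado (cutoff 7), PAS (cutoff 8) and the odds-ratio-derived NSS
(cutoff 12, published point table) to each child, relabels everyone
strictly by cutoff, and tabulates confusion matrices, sensitivity /
specificity / PPV / NPV, Cohen's kappa, and ROC AUC per system, plus the
NSS error profile by symptom-duration stratum.  Writes results/table4.csv,
results/table5.csv and results/scores.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from appscore.cohort import read_cohort
from appscore.evaluation import compare_systems, duration_table, pct
from appscore.scorers import score_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort(args.cohort)
scores = score_cohort(cohort)
args.outdir.mkdir(parents=True, exist_ok=True)
scores.to_csv(args.outdir / "scores.csv", index=False)

reports = compare_systems(cohort, scores)
rows = []
print(f"reclassification of {len(cohort)} patients:")
for system, rep in reports.items():
    m = rep.metrics
    rows.append(
        {
            "system": system.upper(), "cutoff": rep.cutoff,
            "tp": rep.cm.tp, "fp": rep.cm.fp, "fn": rep.cm.fn, "tn": rep.cm.tn,
            "sensitivity_pct": pct(m.sensitivity), "specificity_pct": pct(m.specificity),
            "ppv_pct": pct(m.ppv), "npv_pct": pct(m.npv),
            "kappa": round(m.kappa, 3), "auc": round(m.auc, 3),
        }
    )
    print(f"  {system.upper():>3} (cutoff {rep.cutoff:>4}): "
          f"sens {pct(m.sensitivity):5.1f}%  spec {pct(m.specificity):5.1f}%  "
          f"PPV {pct(m.ppv):5.1f}%  NPV {pct(m.npv):5.1f}%  "
          f"kappa {m.kappa:.3f}  AUC {m.auc:.3f}")
pd.DataFrame(rows).to_csv(args.outdir / "table4.csv", index=False)

t5 = duration_table(
    cohort.df["duration_hours"].to_numpy(),
    scores["nss_positive"].to_numpy(),
    cohort.group_a_mask.to_numpy(),
)
t5.to_csv(args.outdir / "table5.csv", index=False)
print("NSS error profile by symptom duration (share of stratum):")
for _, row in t5.iterrows():
    print(f"  {row.duration:>8} (n={row.n:>4}): "
          f"TN {row.tn_share:5.1%}  FP {row.fp_share:5.1%}  "
          f"FN {row.fn_share:5.1%}  TP {row.tp_share:5.1%}")
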