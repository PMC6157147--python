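# Methods

## Outcome and groups

The diagnostic truth is histopathology: a patient belongs to the
appendicitis group (A) iff they were operated *and* the specimen showed
acute appendicitis. Children discharged without surgery and negative
appendectomies both count as non-appendicitis (NA). This is the only
labeling the derivation data support — unoperated children have no
histopathology, so "no surgery" is treated as "no appendicitis" and the
package never imputes an outcome. Consequence: any miss among unoperated
children is invisible, and all performance figures are in-sample
reclassification figures, not prospective accuracy.

## Score construction

Each of the 21 predictors gets its univariable odds ratio (OR) of group-A
membership. For a binary predictor the logistic MLE equals the 2×2
cross-product ratio, so the estimate is computed in closed form with a
Wald 95% CI on log OR; a statsmodels logistic fit serves as an independent
oracle in the tests. When any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe) and the record is flagged rather than silently patched.

Points are assigned by binning the OR: 0.5 on (0, 3), 1 on [3, 6), 2 on
[6, 9), 3 on [9, ∞). The published rule writes the bins as "<3", "3-6",
"6-9", ">9", which is ambiguous at the boundaries; no published OR lands
exactly on 3, 6 or 9, and the lower-closed convention adopted here
reproduces the published point column for 20 of 21 predictors. The single
exception — leukocytosis, OR 5.809, printed with 2 points where every
convention gives 1 — cannot be a boundary artifact. Both tables therefore
ship: the published sheet verbatim (`published_point_table`, maximum 34)
as the default scoring table, and the rule-faithful variant
(`rule_point_table`, maximum 33) together with a structured discrepancy
report. ORs ≤ 1 were never assigned points in the published sheet; the
builder maps them to 0.5 with a warning by default and can exclude them.

The NSS cutoff is 12 by default and is an ordinary parameter.

## Established scores

ASS (Alvarado) and PAS use their published item weights and the cutoffs 7
and 8. The recorded variables do not name the items one-for-one, so the
package fixes an explicit mapping: "nausea or vomiting" := nausea OR
bilious vomiting; ASS "elevated temperature" and PAS "fever" := pyrexia;
ASS "left shift" := neutrophilia; PAS "cough/percussion/hopping
tenderness" := positive heel drop test. These are this package's
conventions — the derivation study does not state how it scored the
established systems — and each is a one-line change in `scorers.py`.

## Synthetic cohorts

The derivation data are not deposited, so all cohort-level computations
run on synthetic cohorts drawn from the published group-conditional
summaries: 355 A / 603 NA, the per-variable prevalences of the group
comparison table (transcribed as printed, including nausea's lower
prevalence in the appendicitis group), symptom-duration moments
30.51±30.60 h (NA) and 39.84±35.63 h (A), age moments 10.6±4.6 / 10.9±4.1
years, and 45/603 negative appendectomies.

Within a group, finding $f$ is positive iff
$\rho L + \sqrt{1-\rho^2}\,\varepsilon_f > \Phi^{-1}(1-p_f)$, with one
latent standard-normal severity $L$ per patient and independent
$\varepsilon_f$. Marginals match $p_f$ exactly for any
$\rho$ = `correlation_strength`; any two findings have tetrachoric
correlation $\rho^2 \ge 0$, matching the clinical expectation that
findings co-occur; $\rho = 0$ gives full independence. The default is
$\rho = 0.3$, a mid-range choice — the published tables contain no
information about the real correlation structure, so the value is exposed
in the config rather than estimated. Gender is drawn independently of
severity; negative appendectomies are assigned independently of findings
(the study publishes no predictor profile for them); durations are
log-normal, moment-matched ( $\sigma^2=\ln(1+cv^2)$ ) and floored at 1 h;
ages are normal truncated to the 1–18 y inclusion range.

What the generator does **not** emulate, and what that implies: the real
joint distribution of findings. Margins plus equicorrelation pin down
single-predictor quantities — univariable ORs, the univariate screen, the
binning — so tests of those stages transfer to real data. Multi-item
*threshold* behavior does not transfer: how often a non-appendicitis child
accumulates ASS ≥ 7 or PAS ≥ 8 depends on higher-order co-occurrence. At
$\rho = 0.3$ the simulated ASS false-positive rate is roughly half the
published one, so ASS agrees with truth better in simulation (κ ≈ 0.64)
than in the real cohort (0.441), and the published κ ordering
NSS > PAS > ASS appears in simulation as NSS > ASS > PAS; the published
ordering emerges only under much stronger dependence (around
$\rho \approx 0.7$). The NSS-dominates-both property, the substantive
claim, holds at every $\rho$ examined. The acceptance test asserts the
full published ordering at the default calibration and is expected to
fail on its PAS-vs-ASS leg; it is kept failing rather than re-tuned,
precisely because it documents this limit of margin-only calibration.

## Statistical machinery

* **Univariate screen** — Pearson chi-square without continuity
  correction for the 24 binary variables (Yates behind a flag), pooled
  two-sample t-test for age and duration (Welch behind a flag). Raw
  p-values, no multiplicity adjustment (documented; 26 tests). A variable
  whose 2×2 table has a zero margin in a small cohort yields a NaN row
  rather than aborting the screen. The rarest finding (appendicolith,
  0.5% of the NA group) sits near the chi-square validity boundary at the
  study size; this is reported, not "fixed".
* **Forward stepwise** — entry by Rao score test (the candidate with the
  smallest p enters if p < `entry_p`, ties broken by candidate order),
  removal by Wald test (worst included term leaves if p > `removal_p`),
  defaults 0.05 / 0.10, iterated to a fixed point. The procedure is
  deterministic given cohort and candidate order; a visited-set guard
  stops the rare enter/remove oscillation on tiny cohorts. Symptom
  duration > 24 h is an eligible candidate in the clinical+biochemical
  and combined sets (it is part of clinical history; radiological-only
  excludes it).
* **Classification metrics** — predicted probabilities dichotomized at
  0.5 (the derivation study does not state its threshold; 0.5 is the
  conventional default and a parameter here). AUC by the rank
  (Mann–Whitney) construction via scikit-learn, verified in tests against
  exhaustive ordered-pair counting; 95% CI by the Hanley–McNeil normal
  approximation (the study does not state its CI method).
* **Cohen's κ** — computed in exact rational arithmetic
  (`fractions.Fraction`) and converted to float once, so κ = 1 and κ = 0
  boundary cases are exact.
* **Percentages** — reported at one decimal with round-half-away-from-zero
  (so 45/400 → 11.3%), matching clinical-table convention; raw fractions
  are always kept alongside. The published tables contain small internal
  inconsistencies against their own counts (e.g. PAS PPV prints 80.8
  where 192/238 gives 80.7; the NSS row's κ and sensitivity differ
  between text, abstract and counts); this implementation is
  count-faithful throughout.

## Simulation experiment sizes

The test suite's stochastic experiments use sizes chosen to make the
checked properties sharp while keeping the default run quick: marginal
calibration and duration moments at n = 10⁵ within 3 standard errors;
Wald-CI coverage over 200 replicates of n = 20 000 (band 95% ± 3%);
stepwise support recovery over 200 replicates of n = 20 000 with three
true OR-5 signals among three nulls. The recovery experiment uses
entry 0.01 / removal 0.05 — stricter than the modeling defaults — because
exact support recovery is the target and, at n = 20 000, power against
OR 5 is effectively 1, so the stricter entry costs nothing while holding
the null-inclusion rate near 3%. Type-I behavior of the default 0.05
entry is tested separately.

## Known limitations

* All performance metrics are in-sample; the derivation study's
  reclassification design is optimistic by construction and the package
  does not add cross-validation (out of scope by design).
* The generator cannot validate multi-item threshold behavior of ASS/PAS
  against the real cohort (see above).
* Verification bias is inherited from the outcome definition: unoperated
  children are assumed disease-free.
* No Firth/penalized regression; separation is detected and flagged, not
  resolved.
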