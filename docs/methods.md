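# Methods

This note documents the models and procedures `arthrasight` implements,
the defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical conventions that make results
reproducible.

## Cohort model and first-visit classification

A patient record holds 13 ternary joint-symptom items in a fixed order
(1 symptom onset < 1 year; 2 four to ten joints with symptoms; 3 MCP
symptoms; 4 MTP symptoms; 5 symptoms in several small joint regions;
6 symmetric symptoms; 7 morning stiffness ≥ 60 min; 8 worst symptoms in
early morning; 9 daytime improvement; 10 increasing number of joints over
time; 11 experienced swelling of small hand joints; 12 first-degree
relative with RA; 13 local tenderness on examination), raw serology, a
joint-exam summary, and months to RA or censoring within a 48-month
horizon.

Serology cut-offs: RF positive at ≥ 20 U/ml, ACPA positive strictly above
20 AU/ml (the cut-off corresponds to mean + 2 SD of healthy controls and
values *above* it are regarded positive), CRP elevated at ≥ 5 mg/L,
survivin positive at ≥ 450 pg/ml (mean + 3 SD of healthy controls; assay
detection limit 100 pg/ml, below-detection values stored as 0). The
inclusive-vs-strict convention per marker is fixed and tested so that
dichotomisation is exactly reproducible; `any_ab` is RF and/or ACPA, and
`female_over_50` requires age strictly above 50.

The EULAR/ACR 2010 classification score is the standard additive rubric:
joints (1 large 0; 2–10 large 1; 1–3 small 2; 4–10 small 3; > 10 joints
including ≥ 1 small 5), serology (negative 0; low-positive 2;
high-positive, > 3× cut-off, 3), acute phase (abnormal CRP 1) and duration
(≥ 6 weeks 1). ESR is not part of the data model, so the acute-phase point
uses CRP alone. Swelling with score ≥ 6 classifies RA at first visit,
swelling with score < 6 UA, no swelling arthralgia; arthralgia patients
with an RA event within the horizon are pre-RA. Records with a missing
outcome are censored at 48 months.

## Synthetic cohort generator

The generator realises the statistical structure the analysis assumes; it
is the test-bed for every downstream stage.

* **Strata and sizes.** Four first-visit strata at sizes (148 remaining
  arthralgia, 32 pre-RA, 73 UA, 63 RA) — a first-visit case mix of 180
  arthralgia patients with a 17.8% progression rate, 73 UA and 63 RA.
* **Marker prevalences.** Pooled arthralgia prevalences are calibrated to
  the observed cohort counts (survivin 61/180, any antibody 53/180,
  elevated CRP 54/180; UA survivin 20/73, any antibody 10/73; RA survivin
  31/63, any antibody 50/63, CRP 28/55 — CRP was unassessed in 8 RA
  records, treated as missing at random, and unassessed in UA, where the
  arthralgia rate stands in). The observed arthralgia counts for RF (39),
  ACPA (12) and their union (53) are mutually inconsistent (39 + 12 < 53),
  so the generator keeps the union and the ACPA count — both used by the
  analysis — and raises RF to 41, disjoint from ACPA.
* **Pre-RA enrichment.** Only pooled arthralgia marker prevalences are
  observable, but serology can only add predictive value if progressors
  carry the markers more often. The package's calibration splits each
  pooled prevalence into pre-RA vs remaining-arthralgia values with an
  odds ratio of 3.0, keeping the pooled marginal exact. The female > 50 y
  parameter gets a mild association instead, via a +4-year age shift in
  pre-RA. These are acknowledged free parameters, chosen once: they
  reproduce the qualitative pattern (every marker-enriched model beats the
  clinical base model; the ≥ 4-parameter group progresses far more often),
  not any particular printed AUC.
* **Symptom prevalences.** Per-item prevalences are free parameters
  constrained to the qualitative facts: a symptom-burden gradient
  arthralgia < pre-RA < RA, and pre-RA vs remaining-arthralgia odds ratio
  3.0 for the three discriminating items (5, 10, 11) — comfortably above
  the screening threshold of 2 — and 1.3 for the other ten, comfortably
  below. Remaining-arthralgia baselines span 0.15–0.45; UA and RA apply
  whole-stratum odds multipliers 2 and 4.
* **Marker–symptom association.** Within each stratum, a symptom is
  Bernoulli with odds = baseline × Π (odds multipliers of the patient's
  positive markers). Default multipliers: survivin 2.5 on items 1, 2, 5,
  6, 8, 10, 13; CRP 2.5 on item 1; any antibody 2.5 on item 6. The
  baseline odds are solved numerically (Brent's method on the log-odds)
  so the stratum marginal equals the configured prevalence exactly in
  expectation; consequently the *conditional* within-stratum OR equals the
  configured multiplier, and the marker marginals are untouched. An
  infeasible marginal/association combination raises a config error naming
  the item.
* **Missingness.** Symptom cells are masked at 1.98% — MCAR by default; a
  MAR sensitivity mode doubles the masking odds of symptom-negative cells
  at the same overall rate.
* **Outcome.** Pre-RA months-to-RA follow a discrete monthly hazard
  h = h₀ · exp(β · n), with h₀ = 0.01/month, β = ln 1.4 per positive
  parameter of the 6-parameter algorithm, truncated to the 48-month
  horizon by inverse-CDF conditioning (all pre-RA patients event
  in-window, matching their definition). Monthly resolution reflects
  clinic-visit granularity; ties are expected and handled.
* **Exam fields** are drawn consistent with the intended class and
  fixed up deterministically against the 2010 score (RA records are
  guaranteed ≥ 6 by escalating to > 10 joints and ≥ 6 weeks duration; UA
  records are capped below 6 by reduction to one large joint), so
  first-visit classification recovers the generation strata exactly.

What the generator does **not** emulate: item–item dependence beyond what
shared markers induce, longitudinal symptom trajectories, UA-to-RA
conversion (times unidentifiable in routine care), informative censoring,
or any biology of the serological markers. Passing tests therefore
demonstrate that the pipeline recovers known structure from data of this
shape and size — not that the structure is true of any real cohort.

## Multiple imputation

Default: chained equations, m = 5 completions, 10 sweeps. Each sweep
refits, per item with missing cells, a logistic regression of that item on
the other twelve and redraws the missing cells Bernoulli from a
coefficient vector sampled from the approximate posterior
N(β̂, I⁻¹(β̂)). The fit is an in-package iteratively-reweighted
least-squares with a small L2 penalty (λ = 0.1, intercept unpenalised):
binary items at n ≈ 180 readily produce separation, the penalty keeps
estimates finite, and the penalised information matrix supplies the
posterior covariance directly. `marginal_bernoulli` (draw from the item's
observed prevalence) is provided as a transparent fallback; at ~2%
missingness the two are indistinguishable downstream, which the test suite
demonstrates (pooled odds ratios deviate from complete-data odds ratios by
≈ 0.1 SE on average). Items entirely missing are rejected; items missing
in ≥ 50% of records must be excluded upstream; constant items are imputed
by their constant.

Pooling: point estimates (log-OR, AUC, proportions) are averaged across
completions; variances combine by Rubin's rules (within-mean plus
(1 + 1/m) × between-variance). With several completions, the screening CI
uses the Rubin-pooled Woolf variance and a normal p-value; with one
completion, the Pearson χ² p-value.

## Association screening

Orientation: exposure = symptom or marker, outcome = later-diagnosed
group. Default CI is Woolf's log-normal interval; a conditional mid-P
exact interval (root-finding on Fisher's noncentral hypergeometric tail
probabilities) is available, since two-by-two web calculators commonly
default to it. Zero cells trigger the Haldane–Anscombe +0.5 correction of
all four cells, flagged on the result. Four p-values are exposed —
uncorrected Pearson χ² (default), Yates, Fisher exact, hypergeometric
mid-P — because printed p-values in the field are rarely attributable to a
unique test. No multiplicity adjustment is applied across the 13 items, by
design. The screening rule selects items with estimated OR strictly above
2.0.

## Composite scores and diagnostics

Scores are unweighted counts of positive components. The ROC groups tied
scores into single operating points; the trapezoidal AUC then equals the
tie-corrected Mann–Whitney U/(n₁n₀) (asserted to 1e-12 against a
pair-counting oracle). The AUC p-value uses the normal approximation to U
with tie correction; the AUC CI uses the Hanley–McNeil standard error.
Operating-point proportions carry Wilson intervals by default (mid-P exact
optional); PPV intervals are reported, not asserted, because their flavour
is rarely identifiable from published tables. The default operating cut is
score ≥ 3 for every model row, including the 5- and 6-component models
(configurable). When several completions are supplied, symptom components
are pooled by per-cell majority vote before scoring (ties toward present);
per-completion analysis with mean pooling remains available through the
library. Percent formatting is half-up at one decimal throughout.

The audit helper inverts printed, rounded sensitivity/specificity pairs to
the set of integer confusion matrices consistent with them, flagging
uniqueness — e.g. sens 21.9% / spec 92.6% over 32 events and 148
non-events admits exactly one matrix (tp 7, fn 25, fp 11, tn 137), hence
PPV 7/18 = 38.9%.

## Survival analysis

The six-parameter algorithms are fixed: variant A = items 5, 10, 11 +
survivin + any antibody + female > 50 y; variant B replaces the last with
elevated CRP. Patients with ≥ 4 positive parameters form the high-risk
group. Kaplan–Meier estimation is delegated to lifelines, with Greenwood
variances computed from the at-risk table; progressors contribute an event
at their month of RA and non-progressors are censored at 48 months. The
48-month PPV is the plain event proportion of the high-risk group (no
early censoring exists under the generator's defaults); when early
censoring is present the complementary product-limit estimate 1 − S(48) is
reported alongside and the result flagged. The group odds ratio reuses the
2×2 machinery.

## Numerical conventions and test problem sizes

Brent root-finding tolerances 1e-10–1e-13; IRLS convergence 1e-8 on the
max coefficient step; linear predictors clipped at ±30 before the
logistic; percent rounding decimal half-up. Seeds flow from a single
integer per run: the generator consumes it directly, imputation uses
seed + 1 (mod 2³¹); identical seed and configuration give byte-identical
output bundles.

The stochastic validation suite runs 100 replicate cohorts at 20× stratum
sizes for parameter recovery (screening selects exactly items {5, 10, 11}
in ≥ 80% of replicates; the survivin–item-13 CI covers the configured OR
2.5 at near-nominal rates; every marker-enriched model out-AUCs the
clinical base in ≥ 90%; the ≥ 4-parameter group has the higher 48-month
event proportion in all replicates) and 100 study-sized replicates for
imputation robustness. These sizes give the Monte-Carlo precision the
assertions need while keeping the default test run fast.

## Known limitations

* Pre-RA marker enrichment (OR 3.0) and all symptom prevalences are
  calibration choices, not measurements; any conclusion that depends on
  their exact values is outside what the synthetic cohort can support.
* The chained-equation posterior draw uses the asymptotic normal
  approximation, not a bootstrap; at 2% missingness this is immaterial,
  at high missingness it would understate between-imputation variance.
* The 2010 score's acute-phase category is CRP-only (no ESR), which can
  underscore by one point relative to a full criteria form.
* Survival machinery assumes censoring only at the horizon or at random;
  competing risks and log-rank/Cox modelling are out of scope.
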