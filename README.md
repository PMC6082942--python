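# arthrasight

Recognition of imminent rheumatoid arthritis (RA) among patients with
unexplained arthralgia.

Most patients who present to a rheumatology clinic with joint pain but no
detectable joint swelling will never develop RA — yet roughly one in five
does, within a few years. `arthrasight` implements, as a tested and
reusable pipeline, a strategy for picking those *pre-RA* patients out at
their first visit: screen first-visit joint-symptom items by their odds
ratio between progressors and non-progressors, combine the discriminating
symptoms with serological biomarkers (serum survivin, RA-specific
autoantibodies, C-reactive protein) into unweighted composite scores,
evaluate the scores by ROC/AUC and operating-point diagnostics, and follow
the time to RA with Kaplan–Meier curves stratified by how many risk
parameters a patient carries.

It is aimed at biostatisticians and clinical epidemiologists who want the
whole chain — cohort data model, multiple imputation of sparse symptom
items, 2×2 odds-ratio machinery, composite-score diagnostics and survival
analysis — in one place, together with a calibrated synthetic first-visit
cohort generator so every stage can be exercised and validated without
access to patient data.

## The method

**Data model.** Each patient carries 13 ternary joint-symptom items
(present / absent / missing), raw serology (RF U/ml, ACPA AU/ml, CRP mg/L,
survivin pg/ml), a first-visit joint exam, and a longitudinal outcome
(months to RA within a 48-month horizon). Serology is dichotomised at the
clinical cut-offs (RF ≥ 20 U/ml, ACPA > 20 AU/ml, CRP ≥ 5 mg/L, survivin
≥ 450 pg/ml). Patients with joint swelling scoring ≥ 6 on the EULAR/ACR
2010 classification criteria are RA at first visit; swelling with score
< 6 is undifferentiated arthritis (UA); no swelling is arthralgia.
Arthralgia patients who fulfil the RA criteria during follow-up are
labelled **pre-RA** at their first visit.

**Screening.** For each symptom item *i*, the odds ratio

&nbsp;&nbsp;&nbsp;&nbsp;OR&#8336; = (a·d)/(b·c)

between pre-RA and remaining arthralgia is estimated with a Woolf 95% CI,
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); items with OR > 2.0 enter the
model.

**Composite scores.** A model is an unweighted count of positive binary
components: score = Σ&#8342; 1[x&#8342; = 1] ∈ {0, …, K}. The score's AUC
equals the tie-corrected Mann–Whitney statistic U/(n₁n₀); a patient is
test-positive at score ≥ 3 (the default operating cut), giving
sensitivity, specificity, PPV and NPV with Wilson or mid-P exact CIs.

**Survival.** Among arthralgia patients, carrying ≥ 4 of the 6 algorithm
parameters (3 clinical items + survivin + any antibody + female > 50 y, or
CRP in the alternative variant) defines the high-risk group; RA-free
survival is the product-limit estimate S(t) = Π 1 − dᵢ/nᵢ, and the
48-month PPV is the event proportion of the high-risk group.

## Worked example

```python
import arthrasight as a

cfg = a.PipelineConfig(seed=7, output_dir="out")
res = a.run_pipeline(cfg)

print("selected symptoms:", res["screen"].selected)
print(res["models"][["model", "auc", "sens", "spec", "ppv"]].round(3).to_string(index=False))
s = res["km"]["A"]
print(f"variant A: high group {s['n_high']} patients, {s['events_high']} events; "
      f"48-month PPV {100*s['ppv']:.1f}% (95% CI {100*s['ppv_ci'][0]:.1f}-{100*s['ppv_ci'][1]:.1f}), "
      f"OR {s['odds_ratio'].or_hat:.2f}")
```

prints

```
selected symptoms: [5, 6, 8, 10, 11]
                       model   auc   sens   spec    ppv
                  5 clinical 0.753 59.375 76.351 35.185
              + Survivin+CRP 0.813 90.625 62.162 34.118
            + Survivin+AnyAB 0.804 81.250 63.514 32.500
                 + CRP+AnyAB 0.817 87.500 58.784 31.461
        + Survivin+CRP+AnyAB 0.836 90.625 52.703 29.293
+ Survivin+AnyAB+female >50y 0.801 84.375 54.054 28.421
variant A: high group 31 patients, 17 events; 48-month PPV 54.8% (95% CI 37.8-70.8), OR 10.85
```

The pipeline simulated one study-sized cohort (180 arthralgia of whom 32
progress, 73 UA, 63 RA at first visit), imputed the ~2% of missing symptom
cells, screened the 13 items (at this single study-sized draw, sampling
noise lifts two extra items past OR 2 alongside the three truly enriched
ones — items 5, 10, 11; at larger sample sizes exactly those three are
selected), evaluated the screened clinical base model and its
marker-enriched variants at cut ≥ 3, and stratified the Kaplan–Meier
analysis at ≥ 4 of 6 parameters: a compact high-risk subgroup (31 of 180
arthralgia patients) captures 17 of the 32 progressors, with a 48-month
PPV of ~55% against the 17.8% background progression rate.

Every stage is also available separately (`a.generate_cohort`,
`a.impute`, `a.screen_symptoms`, `a.enrich_model`, `a.km_estimate`, …) and
from the shell:

```
arthrasight simulate --seed 7 --out cohort.csv
arthrasight impute --in cohort.csv --m 5 --seed 7 --out-prefix imp_
arthrasight screen --in cohort.csv --imputations 'imp_*.csv' --out screen.csv
arthrasight run --seed 7 --out bundle/
```

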