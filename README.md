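# dietrenal

Dietary pattern adherence scores and one-year kidney-function analysis for
longitudinal nutrition cohorts.

In nutritional epidemiology, the question of whether improving adherence to
a healthy dietary pattern preserves kidney function is typically studied by
scoring each participant's diet at two timepoints, categorizing the
one-year change in each score, and regressing one-year change in estimated
glomerular filtration rate (eGFR) — or the odds of a ≥10 % eGFR decline —
on those change categories with adjustment for confounders and
cluster-robust variance by recruiting center. `dietrenal` implements this
whole workflow as a tested, reusable library plus CLI, for biostatisticians
and nutrition researchers who want to run (or audit) such an analysis on
their own participant-level tables, and ships a synthetic cohort generator
with known embedded effects so every stage is verifiable without any
private data.

## What it computes

**Four a priori dietary pattern scores** per participant-timepoint:

* **17-item energy-reduced Mediterranean diet screener** (0–17): one point
  per binary criterion met (e.g. vegetables ≥ 2 units/day, legumes ≥ 3
  servings/week, moderate wine); criteria are data-driven (YAML presets).
* **Trichopoulou Mediterranean diet score** (0–9): favorable components
  score 1 when intake ≥ the sex-specific population median
  (vegetables, fruits+nuts, legumes, cereals+potatoes, fish, MUFA:SFA
  ratio), unfavorable components (meat, dairy) score 1 when below it, and
  alcohol scores 1 inside a moderate window (10–50 g/day men, 5–25 g/day
  women).
* **DASH score** (8–40): eight components scored 1–5 by population
  quintile, ascending for fruits, vegetables, legumes+nuts, low-fat dairy
  and whole grains, descending for sodium, red/processed meat and
  sugar-sweetened beverages.
* **Protein diet score** (0–20): 0–10 points for the undecile stratum of
  protein energy share (E%) plus 0–10 for the stratum of the plant:animal
  protein ratio.

**Renal outcomes** from serum creatinine via the 2009 CKD-EPI creatinine
equation (no race coefficient),

```
eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018 [if female]
```

with κ = 0.7/0.9 and α = −0.329/−0.411 for women/men; one-year change
ΔeGFR, percent change 100·ΔeGFR/eGFR₀, and the ≥10 % decline flag.

**Association models**: participants are categorized as
decrease/maintenance (Δscore ≤ 0, reference) vs tertiles of increase;
linear (ΔeGFR) and logistic (decline) models are fitted at three nested
covariate tiers (M1: sex, age, and baseline eGFR for linear models;
M2: + BMI, smoking, education, physical activity, diabetes, hypertension,
hypercholesterolemia, center-size quartile, intervention arm, energy;
M3: + baseline score and one-year weight change) with sandwich variance
clustered on recruiting center. Trend tests code the exposure as its
category-median change; interactions are tested by likelihood ratio; and a
leave-one-item-out analysis refits both outcomes for each of the 17
screener items, rescaling estimates by 16/17 (on the log scale for odds
ratios).

## Worked example

```python
from dietrenal import (
    GeneratorConfig, ModelSpec, generate_cohort, apply_exclusions,
    build_analysis_frame, fit_linear_change, trend_test,
)

cfg = GeneratorConfig(n_participants=2000, n_centers=12, seed=42,
                      true_effect_beta=0.23)   # ml/min/1.73m² per score point
cohort = generate_cohort(cfg)
analytic, flow = apply_exclusions(cohort.table)
print(flow.report())
frame = build_analysis_frame(analytic)
spec = ModelSpec(outcome="delta_egfr", score="ermed17",
                 coding="categorical", tier="M3")
res = fit_linear_change(frame, spec)
for cat, (est, lo, hi) in res.estimates.items():
    print(f"{cat:10s} beta {est:6.2f}  (95% CI {lo:6.2f} to {hi:6.2f})"
          f"  n={res.n_per_category[cat]}")
print(f"p for trend: {trend_test(frame, spec):.4f}")
```

prints

```
Enrolled participants: 2000
Excluded, incomplete dietary questionnaire: 0
Excluded, extreme total energy intake: 62
Excluded, missing creatinine: 0
Analytic sample: 1938

DecrMaint  beta   0.00  (95% CI   0.00 to   0.00)  n=1109
T1         beta  -0.52  (95% CI  -1.28 to   0.23)  n=361
T2         beta   0.81  (95% CI  -0.32 to   1.94)  n=227
T3         beta   0.95  (95% CI   0.01 to   1.90)  n=241
p for trend: 0.0192
```

Reading the output: 62 of 2000 synthetic participants drew implausible
energy intakes and were excluded by the sex-specific bounds; among the
rest, participants whose screener score rose the most over the year (T3)
gained on average 0.95 ml/min/1.73 m² more eGFR than the
decrease/maintenance reference, with a significant monotone trend —
consistent with the 0.23-per-point effect embedded by the generator.

The same workflow is available from the shell:

```bash
dietrenal generate --out run/cohort --seed 42 --n 2000
dietrenal all --seed 42 --out run/full --overwrite
dietrenal report --run-dir run/full
```

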