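# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the deliberate design choices of
`dietrenal`. It is the companion to the README's overview.

## Scoring procedures

### 17-item screener

Each of the 17 items is a binary criterion on one dietary variable
(frequency of consumption or a habit flag); the score is the count of
criteria met, 0–17. Criteria live in a YAML preset
(`dietrenal/data/ermed_criteria.yaml`) rather than code, with two presets
shipped. The default (`printed`) takes the white-bread item in its
"≥ 1 serving/day" direction as commonly printed; because that direction
reads contrary to the screener's healthful intent, an alternative preset
(`reversed_breads`) flips items 14 and 16 for sensitivity analyses. The
default follows the printed text; nothing in the pipeline depends on the
choice beyond the item indicators themselves.

Threshold comparisons are boundary-exact: "≥ 2" is met at exactly 2,
"< 1" is not met at exactly 1. The moderate-wine item is an inclusive
sex-specific window. When a cohort table carries pre-answered item
booleans, they take precedence over re-evaluating the criteria; an item
resolvable neither way raises an error naming the item.

### Median- and quantile-anchored scores

The Trichopoulou score needs sex-specific component medians, the DASH
score population quintiles, and the protein diet score 11 equal-frequency
strata of protein E% and the plant:animal protein ratio. All three sets of
reference statistics are estimated once from the baseline rows of the
analytic sample and then frozen; year-1 scores reuse the baseline cutoffs,
so a participant's one-year score change reflects intake change rather
than cutoff drift. This matches the a priori spirit of the scores; a
`reference="per-timepoint"` switch recomputes cutoffs at year 1 instead
for sensitivity analyses.

Numerical conventions, fixed for reproducibility:

* Quantiles use the median-unbiased empirical estimator
  (`numpy` method `median_unbiased`). With n divisible by 5 and no ties,
  the four quintile cutoffs fall strictly between order statistics, so the
  five groups hold exactly n/5 participants each (property-tested against
  a rank oracle).
* A value tied exactly with a cutoff is assigned to the **lower** stratum.
* "11 strata" are implemented as undeciles (cutoffs at k/11,
  k = 1..10) of the cohort distribution; the construction is cohort-rank
  based and no absolute cutoffs exist for it.
* A zero denominator in a ratio component (plant:animal protein with no
  animal protein; MUFA:SFA with no saturated fat) maps to +infinity, which
  preserves the monotone ordering and lands in the top stratum without
  magic constants. Undecile cutoffs are interpolated on the finite part of
  the distribution.
* Minimum reference sample sizes: 5 non-missing observations per quintile
  component (fewer than 5 *distinct* values warns; a constant component is
  an error), 11 per undecile component, and at least one participant per
  sex for medians.

## Renal outcomes

eGFR uses the 2009 CKD-EPI creatinine equation without the race
coefficient; the sex-specific constants live in a single table. Serum
creatinine is expected in mg/dL; values above 15 mg/dL are rejected as
probable µmol/L unless explicitly overridden. Year-1 eGFR is evaluated at
age + 1.

Percent change is 100·(eGFR₁ − eGFR₀)/eGFR₀ and a decline is flagged at
percent change ≤ −10. The boundary is inclusive ("≥ 10 % decline"); a
`strict` flag makes it exclusive for sensitivity analyses. The decline
flag is invariant to rescaling both eGFR values by a common factor.

The inverse mapping (creatinine for a target eGFR) is computed by
bisection on [10⁻³, 40] mg/dL to a tolerance of 10⁻⁸ mg/dL, exploiting
strict monotonicity. The synthetic-data generator uses this inverse, so
the generator and the estimator share a single eGFR definition; the
round-trip is exact to the bisection tolerance.

## Analytic sample and exposure categories

Exclusions run in a fixed order — incomplete dietary questionnaire at
either timepoint, total energy outside sex-specific plausibility bounds
(women < 500 or > 3500 kcal/day, men < 800 or > 4000 kcal/day; the bounds
themselves are retained), missing creatinine at either timepoint — and a
participant failing several rules is counted under the first (sequential
attribution, mirroring how study-flow paragraphs are written). An
`report_overlap` flag additionally counts per-rule failures regardless of
order. The energy rule is applied at both timepoints.

One-year score change ≤ 0 forms the decrease/maintenance reference
category ("maintenance" is exactly zero change, which belongs there);
strictly positive changes are ranked (ties broken by participant id) and
split into three near-equal groups, with boundary ties pushed into the
lower tertile. Each category carries its median change for trend coding.
Fewer than 3 strictly positive changes is an error: tertiles are
undefined.

## Association models

Ordinary least squares for ΔeGFR and maximum-likelihood logistic
regression for the decline flag, via statsmodels, with sandwich variance
clustered on recruiting center (the clustering unit is configurable). The
small-sample correction (G/(G−1)-type) is on by default and exposed as a
flag. Linear models use t critical values with G−1 degrees of freedom for
confidence intervals — the standard finite-cluster convention — while
logistic models use normal critical values; under a null embedded effect
the 95 % interval for the per-point coefficient covers zero at the nominal
rate in simulation (checked in the test suite). With singleton clusters
and the correction off, cluster-robust standard errors reduce to the
HC0 heteroskedasticity-robust ones.

Covariate tiers are nested (M1 ⊂ M2 ⊂ M3) as listed in the README.
Recruiting center enters M2+ as indicator variables for the quartile of
center enrolment, computed at the center level on the analytic sample
(with fewer than four centers, as many groups as centers). Smoking and
education are indicator-coded with "never" and "primary" as references.
The significance convention is two-tailed 0.05 with no multiplicity
adjustment.

The trend test replaces the category indicators with one continuous
regressor equal to each participant's category-median change and reports
that regressor's cluster-robust two-sided p-value. Interaction tests
compare models with and without exposure×modifier cross-product terms by
likelihood ratio (non-robust ML likelihoods, as is standard for LRTs),
with one degree of freedom per added estimable term; a modifier main
effect already spanned by the covariates (e.g. sex in M1) is not
duplicated.

Logistic fits check the exposure-by-outcome contingency table first and
raise an explicit separation error for zero-event categories instead of
diverging silently.

### Item-removal decomposition

For each screener item, the item's indicator is subtracted from the score
at both timepoints, the continuous-exposure M3 models are refitted with
the 16-item score change — adjusting additionally for the removed item's
own one-year change, and using the 16-item baseline score as the baseline
adjustment — and the coefficient (log odds ratio) is rescaled by 16/17 to
stay on the full score's per-point scale. Percent change relative to the
full-score estimate is computed on the raw scale for β and on the log
scale for odds ratios, so attenuation toward the null reads as a negative
percent change for both outcomes. Removing an item whose indicator never
changes reproduces the full fit exactly up to the 16/17 scaling (tested).

## Synthetic cohort generator

The generator emulates the table structure of an elderly Mediterranean
intervention cohort — men 55–75 and women 60–75 years, BMI 27–40,
recruited by 23 centers of unequal (Dirichlet-weighted) size by default —
with two timepoints per participant. Its defaults define the study
conditions used throughout the tests: energy intake log-normal with
arithmetic mean 2347.9 and SD 549.5 kcal/day, protein energy share
16.9 ± 2.8 %, covariate prevalences (diabetes 0.30, hypertension 0.84,
hypercholesterolemia 0.70, current/former smoking 0.13/0.43), and
plausible log-normal food-group and screener-variable intakes documented
in `simulate.py`. Where no printed value exists (individual food-group
locations, the intra-center correlation, the within-participant eGFR noise
of 7 ml/min/1.73 m², the 0.5 latent baseline/year-1 intake correlation),
values were chosen once as typical of such cohorts and are configurable,
not calibrated to any test outcome.

Generation is "backwards" from the estimator: baseline creatinine is
log-normal by sex, fixing baseline eGFR through CKD-EPI; the year-1 eGFR
target adds a mean drift (−0.94 ml/min/1.73 m² by default), a configurable
true effect `true_effect_beta` times the one-year change of a designated
score (the screener by default, computed by the *same* scoring code the
pipeline uses), a center random intercept sized as
σ_b² = ICC/(1−ICC)·σ_ε² to realize the configured intra-center
correlation, and Gaussian noise; year-1 creatinine is then obtained by
numerically inverting CKD-EPI. Screener item booleans are derived from the
generated dietary variables through the criteria table, so generated data
and scores cannot disagree. Missing values are written as explicit NA
sentinels, never as zeros. A fixed seed yields byte-identical output.

An injection utility plants exact numbers of exclusion-rule violations
(missing questionnaire, extreme energy beyond the sex-specific bound,
missing creatinine) in disjoint participant sets unless overlap is
requested, for testing the flow accounting.

What the generator does **not** emulate: the 143 individual
food-frequency items (generation starts at the food-group/variable level
the scores consume), correlations *between* food groups beyond the shared
within-participant persistence, measurement error in creatinine,
informative missingness, and secular dietary trends. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
unbiased under its assumed data-generating model, not that any particular
real-world association holds.

## Simulation sizes and calibration checks

The validation suite recovers an embedded per-point effect of
0.23 ml/min/1.73 m² from 100 replicate cohorts of n = 5000 — the mean
estimate must sit within the Monte-Carlo 95 % interval of the truth — and
checks null calibration (confidence-interval coverage of zero, uniformity
of trend p-values by Kolmogorov–Smirnov) on 200 null replicates of
n = 600–800. Oracle-equivalence checks run quintile, tertile and median
assignments against brute-force rank-based implementations on 1000 random
cohorts and the CKD-EPI evaluation against an independent scalar
implementation on a (sex, age, creatinine) grid.

## Known limitations

* The cluster-robust estimator is the standard CR1-type correction; with
  very few clusters (< ~10) its intervals undercover, as is well known —
  wild-bootstrap alternatives are out of scope.
* Mixed-effects alternatives to sandwich variance are not provided.
* Cystatin-C and combined eGFR equations, and albuminuria outcomes, are
  out of scope.
* The screener criteria presets encode serving/frequency thresholds; unit
  conversion from gram intakes to servings is the caller's responsibility
  when scoring real questionnaire data.
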