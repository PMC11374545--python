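# Methods

## Scoring model

Each diet index is a sum of unit scores over the 46 cells of the
23-food-group × {core, discretionary} grid. Per cell, the analysis sample's
survey-weighted consumption distribution (zeros included) is cut at its
20/40/60/80 weighted percentiles; a participant's base score is their
quintile 1–5, reversed to 6 − s for penalised categories and multiplied by
the context weight. Orientations and weights per index:

| index | healthy plant | unhealthy plant | animal | weight-2 cells |
| --- | --- | --- | --- | --- |
| PDI | positive | positive | reverse | none (46 units) |
| hPDI | positive | reverse | reverse | healthy-plant × core (53 units) |
| uPDI | reverse | positive | reverse | unhealthy-plant × discretionary (51 units) |

The weight placement is the unique {1, 2} assignment that reproduces all the
published theoretical totals simultaneously (PDI 46–230, uPDI 51–255, hPDI
lower bound 53) together with the "ten for healthy-plant core in the top
quintile, five from discretionary" example. The printed hPDI upper bound is
internally inconsistent in the source ("between 53 and 26"); the scheme
implies 265, which this package uses as a derived, not published, bound.

### Numerical choices

* **Weighted quantile**: inverse weighted ECDF, type "lower" — the cut is
  the smallest observed value whose cumulative weight share reaches the
  target. Reproducible, exactly checkable against a brute-force scan, and
  invariant to rescaling all weights.
* **Ties**: intake equal to a cut takes the lower quintile (half-open bins).
  In zero-heavy units (≥ 20 % of weighted mass at zero) the lower cuts
  collapse to zero, so all non-consumers land in Q1 and consumers occupy the
  upper bins — the deterministic consequence of the tie rule, pinned by
  tests rather than smoothed away.
* **Per-unit quintiles**: quintiles are computed per (group, context) cell,
  not per group subdivided afterwards; only this reading yields 46 PDI
  scoring units.
* Cutpoints are computed once on the post-exclusion analysis sample with the
  calibration weights, then applied to the same sample.

## Derived nutrients

PRAL (mEq/d) = 0.49·protein(g) + 0.037·phosphorus(mg) − 0.021·potassium(mg)
− 0.026·magnesium(mg) − 0.013·calcium(mg); "phosphate" in the source formula
is interpreted as dietary phosphorus, the convention of the original PRAL
estimator. The protein:fibre ratio is undefined below 0.1 g/d fibre and is
flagged (NaN / raised error) instead of returning absurd magnitudes.

## Outcome rules

CKD: eGFR < 60 ml/min/1.73 m² → stage 3–5 regardless of albuminuria;
eGFR ≥ 60 (60 itself included, "less than 60" being strict) with
ACR ≥ 2.5 mg/mmol (men) / 3.5 mg/mmol (women) → stage 1–2; otherwise no
CKD. The ACR cut-off is configurable because survey-specific flags differ.
Blood pressure: the analysis value is the second reading, or the mean of the
second and third when a third was taken (the acquisition protocol triggers a
third reading when the first two differ by > 10 mmHg on either component);
the first reading never enters. Hypertension at ≥ 140/90 (either component,
inclusive); diabetes risk bands HbA1c < 6 %, 6–6.4 %, ≥ 6.5 %; BMI is
weight/height².

## Survey inference

Point estimates use the calibration weights; variance uses the
delete-a-group jackknife with R = 60 replicate weight sets and
variance factor (R−1)/R, both configurable. 95 % CIs are normal
(± 1.96·se) and p-values are two-sided normal — chosen over a t reference
for simplicity and because replicate counts in this design are large.
Linear models solve weighted least squares; logistic models run IRLS to a
relative deviance tolerance of 1e-8 (max 100 iterations), with perfect
separation detected by a vanishing per-weight deviance and rank deficiency
rejected up front. Replicate standard errors refit the full model per
replicate weight set, warm-started at the main fit. The trend test enters
the total-score quintile as a numeric 1–5 term (quintile medians are not
implemented). The categorical test computes Pearson's χ² on weighted cell
proportions scaled to the sample size and divides by a first-order
design-effect correction (mean replicate-estimated cell design effect); with
equal weights and degenerate replicates it reduces exactly to the textbook
statistic. Diet-index exposures enter regressions as continuous per-unit
scores, so logistic coefficients exponentiate to per-point odds ratios.

Model ladder: M1 age + sex; M2 adds education, physical activity, smoking;
M3 adds BMI to M2; M4 adds energy and alcohol to M2; M5 both; the fully
adjusted CKD model uses age, sex, energy, education, physical activity,
smoking, diabetes, hypertension, BMI and alcohol. BMI and waist
circumference outcomes are never BMI-adjusted. HDL, TAG, glucose, HbA1c,
systolic BP, waist and BMI are modelled on the natural-log scale.

## Exclusions

Applied sequentially, each participant counted at the first rule that
removes them: (i) age < 18; (ii) missing second recall; (iii) two-day mean
energy below 800 kcal/d (3347.2 kJ/d, men) or 500 kcal/d (2092.0 kJ/d,
women), kcal→kJ at 4.184; (iv) missing any required covariate or variable
of interest. Fasting-dependent lipids (LDL, TAG, glucose) are not in the
default required set; models with those outcomes drop non-fasted rows at
fit time with the design subset in step.

## Synthetic cohort generator

The generator's defaults are the study conditions: n = 2060, CKD prevalence
250/2060, moderate-severe fraction 103/250, injected uPDI log odds ratio
ln(1.037), R = 60 replicate groups, population total 8 769 986.

A scalar latent healthfulness trait per participant (correlated ~0.25 with
standardised age) drives everything dietary: per (group, context) cell,
consumption is zero-inflated (consumer probability tilted by the trait) and
consumer intake is log-normal with the log-median shifted by
±0.35 × trait (healthy plant up, unhealthy plant down, animal down 0.6 as
much); recall days are independent draws around the participant's latent
level, with an extra 25 % day-skip for episodic cells (zero-inflation
≥ 0.5, e.g. legumes/core at π₀ = 0.6, deliberately stressing the quintile
tie rule). Cell medians are round per-group portion figures scaled so mean
energy lands near 8.7 MJ/d, typical of adult two-recall surveys. Nutrients
are linear in group grams via an order-of-magnitude density matrix with
10 % multiplicative log-normal noise, so fibre, potassium and magnesium
fall as uPDI rises; alcohol is drawn separately (55 % drinkers, log-normal
median 12 g/d) and contributes 29 kJ/g to energy.

Part of the intake mass is emitted through four multi-ingredient dish codes
(grams chosen within the feasible simplex of the drawn cell intakes), the
rest through single-ingredient codes — so the recall file exercises
ingredient decomposition while round-tripping exactly to the intakes the
generator scored.

Disease is injected on the *scored* exposure: the generator computes uPDI
with the package's own engine on the generated cohort (full sample,
calibration weights) and draws stage 3–5 CKD from
logit p = c + ln(1.037)·uPDI + 0.03·(age−48) + 0.25·male + 0.6·diabetes +
0.4·hypertension + 0.02·(BMI−27), with c solved by bisection so the
marginal prevalence matches the moderate-severe target; stage 1–2 is then
assigned among the remainder at the rate that brings total CKD prevalence
to target in expectation. Biomarkers are drawn consistently with the
assigned stage (eGFR truncated below/above 60, ACR below/above the
sex-specific albuminuria cut), so the rule-based classifier recovers the
generated truth exactly — making parameter recovery a genuine end-to-end
test of decomposition, scoring, classification and survey fitting together.
The covariate effect sizes are plausible orders of magnitude, configurable,
and claim no correspondence to any real survey.

Replicate weights are delete-a-group jackknife with groups assigned
round-robin by participant index; calibration weights are log-normal
(sd 0.35) normalised to the population total.

### What the generator does not emulate

No household/PSU clustering (replicate groups are synthetic), no weight
calibration to demographic benchmarks, no seasonality or weekday structure
in recalls, no measurement error in the recall itself beyond day-to-day
variation, and no realistic food catalogue (50 synthetic codes). Passing
parameter recovery therefore demonstrates the correctness of the analysis
machinery under the assumed design, not the robustness of the published
epidemiological findings to real-data complications.

## Verification design and problem sizes

Analytic anchors (index bounds, PRAL arithmetic, classifier boundaries,
BP selection) are asserted exactly. Engine-vs-oracle checks run the
vectorised paths against independent brute-force implementations (weighted
ECDF scans, per-unit scoring loops, explicit jackknife loops, statsmodels
OLS/Logit under equal weights) on cohorts of ≤ 50. Stochastic properties
use fixed seed lists: generator calibration and odds-ratio recovery run 200
cohorts at n = 2060 (bias judged against the Monte-Carlo standard error;
CI coverage required in [92 %, 98 %]), and the trend test's type-I error
uses 1000 null replicates at n = 300 with fresh weights and quintiles per
replicate, so the measured 5 % level is unconditional rather than specific
to one weight configuration.

## Known limitations

* The two animal food groups beyond the nine conventionally named ones are
  placeholders; the taxonomy enforces only the 23-group count and the
  7/5/11 category split.
* Variance estimation implements only the replicate-weight jackknife — no
  Taylor linearisation, bootstrap or BRR.
* The categorical test's design correction is first-order (mean cell design
  effect), not a second-order Rao–Scott adjustment.
* Missing data are handled solely by exclusion, mirroring the analysis the
  package models; no imputation.
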