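# Methods

## The model

`dmintake` centres on an empirical prediction equation for the dry-matter
intake (DMI, kg/d) of lactating Holstein cows, the model adopted by the
Korean feeding standards for dairy cattle (KFSD):

    DMI = 4.103 + 0.112·MBW + 0.284·FCM − 0.119·NDF

where MBW is metabolic body weight (BW^0.75, kg^0.75, proportional to
maintenance energy demand), FCM is 4% fat-corrected milk (kg/d, an
energy-equivalent milk yield), and NDF is the neutral detergent fibre content
of the diet (% of dietary DM, the rumen-fill constraint).  The model is a
plain linear form: intake is driven up by body size and milk output and down
by dietary fibre.  Early-lactation intake depression is handled
multiplicatively by a lag function

    Lag[x] = 1 − exp(−rate·(WOL + offset))

with WOL the week of lactation; Lag[2] (rate 0.316, offset 2.36) assumes peak
milk in month 2 and Lag[3] (rate 0.192, offset 3.67) in month 3.  The source
material prints the Lag[2] rate twice as 0.316 (in the equation tables) and
once as 0.318 (in the running text); the package defaults to 0.316 and the
constant is an ordinary `LagSpec` field for anyone who prefers the other
value.  The lag multiplier is applied at every week of lactation — it
asymptotes to 1 within machine precision long before week 60, so restricting
it to the first 16 weeks would only introduce a kink.

Comparator equations on the same inputs: NRC 2001
(`(0.372·FCM + 0.0968·MBW)·Lag[x]`, Lag[3] by default), CNCPS
(`(0.0185·BW + 0.305·FCM)·Lag[x]`, Lag[2] by default) and the parity-specific
Japanese feeding standard, which carries its own built-in lactation-stage
term.

FCM is computed by the standard Gaines energy form
`FCM = 0.4·MY + 15·(fat%/100)·MY`, the identity at exactly 4% milk fat.
All percentage inputs are percentage points, never fractions; range checks
enforce this.  Negative linear predictions (possible only at inputs far
outside the supported range) are clamped to 0 with a warning.

## Database curation

Literature records (treatment means clustered by study) pass six inclusion
rules applied in a fixed order with first-failing-rule attribution: milk
yield reported; Holstein; DMI ≥ 2% of body weight; forage fraction of dietary
DM in [30, 100) (both low-forage and all-forage diets excluded, boundary 30
retained); dietary NDF ≥ 25% of DM; week of lactation reported.  A missing
`breed` column is read as all-Holstein, since single-breed databases commonly
omit it; a record whose DMI-per-BW cannot be evaluated is rejected under that
rule because the rule cannot be certified.  Studies with at least four
retained observations form the development set, the rest the evaluation set.
The original procedure kept exactly four observations from larger studies;
how those four were chosen is not recorded, so the package keeps all
observations by default and offers a seeded random `cap_per_study`
subsample.

## Model development

Phase one screens candidate predictors with a study-random coefficient
model y = Xβ + Zu + e: each study contributes an independent random
intercept and one independent random slope per fixed-effect column
(diagonal per-study variance blocks, no covariances), residuals iid.
Fitting is REML through `statsmodels` `MixedLM` with the diagonal structure
imposed through its free-parameter mask.  Columns are scaled to unit SD
before fitting — a pure scaling, which preserves the diagonal-G model class
while greatly improving optimizer conditioning — and all estimates and the
restricted log-likelihood are mapped back to the original scale (scaling X
by diag(c) shifts the REML log-likelihood by −Σ log cⱼ, which is undone so
criteria are comparable across candidate subsets).  Because the
restricted-likelihood surface has a near-flat ridge (a non-centred random
slope evaluated near the predictor mean is almost indistinguishable from a
random intercept), a single gradient fit can stall: the BFGS solution is
polished by a derivative-free Powell pass and the better of the two is kept.
Variance components sit on a floor at zero; a fit with any component at the
boundary is reported with `boundary=True` and treated as converged.

Information criteria under REML count only variance parameters:
q = (number of random-effect variances) + 1 for σ², AIC = −2ℓ + 2q,
BIC = −2ℓ + q·ln(s) with s the number of studies (an N-based BIC is a flag
away).  All candidate subsets are fitted on the common complete-case row
set so criteria are comparable; subsets are ranked by AIC with BIC as the
tie-break.  Exclusion pairs (BW/MBW, MY/FCM, each nutrient with its own
intake variant) keep alternative encodings of the same quantity from being
co-selected, and a subset-size cap (default 4) bounds the enumeration.

Phase two re-estimates the winning subset by ordinary least squares without
random effects — that is how the published coefficients and their standard
errors are defined, so the package reproduces the choice (including its
disregard of study clustering in the phase-two standard errors; cluster-
robust SEs would be the modern alternative but are deliberately not the
default).

## Evaluation statistics

Precision is R² of observed on predicted; accuracy is RMSPE
(√mean((obs−pred)²)).  Bias is decomposed by regressing the residual
(obs − pred) on the mean-centred prediction: the intercept is the mean bias
(exactly the arithmetic mean residual, by centring) and the slope is the
slope bias; each gets a classical two-sided t-test.  Identities maintained
by tests: lin_slope = 1 + slope_bias on the same data, and
RMSPE² = mean_bias² + slope term + dispersion exactly.  Model comparison
uses listwise deletion across all requested models so every row of a
comparison table shares the same n.  Seasonal evaluation filters by a
`month` tag: cold = Nov–Jan, warm = Mar–Jun.

## Sensitivity analysis

Input marginals are fitted from data over seven candidate families (normal,
lognormal, gamma, Weibull, logistic, uniform, triangular) and judged by
χ² (equal-probability bins, ⌈2·n^0.4⌉ of them), Kolmogorov–Smirnov and
Anderson–Darling statistics.  The normal is kept whenever all three tests
fail to reject it at α = 0.05, with p-values from a 500-resample parametric
bootstrap (parameters are re-estimated per resample; fixed-parameter tables
would be anti-conservative when parameters come from the same data).
Otherwise the family with the best mean rank across the three raw statistics
wins; ranking needs no p-values, so only the normality decision pays the
bootstrap cost.

Sampling is Latin hypercube (SciPy's `qmc.LatinHypercube`): exactly one draw
per equal-probability stratum per variable, with independent random pairing
across variables.  A Spearman rank-correlation target can be induced by
Iman–Conover reordering; the default is independence because no correlation
structure is documented for the source database — this is the main known
gap between the simulated and the real input space, and it is why the NDF
coefficient lands near its independence value (≈ −0.25) rather than the
−0.2 reported from the original (possibly correlated) run.

Batches (default 1,000 samples) are appended until the output mean and SD
both change by less than 1% between consecutive batches, with at least three
batches always run and a hard cap (default 10⁶ samples); a run that hits the
cap reports `converged=False` with its trace.  Influence is measured by
standardized regression coefficients — OLS of the output on z-scored inputs,
divided by the output SD — which for a deterministic linear model with
independent inputs equal βⱼ·SDⱼ/SD_out and have squared sum 1.  Standardized
and raw per-unit coefficients are different scales; the package reports the
standardized one and leaves per-unit effects to the equation itself.

## Synthetic data

The literature generator defaults are the development-database conditions:
103 studies, 458 treatment means (4–5 per study), inputs from truncated
normals at the development moments (BW 640.33 ± 50.29 kg, FCM 31.22 ± 6.36
kg/d, fat 3.49 ± 0.46%, NDF 33.35 ± 4.51% DM, forage 53.35 ± 12.82% DM,
CP 16.93 ± 1.76% DM), DMI = KFSD equation + per-study intercept (SD 1.5
kg/d) + residual (SD 1.0 kg/d).  Week of lactation, which the source tables
do not summarise, is a truncated normal (15 ± 10, clipped to [1, 44]); the
parity mix is 30% primiparous.  FCM and fat are sampled and milk yield is
derived as MY = FCM/(0.4 + 0.15·fat): the published MY, fat and FCM means
are mutually inconsistent under independent sampling (deriving FCM from
sampled MY and fat shifts its mean ~0.6 kg/d high, and no valid correlation
closes the gap), whereas sampling FCM directly keeps the regression input
calibrated and the three columns exactly consistent.  Inputs are sampled
independently — the database's input covariances are unpublished — which is
the generator's main realism gap: tests passing on this generator certify
the estimation machinery, not the field covariance structure.  Truncation
is rejection sampling with a 10⁴-round cap; the residual of any record
pushed below the 2%-of-BW intake floor is redrawn so every generated record
passes the inclusion filters by construction.

One calibration caveat: the published coefficients are printed to three
decimals, so the equation evaluated at the database's own input means gives
~23.2 kg/d rather than the printed development-mean DMI of 22.66; the
generator is calibrated to the equation, and tests check the generative
identity exactly and proximity to 22.66 loosely.

The farm generator emulates a monthly automated-feeding trial: 32 cows over
Nov–Jun minus Feb, persistent per-cow body weight (751 ± 79.5 kg), FCM
(31.9 ± 6.47 kg/d) and intake deviation (SD 1.0 kg/d), a tight high-NDF
ration (40.0 ± 0.98% DM), month-to-month residual SD 2.0 kg/d, and an
optional cold-season offset (kg/d, default 0) added to observed DMI in
Nov–Jan.  With the offset at 2.3 kg/d the seasonal evaluation reproduces the
qualitative cold/warm contrast: a strongly significant cold-season mean bias
near the offset and an unbiased warm season.  DMI values beyond 3 SD of a
cow's own mean are flagged as outliers rather than silently dropped.

## Problem sizes and numerical choices

The validation experiments run at the study scale where that is cheap
(coefficient recovery: 20 seeds × 458 observations; sensitivity: 10,000 LHS
samples) and at a reduced scale where the full mixed-model enumeration is
not (selection consistency: 20 seeds × 40 studies × 160 observations —
the AIC gap between the true and runner-up subsets is already ≫ 10 at that
size).  REML convergence: relative likelihood tolerance of the underlying
optimizer, max 500 iterations, variance floor at 0; OLS matches the
normal-equation solution to 1e-8; ties in AIC ranking are broken by BIC and
then by stable sort order.

## Known limitations

Holstein-only scope; no environmental/temperature adjustment term (the cold
-season bias machinery quantifies the gap but the package does not correct
it); empirical treatment-mean scale, so per-cow daily dynamics are out of
scope; independent-input sampling in both the generators and the default
sensitivity run; phase-two standard errors ignore study clustering by
design fidelity.
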