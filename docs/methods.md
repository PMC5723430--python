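# Methods

## Scoring model

**Option decoding.** Every frequency option maps to a times-per-month
midpoint stored in the instrument YAML, never in code: "never" is 0,
bounded ranges use the arithmetic mean of their endpoints, and open-ended
top categories are coded at their stated bound ("2 or more times per day"
→ 2/day). Weekly ranges convert at 30.4/7 weeks per month and
`days_per_month = 30.4` (365.25/12) converts monthly frequencies to daily
intake. Bound-coding of the top category is conservative (it understates
heavy consumers); both it and the calendar constant are overridable in the
instrument file.

**Grams per day.** Foods/beverages: frequency midpoint × item-specific
grams per serving ÷ days per month. Condiments: fraction-of-time option ×
the attached main item's frequency × the condiment's serving ÷ days per
month. Condiment intake therefore propagates missingness from the main
item, which is why imputation runs before scoring.

**Energy.** Recomputed everywhere as 0.017 MJ/g × (carbohydrate + protein)
+ 0.037 MJ/g × fat. Because the formula is linear, group totals, subgroup
totals and the subject total all satisfy it exactly by construction, and
the scoring engine asserts conservation (groups sum to totals, 33
subgroups sum to their four parents) to 1e-9.

**Share tables.** Cohort-level nutrient shares are reported as shares of
summed cohort intake (an additive decomposition whose TOTAL row is exactly
100); mean-of-per-subject-shares is available as an option since published
tables rarely state which convention they use. Per-subject PEI-UPF for
modeling is always the subject's own group-4 energy fraction. Rounding
(1 decimal, or 1 significant figure below 0.1) happens only in the
`*_display.csv` companions; all computation and the primary CSVs are full
precision.

## Imputation

A re-implementation of the missForest algorithm on the option-index
(ordinal integer) representation: initialize missing cells with the column
mode (ties to the lowest category), visit variables in order of increasing
missingness, fit a random forest on the rows where the variable is
observed and predict its missing rows, and repeat until the change metric
(proportion of changed categorical cells + normalized RMS change of
numeric cells) first increases — then return the previous iterate.
Forests are scikit-learn's; ensemble size defaults to 100 trees,
majority-vote prediction resolves ties toward the lowest class index, and
all tree randomness derives from the user seed, so a fixed seed gives a
bit-identical completed table. Observed cells are never modified and
predictions are necessarily drawn from the observed category set.
Out-of-bag error per variable is reported when the observed sample is
large enough to estimate it. Single imputation only — no pooling across
multiple imputations.

## Cohort models

Ordinary least squares of each outcome on the focal dietary index, the
covariate set (maternal: age, race, clinic, weight status, daily energy
kcal, daily fat g, % moderate physical activity; neonatal models add
gestational age at measurement), a *forced* focal×obese interaction (lean
and obese groups get separate slopes and intercepts), and screened
candidate interactions: each focal×covariate product is added to the same
base design and retained iff its two-sided p < 0.05, making the screen
order-independent. Wald CIs use the t distribution with residual df
(appropriate at n ≈ 45). Categorical covariates are treatment-coded with
reference levels Caucasian, low-income clinic, lean. Continuous terms are
uncentered by default (centering is an option); rank-deficient designs
raise an error naming the collinear columns found by pivoted QR. No
multiple-testing correction is applied across outcomes — deliberately, to
mirror the small-cohort analysis convention this package targets; treat
per-outcome p-values accordingly.

Index comparison fits the adjusted model per index, reports each adjusted
R², and computes the extra-sum-of-squares F statistic for adding the
second index's terms to the first index's model,
F = [(RSS_reduced − RSS_full)/Δdf]/[RSS_full/df_full]. The union design is
solved rank-aware, so a duplicate index degenerates to ΔRSS = 0, F = 0
rather than an error. Pearson correlations carry Fisher-z CIs
(SE = 1/√(n−3)).

Diagnostics: Shapiro–Wilk on residuals (normality), the Breusch–Pagan
regression of squared residuals on fitted values (homoscedasticity), the
quadratic-in-fitted term of a residual regression (linearity), and a
lag-1 Ljung–Box test (independence), each flagged at 0.05. The two
regression-based tests are asymptotic; at n = 200 their null rejection
rates sit near 6% rather than exactly 5%. Components that are not
computable for a given sample (zero-variance residuals, tiny n) are
reported as such instead of failing.

## Synthetic generator

The generator is a stated world, fixed once:

| quantity | default | origin |
|---|---|---|
| n subjects | 45 (16 lean / 29 obese) | published cohort size |
| PEI-UPF | mean 54.4, SD 13.2, truncated to [0,100] | published summary |
| HEI-2010 | mean 62.2, SD 13.0, corr −0.74 with PEI-UPF | published summary |
| age | 27.2 ± 5.1 y | published summary |
| race (AA/other), clinic (high-income) | p = 0.533, 0.578 | published frequencies |
| moderate PA | 13.8 ± 4.1 % | published summary |
| gestational age at neonatal measure | 39.6 ± 1.2 wk | published summary |
| energy | 2510 ± 600 kcal/day | 10.5 MJ/day cohort mean; SD a field-typical FFQ spread |
| fat | 95 ± 30 g/day | ≈35% of energy from fat; typical US intake |
| focal effects | 1.33 / 0.22 / 0.14 / 0.62 per %-point | published estimates (GWG kg, thigh and subscapular skinfold mm, neonatal body-fat %) |
| missingness | 5% MCAR | unreported in the source; typical FFQ item nonresponse |

Truncated-normal marginals are moment-matched (the parent mean/SD are
solved so the *truncated* distribution has exactly the stated moments),
and HEI-2010 is tied to PEI-UPF through a Gaussian copula. When scored
PEI-UPF values are supplied from generated responses, their latent normal
scores feed the same copula, so realized shares keep the configured
correlation with HEI. Outcome models use the published covariate
coefficients, an intercept solved so the outcome mean matches the
published cohort mean, and a focal×age plus focal×obese interaction.

**Residual SDs are calibrated, not published.** The source reports no
residual variance, so the defaults (6.3 kg, 1.25 mm, 0.71 mm, 3.37 %) were
computed once so that the focal-term standard error at n = 45 — via the
average design factor √[(XᵀX)⁻¹]₍focal₎ over simulated designs — makes the
focal p-value land at the published value (0.016 / 0.045 / 0.026 / 0.037).
They are a calibration of the stated world, not ground truth.

**Response generation.** Each subject's frequency options start from a
dietary-pattern baseline — group-4 items more frequent the higher the
subject's target share, other items the reverse, plus a subject-level
appetite shift common to all items and ±1 option jitter — and a greedy
pass then applies single-option steps until the implied group-4 energy
share is within 0.25 points of the target (unreachable targets warn and
keep the best achievable share). Portion and condiment options are drawn
independently. Scoring the unmasked responses through the intake engine
recovers the assigned shares with a maximum gap of ~0.24 points (the
closed-loop property the tests assert). What the generator does *not*
emulate: the real DHQ II item inventory, food co-consumption structure
(beyond the single appetite factor), seasonal/secular intake variation,
systematic underreporting, or non-MCAR missingness. A green test
establishes that the pipeline recovers the structure this world contains —
not that the published estimates are correct.

## Numerical and design choices

- Beverages carry their own (longer) frequency scale; the instrument file
  determines its length, since only the endpoint labels are standardized.
- The composition fixture is synthetic but dimensionally realistic
  (per-100 g macros, three serving sizes per item); when a single FFQ
  question covers several foods, the fixture carries one nutrient row (the
  most-consumed food), keeping that convention out of code.
- `fit_ancova` recovery simulations fit the same interaction set the
  generator uses (focal×obese, focal×age); estimator bias < 0.2% and CI
  coverage ≈ 95% at 500 seeds.
- The end-to-end recovery suite runs the cohort-generation → fit chain at
  500 seeds; the full FFQ chain (responses → imputation → scoring → fit)
  is exercised at a handful of seeds because 500 forest imputations would
  dwarf the test budget. The imputation-beats-mode check runs 30-tree
  forests with 5 sweeps (the 100-tree default showed no accuracy
  advantage on this world and triples runtime).
- The simulated cohort's absolute energy scale (~8–9 MJ/day) is below the
  10.5 MJ/day cohort mean: the greedy share-matcher optimizes shares, not
  totals. Shares, not absolute intakes, drive every modeled quantity.

## Known limitations

- Exact reproduction of published coefficients requires the original
  deposited subject-level dataset, which cannot be redistributed here; the
  loader accepts it (with an optional column-rename mapping) at
  `data/final_cleaned_dataset.csv`, and the corresponding test fails
  (rather than skips) in its absence.
- HEI-2010 is consumed as a provided column; computing it from
  food-pattern equivalents is out of scope.
- Nutrient accounting covers the seven tabulated quantities (energy,
  carbohydrate, protein, fat, total sugars, fiber, sodium) only; no
  micronutrients or supplements.
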