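# upfdiet

Scoring and modeling of ultra-processed food consumption from
food-frequency questionnaires, for maternal/neonatal nutrition studies.

## The problem

A month-recall food-frequency questionnaire (FFQ, in the shape of the NIH
Diet History Questionnaire II) records, for every food line item, a
categorical consumption frequency ("never" … "2 or more times per day"),
one of three portion sizes and — for condiments — the fraction of the time
they accompany a main food. `upfdiet` turns those categorical answers into
grams per day, classifies every item into the four NOVA processing groups
(1 unprocessed/minimally processed, 2 processed culinary ingredients,
3 processed, 4 ultra-processed) and 33 nested subgroups, and computes each
subject's **PEI-UPF** — the percent of energy intake derived from
ultra-processed (NOVA group 4) foods:

```
PEI-UPF_i = 100 · E_i(group 4) / E_i(total)
```

Energy is always recomputed from macronutrients rather than read from a
database:

```
E [MJ] = 0.017 MJ/g · (g carbohydrate + g protein) + 0.037 MJ/g · g fat
```

Downstream, PEI-UPF (or any other dietary index, e.g. HEI-2010) enters
ANCOVA-style OLS models of maternal gestational weight gain and neonatal
body composition:

```
y = β0 + β1·PEI-UPF + β2·age + … + γ1·PEI-UPF×Obese (forced)
      + γ2·PEI-UPF×age (retained iff p < 0.05) + ε
```

with treatment-coded race / clinic / weight-status covariates, Wald t CIs,
interaction screening, residual diagnostics, Fisher-z Pearson CIs and
extra-sum-of-squares F comparison of competing indices by adjusted R².

Missing categorical answers are filled by a missForest-style iterative
random-forest imputer operating on the option indices. A synthetic
generator produces FFQ responses and cohort tables with the full
statistical structure (share targets, HEI copula correlation, linear
outcome models), so every stage is testable without access to clinical
data.

## Worked example

```
$ upfdiet simulate --seed 7 --out demo
wrote ['instrument.yaml', 'composition.csv', 'nova_map.csv', 'responses.csv',
 'cohort.csv'] to demo (mean realized PEI-UPF 53.5)

$ upfdiet run --responses demo/responses.csv --cohort demo/cohort.csv \
      --trees 30 --out-dir demo_out
wrote 19 report files to demo_out
```

`group_shares.csv` decomposes cohort intake by NOVA group (columns are %
of total cohort intake; the simulated cohort obtains about half its energy
from group 4):

```
nova_group  energy_MJ_per_day  energy_pct  carb_pct  protein_pct  fat_pct
         1                3.2        36.5      31.2         61.1     31.8
         2                0.4         4.2       1.2          0.0     10.2
         3                0.8         8.7       6.8         13.2      8.9
         4                4.4        50.7      60.8         25.7     49.1
     TOTAL                8.7       100.0     100.0        100.0    100.0
```

`model_gwg_kg_display.csv` is the fitted gestational-weight-gain model
(β, 95% CI, p), here recovering the simulated focal effect of 1.33 kg per
PEI-UPF percentage point as 1.2 (0.5, 1.9), and retaining the
PEI-UPF×age interaction that the generator builds in:

```
           term    beta   ci_low  ci_high       p
        pei_upf   1.200   0.5000    1.900 0.00200
            age   2.200   0.8000    3.500 0.00200
    pei_upf:age  -0.040  -0.0700   -0.020 0.00300
  pei_upf:obese  -0.008  -0.3000    0.300 1.00000
        ...
```

The run summary reports the PEI-UPF ↔ HEI-2010 correlation of the scored
cohort, r = −0.77 [−0.87, −0.62] (the generator targets −0.74), and
`index_comparison.csv` the adjusted-R²/extra-SS-F contest between the two
indices per outcome.

The same operations are available as library functions
(`upfdiet.build_profile`, `upfdiet.fit_ancova`,
`upfdiet.compare_indices`, …); the CLI is a thin wrapper.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete chain from scratch — simulates an input bundle,
imputes the masked responses, scores them into intake profiles, fits the
outcome models and index comparisons — and writes the results manifest to
`--out`. All randomness derives from `--seed`.

## Layout

- `src/upfdiet/instrument.py` — instrument/option model, food table, NOVA
  map and response I/O, cohort-table loader
- `src/upfdiet/intake.py` — grams/day, energy recomputation, NOVA
  aggregation, PEI-UPF, share tables
- `src/upfdiet/impute.py` — iterative random-forest imputation
- `src/upfdiet/models.py` — ANCOVA fits, screening, diagnostics, index
  comparison, Pearson CIs
- `src/upfdiet/synthetic.py` — cohort and response generator
- `src/upfdiet/pipeline.py`, `cli.py` — orchestration, reports, CLI
- `docs/methods.md` — model and generator documentation
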