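# cmrpop

Capture-mark-recapture survival modelling and count-based population
analysis for colonial birds, built around the demographic workflow of a
two-colony gull monitoring programme:

* **Encounter histories** (`cmrpop.encounter_data`): MARK-style `.inp` and
  tabular readers/writers, validation, and reduction to cohort-structured
  m-arrays (the sufficient statistic of the CJS likelihood).
* **Constrained CJS models** (`cmrpop.cjs_model`): a compact model grammar
  (`a(1).t/a(>=2)`, `a(1,2,3,>=4)+t`, covariates, colony effects) compiled
  to logit-scale design structures, multinomial m-array likelihood,
  quasi-Newton multistart fitting, Hessian-rank estimable-parameter counts,
  AICc and ΔAICc model-selection tables.
* **Covariate inference** (`cmrpop.covariate_inference`): analysis of
  deviance (ANODEV) with explained-variation r², automatic derivation of
  the constant/time reference models for a covariate model, covariate
  standardization and monotone (PCHIP) gap filling.
* **Goodness of fit** (`cmrpop.gof`): U-CARE-style TEST3.SR / TEST3.Sm /
  TEST2.CT / TEST2.CL contingency components with expected-count pooling,
  summed to a global chi-square test.
* **Population growth** (`cmrpop.population_growth`): breeding success,
  summary two-sample t tests, annual growth rates, and the log-growth
  regression estimator of the stochastic growth rate (handles census gaps,
  t-based confidence intervals).
* **Projection and immigration** (`cmrpop.projection_immigration`):
  female-based pre-breeding-census stage matrices with an age-specific
  recruitment schedule, dominant-eigenvalue growth, trajectory projection,
  and the marked-fraction immigration correction.
* **Synthetic data** (`cmrpop.synthetic_data`): seeded generators for
  encounter histories (age/time-structured survival and resighting,
  permanent emigration confounded with mortality), census series and
  productivity records, plus study-scale presets.
* **Pipeline** (`cmrpop.pipeline_cli`): end-to-end orchestration (resight
  structure selection → survival selection → ANODEV → GOF → growth →
  projection → immigration) from one YAML config, with a deterministic
  machine-readable report bundle.

## CLI

```sh
# fit a single model
cmrpop fit --histories colony.csv --survival "a(1).t/a(>=2)" --resight "t" \
    --covariate FISH=fish.txt --out fit.json

# analysis of deviance from three fit reports
cmrpop anodev --cst cst.json --cov cov.json --time time.json

# goodness of fit, growth, projection
cmrpop gof --histories colony.csv
cmrpop growth --census census.txt --alpha 0.05
cmrpop project --rates rates.yaml --years 10

# synthetic inputs
cmrpop simulate histories --config sim.yaml --seed 1 --out colony.csv

# whole study
cmrpop study run --config study.yaml --out report/
```

History files are plain text: tabular (`id,group,<year>,...` with 0/1
flags) or `.inp` lines such as `1100 1;` (the occasion years are always
given explicitly, e.g. `--occasions 1998,1999,2000,2001`). Covariate and
census files are 2-column `year value` text.

A study config names, per colony, the history file, the candidate
resighting and survival model grammars, and optional covariate files; plus
census/productivity files, vital rates for projection, and immigration
records. See `tests/test_pipeline_cli.py` for a complete working example.

## Model grammar

Tokens: `a(...)` age-class lists in years since marking (the last class
open-ended, `>=k`), `t` time, `col` colony, and uppercase covariate names.
`.` is interaction, `+` an additive effect, `/` separates independent
per-age-class structures. Examples:

| formula               | meaning                                         |
|-----------------------|-------------------------------------------------|
| `t`                   | one parameter per occasion                      |
| `a(1,2,>=3).t`        | full age × time interaction                     |
| `a(1,>=2)+t`          | age intercepts plus additive time               |
| `a(1).t/a(>=2)`       | time-varying first year, constant older         |
| `a(1).FISH/a(>=2)`    | first-year intercept + slope on FISH            |
| `a(1,>=2)+FISH`       | age intercepts plus one shared FISH slope       |
| `a(1).col.t/a(>=2).col` | colony × time first year, colony-specific older |

Within a `.`-product containing the age factor a covariate contributes an
intercept *and* a slope per categorical level combination; a bare `+COV`
term contributes a single shared slope. Covariates are standardized (zero
mean, unit population sd) before entering the design.
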