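# suscept

Moderated hierarchical regression for occupational-burnout cohorts, with
region-of-significance probing and classification of moderator-by-environment
interactions against three susceptibility models (diathesis stress,
differential susceptibility, vantage sensitivity).

The pipeline takes a per-subject table — demographics, four
job-characteristic scales (or their raw questionnaire items), three burnout
subscales, and a raw hair-cortisol concentration as a biological moderator —
and runs:

1. **Scoring** (`suscept.scoring`): weighted-sum JCQ scales (job control
   24–96, psychological demands 12–48, supports 4–16), MBI subscale means
   (1–7), Cronbach's alpha, base-10 log transform of the moderator, and a
   normality audit (small-sample skewness/kurtosis with closed-form SEs and
   a seeded Monte-Carlo Lilliefors KS test).
2. **EM imputation**: multivariate-normal expectation-maximization over the
   scale and outcome variables; the moderator is never imputed.
3. **Descriptives** (`suscept.descriptives`): pairwise Pearson correlations,
   one-way ANOVAs by department and shift, Harman single-factor screen,
   one-factor ML confirmatory factor analysis (chi2, GFI, CFI, TLI, RMSEA),
   and Meng/Steiger dependent-correlation comparisons.
4. **Moderation** (`suscept.moderation`): twelve four-step hierarchical
   regressions (4 environments x 3 outcomes): demographics, environment,
   moderator, interaction — with delta-R² F-change tests, dummy-coded
   demographics, centered predictors, tolerance/VIF diagnostics, and the
   final-model coefficient covariance.
5. **Probing & classification** (`suscept.probing`): simple slopes at
   moderator M±1SD, Johnson–Neyman region of significance on the
   environment axis over ±2 SD, crossover point, proportion-of-interaction
   (PoI) and proportion-affected (PA) indices, and pattern classification
   by which ends of the evaluation range show a significant group
   difference.

Because no subject-level data are deposited for the motivating study, a
first-class synthetic generator (`suscept.synthetic`) draws cohorts matching
the published marginals, 8x8 correlation structure, lognormal moderator, and
demographic proportions, with plantable interaction regimes (configurable
crossover location) so every stage is testable against known truth.

## CLI

```sh
# draw a synthetic cohort (bundled defaults) and write it as CSV
suscept simulate --seed 1 --out cohort.csv

# full pipeline from a config (or bundled synthetic defaults)
suscept analyze --config config.yaml --seed 1 --out report_dir
suscept analyze --seed 1 --out report_dir          # synthetic defaults

# probe every interaction regardless of significance
suscept probe --seed 1 --out report_dir

# re-render a structured report's classification section as text
suscept report --json report_dir/report.json --out rendered
```

A config YAML holds either `input_path` (delimited cohort table) or a
`synthetic_spec` block, plus `alpha`, `eval_range`, polarity declarations
and output options; see `src/suscept/data/default_spec.yaml` for the
bundled generator spec. Outputs are `report.json` (full precision,
byte-stable under a fixed seed), rounded CSV tables (regressions,
correlations, probes, plot data) and `run.log`.

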