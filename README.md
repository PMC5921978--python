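# gpselect

Counterfactual simulation of GP-trainee selection processes: how many
trainees would obtain GP Registration within three and five years
full-time-equivalent (FTE) training time under different ways of filling a
given number of training posts?

The pipeline mirrors a cohort analysis of UK GP-training applications:

1. **`gpselect.cohort`** — domain types, CSV I/O, exact GMC-identifier
   linkage of applications to training-performance records, eligibility
   filtering and the application-accounting summary.
2. **`gpselect.synth`** — a synthetic cohort generator. The original linked
   selection/performance dataset is confidential, so the generator produces
   applicant cohorts with the structure the analysis needs (scores and
   outcomes correlated through a latent aptitude) plus the missingness
   pattern of a historical cut-score selection: Stage 3 scores observed only
   above the cut, training outcomes only for appointed trainees. A complete
   truth table accompanies every cohort for validation.
3. **`gpselect.imputation`** — fully-conditional-specification (chained
   equations) multiple imputation of the selection-censored variables:
   logistic regression with posterior draws for binary variables, Bayesian
   linear regression + predictive mean matching for continuous ones,
   M completed datasets (default 10).
4. **`gpselect.processes`** — the four selection processes: random
   selection, the 2015 cut-score process (181 on each Stage 2 test plus a
   Stage 3 competency outcome, Rounds 1 then 2), ranking on Stage 2 totals
   only, and ranking on Stage 3 totals only.
5. **`gpselect.outcomes`** — FTE time arithmetic (out-of-programme time
   subtracted, less-than-full-time months scaled by 1/1.67), 3/5-year
   registration counts, pooling across imputations into a results table, and
   the derived analytics (registration rates, extension proportions,
   marginal-cohort statistics, process comparisons). The published pooled
   table ships as a fixture (`gpselect/data/table4.csv`) for the analytics.

## CLI

```sh
gpselect generate --params params.yaml --seed 1 --out-dir data/
gpselect impute   --in-dir data/ --m 10 --iterations 10 --seed 1 --out-dir imputed/
gpselect simulate --in-dir imputed/ --targets 1000,1500,2000,2500,3000,3500,4000 \
                  --seed 1 --out results.csv
gpselect report   --results results.csv --out analytics.json --plot fig1.png
```

`generate` writes `applications.csv`, `performance.csv` and `truth.csv`;
`impute` writes one completed CSV per imputation plus a provenance JSON with
convergence traces; `simulate` writes the pooled results table;
`report` derives the percentage analytics (and optionally a
registrations-vs-posts-filled figure).

## CSV schemas

UTF-8, comma-separated, header row required, empty cell = missing value.
Dates are ISO-8601 and truncated to month resolution internally.

`applications.csv`: `gmc_id`, `year`, `round` (R1/R2; R3 is recoded to R2 on
load), `cps_score`, `pd_score`, `stage3_total`, `stage3_competent`,
`withdrew`, `offer_accepted`, `passed_stage1`, `took_stage2`, `gender`
(F/M), `ethnicity_bme`, `uk_pmq`. Booleans are `true`/`false`.

`performance.csv`: `gmc_id`, `start_date`, `ltft_months`, `oop_months`,
`arcp4`, `registration_date` (empty if not registered), `censor_date`.

Rows that fail to parse are collected into a row-indexed rejects report
rather than silently dropped; missing mandatory columns raise a schema
error.
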