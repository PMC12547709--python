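# ttegast

Time-to-event prediction of **gastrostomy requirement in ALS** from
routine clinical covariates.

In amyotrophic lateral sclerosis, gastrostomy (feeding-tube placement)
should be considered once a patient reaches **5% weight loss from
diagnosis**; placing it late raises periprocedural risk and rarely
stabilises weight. This package predicts *when* an individual patient
will reach that threshold, giving clinicians lead time. It is aimed at
biostatisticians and clinical ML researchers working with longitudinal
ALS registry data (weights, ALSFRS-R, FVC, onset characteristics).

## What is inside

- **Outcome engine** — derives the survival target `T` = first time the
  weight series crosses `0.95 ×` baseline (linear interpolation between
  visits), after the published cleaning rules: drop patients with
  gastrostomy within 30 days of diagnosis or first weight beyond 3
  months, delete post-gastrostomy measurements, and delete points whose
  rate of change `|Δkg/Δday|` exceeds the cohort's 95th percentile.
- **Survival models** — discrete-time neural models (logistic hazard
  `h_j(x) = σ(f_j(x))` with masked Bernoulli likelihood; PMF; MTLR) on a
  quantile time grid, trained with AdamW (decoupled weight decay) under
  cosine warm restarts; and Royston–Parmar flexible parametric splines
  `g(S(t|x)) = s(ln t; γ) + β·x` on the odds or hazard scale, with
  restricted cubic `s` (two internal knots is the reference
  configuration).
- **Metrics** — median absolute error (uncensored subjects only, in
  months), fixed-horizon AUROC at 12 months, tie-adjusted concordance;
  the Weighted Normalised Sum tuning composite (MAE weighted 3:1 over
  AUROC) and TOPSIS for final model selection.
- **Tuning** — nested cross-validation (outer 80/20, ten inner 80/20
  rounds with median-ensembled survival curves) around a two-stage
  search: grid over scheme/architecture, then a tree-structured Parzen
  estimator over the remaining hyperparameters.
- **Imputation** — MissForest-style iterative random forests (ordered by
  missingness, classic stopping rule, mean of 10 rounds) plus the
  leakage-free *transductive* protocol that completes one external test
  patient at a time against the pre-imputed training table.
- **Interpretation** — replica permutation importance (10 covariates ×
  5 permutations) and the 187,500-row full-factorial quintile grid with
  per-pair slope, R² and difference-ratio interaction statistics.
- **Synthetic cohorts** — a log-logistic accelerated-failure-time
  generator whose weight trajectories cross the 5% threshold exactly at
  the true event time, with censoring, visit jitter, measurement noise,
  implausible spikes and MCAR/MAR missingness; presets `linear-po`,
  `interaction-heavy`, `precision-like`.

## Worked example

```bash
python examples/02_fit_and_evaluate.py
```

prints, for an interaction-heavy synthetic cohort (n = 1200, 900
training / 300 test):

```
spline (odds, 2 knots)   MAE 3.80 months | AUROC@12mo 0.830 | concordance 0.781
logistic-hazard net      MAE 3.78 months | AUROC@12mo 0.847 | concordance 0.785
```

MAE is the median gap between predicted and observed time to 5% weight
loss among patients who reached it; AUROC@12mo asks how well the model
separates patients who do and do not reach the threshold within a year;
concordance measures risk ranking across all usable patient pairs. When
the generating process contains covariate interactions, the non-linear
network edges out the additive spline on discrimination.

The other examples walk the remaining capabilities: cohort simulation
and outcome derivation (`01`), imputation including the
external-validation protocol (`03`), hyperparameter search (`04`), and
model interrogation (`05`). A thin CLI mirrors the stages:
`tte simulate`, `tte validate`, `tte derive`, `tte impute`,
`tte evaluate`, `tte predict`.

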