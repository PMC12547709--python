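# Methods

## Outcome definition and cleaning

The event is the first time, in days from diagnosis (day 0), at which a
patient's weight reaches 95% of baseline — the accepted objective
indicator that gastrostomy should be considered. Baseline is the
earliest surviving measurement, which must lie within 91 days of
diagnosis ("three months" at 30.44 days/month, the package-wide month
length). The crossing time is obtained by linear interpolation between
the bracketing measurements; a measurement exactly at threshold dates
the event at that visit. Patients who never cross are censored at their
last weight day or recorded end of follow-up, whichever is later.
Censored patients are excluded from absolute-error evaluation but kept
for concordance and horizon AUROC.

Cleaning applies four rules, in order:

1. patients with gastrostomy ≤ 30 days from diagnosis are dropped
   (they needed the intervention at baseline; prediction is moot);
2. patients whose first weight is > 91 days from diagnosis are dropped;
3. weight points on or after the gastrostomy day are deleted
   (gastrostomy stabilises weight and would contaminate the trajectory);
4. points whose incoming rate `|Δkg/Δday|` exceeds the cohort-wide 95th
   percentile of inter-measurement rates are deleted; same-day duplicate
   measurements have infinite rate and always go. The filter uses
   absolute rates by default (`absolute_rates=False` switches to signed)
   and runs in a single pass: the percentile is computed once, stored in
   the cleaned table's metadata, and reused if cleaning is re-applied,
   making the operation idempotent.

Note the 95th-percentile rule removes the fastest 5% of observed
changes *by construction*, even in noise-free data; it trades a small
loss of genuine rapid decliners for robustness to transcription errors.

Derived covariates: the ALSFRS-R slope assumes linear decline from the
healthy maximum of 48 at symptom onset to the score at diagnosis over
the diagnostic delay, stored as a non-negative decline rate in
points/month. The 6-month longitudinal feature takes the measurement
nearest day 183 within days 122–243 (ties to the earlier visit) and
converts it to kg/month from baseline.

## Survival models

**Discrete-time networks.** Follow-up is discretised by a
`TimeGrid` (default: quantile bins of the event times, deduplicated;
bin count is a tuned hyperparameter). A small fully-connected network
(ReLU, optional batch normalisation and dropout) maps encoded
covariates to per-bin quantities:

- *logistic hazard*: outputs are per-bin conditional-event logits;
  the likelihood for a subject in bin `k` is the usual censored
  Bernoulli product, `−ln h_k − Σ_{j<k} ln(1−h_j)` for events and
  `−Σ_{j≤k} ln(1−h_j)` for subjects censored in bin `k` (censoring
  contributes through its bin inclusive);
- *pmf*: `m+1` outputs softmax to an event-time mass function with an
  explicit beyond-grid bin; censored subjects contribute the tail mass;
- *mtlr*: the same pmf likelihood under a cumulative parametrisation
  (softmax of reverse-cumulative sums), so pmf and mtlr span the same
  model family with different geometry.

The mapping `p_k = h_k Π_{j<k}(1−h_j)` identifies the logistic-hazard
and pmf likelihoods exactly; the test suite checks the identity to
1e-10. Five further scheme names from the wider deep time-to-event
family are registered but deliberately unimplemented so that
configurations naming them fail loudly rather than silently fall back.

Training uses AdamW — Adam with decoupled weight decay (decay applied
to weight matrices only) — under a cosine-annealed learning rate with
warm restarts (period 25 epochs, doubling). Early stopping monitors a
held-out split's NLL (15% internal by default, or the explicit inner
validation fold during nested CV). Everything is driven by a single
`numpy` Generator seed; two fits with the same seed produce
bit-identical loss trajectories. Covariate encoding (z-scored
continuous, reference-dropped one-hot) is fitted on training folds
only.

**Flexible parametric splines.** The Royston–Parmar model writes a
transform of survival as a restricted cubic spline in log time plus a
linear predictor: on the odds scale `logit F(t|x) = s(ln t; γ) + β·x`
(exactly the log-logistic family when `s` is linear), on the hazard
scale `ln H(t|x) = s(ln t) + β·x` (exactly Weibull when linear).
Boundary knots sit at the min/max uncensored log-times, internal knots
at event-time centiles (two knots → 33rd/67th). The right-censored
log-likelihood is maximised by L-BFGS with analytic gradients;
monotonicity of `s` is maintained by a soft quadratic barrier on
`s′(ln t)` over a 101-point check grid spanning the knots ± 0.5, and
verified after the fit (violation raises). Initialisation comes from a
one-parameter log-logistic/Weibull fit (lifelines), β = 0. One test
cross-checks the fitted covariate coefficient against R `flexsurv` on
the same data.

**Point predictions.** The point time read from a survival curve is the
interpolated median survival time; when the curve never reaches 0.5 on
its grid, the restricted mean survival time (trapezoid rule on the
grid, with S(0)=1 prepended) is used instead and the policy is recorded.
The median is the natural companion to a median-based error criterion;
a mean-time policy would be a one-line change. Fold ensembles take the
element-wise median of survival curves (an order statistic, so
monotonicity is preserved) and the median of point times.

## Metrics and combiners

MAE is the *median* absolute difference between predicted and observed
event times over uncensored subjects, reported in months (days /
30.44). AUROC at a horizon (default 365 days) labels positives as
events by the horizon and negatives as subjects — censored or not —
still event-free at the horizon; subjects censored before the horizon
are unlabelable and excluded (inverse-probability weighting was
considered and left out: the comparison protocols here never need it).
Scores tie-break with 0.5 credit (Mann–Whitney). Concordance uses point
predicted times; usable pairs are `(i, j)` with `t_i < t_j` and subject
`i` uncensored, or tied times with exactly one event (the event subject
must rank earlier); tied predictions earn 0.5. Both rank metrics are
validated against O(n²) pair-counting oracles to 1e-12.

The tuning composite (Weighted Normalised Sum) min-max normalises MAE
(flipped) and AUROC across the current trial set and combines them
3:1; a criterion constant across trials is set to 0.5 (it carries no
preference). Final selection uses TOPSIS with equal weights on MAE,
12-month AUROC and concordance: vector-normalised, weighted columns;
closeness = d⁻/(d⁺+d⁻) to the per-column ideal/anti-ideal; ties break
by row order with a warning.

## Tuning protocol

Data are split once into an outer 80% pool and 20% test set; each of
ten inner rounds independently resplits the pool 80/20. A trial trains
one network per inner round (inner validation for early stopping),
median-ensembles the ten survival curves on the outer test set, and is
scored there. The search runs in two stages: a grid over scheme ×
layer configuration at mid-range defaults, then a tree-structured
Parzen estimator (quantile split γ=0.25, per-parameter KDEs, 24
candidates, log-scaled where declared) over learning rate, weight
decay, dropout, bin count and batch size with the architecture frozen.
Composites are recomputed over the full history as trials accrue. After
the budget (default 60 trials), TOPSIS ranks the ten best-composite
trials and the winner is refit on the full outer pool with the
warm-restart optimiser. A trial with three or more failed folds is
marked failed and receives the worst composite. Outer-test subjects
never enter encoding, imputation, training or proposal; `Splits.audit`
enforces the id-level separation.

## Imputation

The iterative random-forest imputer initialises missing cells at the
observed mean/mode, then sweeps variables in order of increasing
missingness, fitting a random forest (sklearn, 100 trees by default) on
the rows observed for that variable with all other variables as
predictors, and replacing its missing cells with predictions. Sweeps
repeat until the normalised change (sum of squared differences for
continuous, disagreement count for categorical) increases, at which
point the previous iterate is returned. Final values average 10
independent rounds (majority vote with lowest-index tie-break for
categorical). Observed cells are never altered, and the audit test
checks that bit-exactly. The outcome variable can optionally join the
predictor set as the *uncensored* event time; censored rows carry the
observed mean for that predictor.

The transductive path serves external validation without leakage: per-
variable forests are fitted once on the fully observed (pre-imputed)
training table, then each test patient is completed independently —
initialise at training means, sweep the patient's missing cells two to
three times, average rounds. No test patient sees another, and the test
row carries no outcome column.

The masking harness removes `n` observed cells per covariate (never
more than two from one patient), re-imputes, and returns true/imputed
pairs per covariate and round; a flag switches to the variant that
removes one covariate value from each of `n` patients.

## Interpretation

Permutation importance permutes one covariate at a time in a full
replica of the data (default: 10 covariates × 5 permutations — 150,000
replica rows for a 3000-patient cohort), re-scores the model, and
reports the percentage change of each metric oriented so that positive
means improvement (for MAE, a decrease), with mean ± SEM over the
repetitions. A repetition whose metric becomes undefined (single-class
AUROC after permutation) is dropped with a warning.

The factorial grid crosses five quintile representatives of each
numeric covariate — the 10th/30th/50th/70th/90th percentiles, i.e. the
midpoints of the quintile intervals — with both binary levels and all
onset sites, holding the cohort label at its reference level:
5⁶·2·2·3 = 187,500 rows for the standard ten covariates. For a pair
(A numeric, B any), the mean prediction as a function of A's levels is
traced per level of B; each trace gets an OLS line (slope, R²), and the
difference ratio h1/h2 compares the spread across traces at A's lowest
level with the spread at its highest. Purely additive predictions give
parallel traces (ratio 1, R² 1 — asserted exactly in tests); a
multiplicative term fans them. Constant predictions are flagged
degenerate (R² defined as 1, ratio 1).

## Synthetic cohorts

Event times follow a log-logistic AFT model
`ln T* = μ + β·z + Σ θ_ab z_a z_b + σ ε` with standard-logistic ε,
μ = ln 300 days and σ = 0.4, over the ten ALS covariates standardised
by declared generator constants. Without interactions this is exactly a
proportional-odds model, so the odds-scale spline is correctly
specified and each coefficient has the closed form `−β/(σ·scale)` —
the basis of the parameter-recovery tests. The observable chain is
closed: weight at diagnosis is measured at day 0 and declines linearly
so the 5% threshold is crossed exactly at `T*`; visits occur at day 0,
a routine day-14 follow-up, then every ~60 ± 15 days, with an
end-of-study measurement at the administrative censoring day (uniform
120–1000 days in the study-shaped preset). Measurement noise, spike
outliers, a gastrostomy date `T*` + 2–8 weeks for 70% of events, and
missingness (MCAR, or MAR with masking probability increasing in the
true ALSFRS-R slope) are layered on top. Weights are floored at 30% of
baseline (cachexia bound), far below the 5% threshold, so the
noise-free closed loop recovers `T*` to floating-point precision.

In the study-shaped (`precision-like`) preset, premorbid weight is
load-bearing by design: the pre-diagnostic weight-loss fraction
`(premorbid − weight_dx)/premorbid` — computable only when both
weights are known — is a strong driver of event time (β = −0.5 per
0.045 loss-fraction SD), and the loss fraction itself tracks observed
progression markers (ALSFRS-R slope, bulbar onset), so a forest can
reconstruct a missing premorbid weight from the rest of the record.
This encodes the clinical mechanism that motivates imputing premorbid
weight at all; premorbid weight is 10% missing (MAR on progression) in
the cohort, and the external-validation condition — a validation subset
lacking it almost entirely — is produced by masking ~95% of the
validation rows.

Effect sizes (0.3–0.5 SD) and, in the recovery preset, balanced
categorical level frequencies and independent covariates were chosen so
that every coefficient is estimable at the preset sizes; the
interaction-heavy preset plants three strong multiplicative terms. The
generator emulates structure, not numbers: it makes no attempt to match
any real registry's marginal distributions, covariance, visit politics
or consent-driven missingness, so passing tests demonstrate that the
machinery is correct and that qualitative orderings (imputation beats
mean substitution; a non-linear model wins under interactions) hold
under the stated mechanisms — not that real-cohort performance figures
transfer.

## Problem sizes and numerical choices

Test and reproduction runs use deliberately modest sizes chosen as the
smallest that leave the checked effects well out of sampling noise:
spline recovery at n = 5000 × 10 seeds; the imputation comparison at
n = 1400 (900 train / 500 validation) × 10 seeds with 30-tree forests
and 2 imputation rounds; nested-CV trials at n = 400–1200 with
single-hidden-layer networks; permutation replicas at the full n = 3000.
Tolerances: oracle equivalences at 1e-12 (pair counting) and 1e-9/1e-10
(combiners, likelihood identities); recovery criteria at 5–10% relative
error; directional orderings at ≥ 8/10 or ≥ 7/10 seeds. Quantile
computations use numpy's default linear interpolation. Hazards/probs are
clipped away from 0/1 only inside log-likelihoods (1e-300 floors);
network divergence reverts to the last checkpoint and flags the fit.

## Known limitations

- No competing risks (death before gastrostomy is treated as
  censoring) and no time-varying covariates inside the models; the
  6-month weight information enters as baseline-style features.
- The 95th-percentile outlier rule is one-pass and cohort-global; a
  per-patient robust filter would behave differently in tiny cohorts.
- TPE treats hyperparameters independently (no joint KDE), and the
  search is single-machine, sequential.
- The spline's monotonicity barrier is soft; pathological datasets
  could in principle stall the optimiser inside the infeasible region,
  which is why the post-fit check raises rather than warns.
- Multiple-imputation variance (Rubin's rules) is out of scope; rounds
  are averaged into point imputations by design.
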