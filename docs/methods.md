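# Methods

## The model of instability

Let a *development procedure* be everything that turns a dataset into a
risk model: the candidate predictor set, the estimator, and its tuning
scheme. Applied to a development cohort of $n$ individuals with binary
outcome $y_i$ and predictors $x_i$, it yields a model with predicted risks
$\hat p_i$. The instability question is epistemic: how different would
$\hat p_i$ be had the procedure been applied to another size-$n$ sample
from the same population? This is distinct from aleatoric outcome noise —
a perfectly stable model can still have low $R^2$.

The bootstrap approximates the sampling distribution of the *whole
procedure*: each replicate draws $n$ individuals with replacement,
re-runs the procedure end to end (the penalty is re-tuned from scratch in
every replicate — freezing it would understate instability from the
tuning step), and applies the replicate model to the original cohort. The
$n \times B$ prediction matrix is the estimated multiverse. Summaries:

- per individual: MAPE (mean |bootstrap − original| prediction, plus the
  variance of those absolute errors), percentile intervals, and the
  classification instability index at each decision threshold;
- per bootstrap model: c-statistic on the original outcomes, net benefit
  at each threshold, and a smoothed calibration curve;
- optional: MAPE summaries within subgroups (fairness), and a learning
  curve of MAPE against development sample size.

Assumptions worth stating: the development sample must represent the
target population (bootstrapping a small or skewed sample underestimates
population-level instability); the outcome is binary and complete-case
(rows with missing values are rejected at load rather than imputed, since
imputation would itself belong inside the replicated procedure); and
instability is assessed for the development population only — external
validation is a different exercise.

## Development procedure

The built-in procedure is lasso-penalized logistic regression:

- predictors are standardized internally (mean 0, SD 1 on the fitting
  sample) so the L1 penalty treats them symmetrically; coefficients are
  reported back-transformed to the original scale, with zeros marking
  dropped predictors;
- the penalty $\lambda$ (objective
  $\tfrac1n\sum_i \text{deviance}_i + \lambda\lVert\beta\rVert_1$,
  intercept unpenalized) is selected by stratified k-fold
  cross-validation (default $k=10$, capped at the minority-class count in
  rare-event resamples) minimizing out-of-fold deviance, ties broken
  toward the larger penalty;
- the default grid is data-dependent, as is standard for the lasso:
  13 log-spaced values from $\lambda_{\max}$ (the smallest penalty that
  zeroes every coefficient, $\max_j |z_j^\top(y-\bar y)|/n$) down to
  $10^{-3}\lambda_{\max}$, recomputed inside every bootstrap sample.
  Explicit grids are supported, including a single fixed penalty and the
  unpenalized limit `penalty_grid=(0,)`;
- fold assignment is seeded from the per-fit seed, so every bootstrap
  replicate re-tunes honestly and the whole analysis is reproducible
  bit-for-bit from one master seed.

The penalized fits go through a coordinate-descent solver written for this
package (`_lasso_path.py`): an IRLS outer loop around cyclic
soft-thresholding updates, warm-started along the descending penalty path,
with working probabilities clipped to $[10^{-5}, 1-10^{-5}]$ and the
numerical core JIT-compiled. The engine re-runs the full cross-validated
tuning inside every bootstrap replicate — hundreds of thousands of small
fits per analysis — so each path fit must stay in the sub-millisecond
range. The solver follows the usual convention of leaving the intercept
unpenalized, and the test suite verifies it against two independent
optimizers of the same objective (statsmodels' L1 `Logit` and, in the
development records, R's `glmnet`, agreement ~1e-7) as well as the
unpenalized maximum-likelihood limit. The unpenalized route
(`penalty_grid=(0,)`) uses scikit-learn's lbfgs fit directly.

Alternative development strategies plug in via the
`DevelopmentProcedure` contract (a `develop(cohort, seed) -> FittedModel`
that must be deterministic given its seed and self-contained).

## Synthetic cohort generator

`gusto_like_spec()` emulates the kind of development data these analyses
are run on: an acute myocardial infarction trial cohort with binary
30-day mortality at ~7% prevalence and eight candidate predictors —
sex (Bernoulli 0.25), age, history of hypertension (0.38), hypotension
(0.08), tachycardia (0.32), previous MI (0.17), ST elevation (0.37), and
systolic blood pressure. The two continuous predictors are standardized
at generation, so their coefficients are per-SD. Outcomes are drawn from
a known logistic model with coefficients
(0.35, 1.00, 0.10, 0.80, 0.45, 0.40, 0.30, −0.60) and intercept −3.70;
the intercept was calibrated once by Monte-Carlo search (n = 4×10⁵) to an
implied prevalence of 0.070, which also puts the true-model c-statistic
at ≈ 0.80, and then frozen. The generating truth is retained on the
cohort object for truth-known tests.

What the generator does *not* emulate: predictor correlation (real
vitals and history flags are correlated), non-linear or interaction
effects, measurement error, and missingness. Passing tests on this
generator therefore demonstrate that the machinery is correct and that
the sample-size behaviour of instability is as theory predicts — not
that any particular real dataset is stable.

## Numerical choices

- **Percentiles** (instability intervals, c-statistic and net-benefit
  spreads, MAPE summaries): empirical quantiles with linear interpolation
  between order statistics, the numpy `linear` rule. The test oracles use
  the same rule.
- **Classification convention**: risk ≥ threshold is positive; ties at
  the threshold classify positive.
- **c-statistic**: midrank (Mann-Whitney) identity, ties between an
  event and a non-event count one half.
- **Calibration smoother**: binomial GLM of the outcome on a natural
  cubic spline basis (default 4 df) of logit(predicted risk), evaluated
  on 100 equally spaced points over the central 99% of the predictions —
  no extrapolation beyond support. Chosen over kernel loess for tail
  stability and speed across hundreds of bootstrap curves; a loess
  smoother is available via `SmootherConfig(kind="lowess")` (with
  robustness iterations disabled, which would otherwise treat the
  minority class of a binary outcome as outliers).
- **Degenerate bootstrap samples** (single-class outcome, failed fit):
  redrawn with a fresh pre-derived seed, logged, capped at 50 per run;
  dropping columns would bias B downward. Degenerate calibration curves
  are skipped with a count.
- **Seeding**: one master seed per run; children for generation,
  subsampling, the original fit and every bootstrap column (plus the
  redraw pool) are pre-derived via `numpy.random.SeedSequence.spawn`, so
  parallel execution (`n_jobs`) is bitwise identical to sequential.
- **Memory**: the n × B matrix is materialized (40,830 × 500 doubles
  ≈ 163 MB); `run_bootstrap(keep_models=False)` drops the per-replicate
  coefficient records when only predictions are needed.
- **Prediction clipping**: predicted risks are clipped to
  $[10^{-12}, 1-10^{-12}]$; the logistic saturates in double precision
  beyond |linear predictor| ≈ 37 and downstream contracts need open-(0,1)
  values.

## Problem sizes

The test suite and `scripts/acceptance.py` exercise the pipeline at
development sizes 200–4000 with B = 100–200 (plus single fits at
n = 50,000 and calibration checks at n = 10⁵), which reproduces the
qualitative large-versus-small contrast — small development samples give
several-fold larger mean MAPE, wider calibration fans and higher
classification instability — at desk scale. The full-scale real-data
analysis (n = 40,830, B = 500) runs through the same code path via
`scripts/reproduce_gusto.py`.

## Known limitations

- Only binary outcomes; no survival or continuous endpoints.
- One development procedure ships built-in; ensembles, trees and
  "researcher multiverse" randomization of the modelling strategy itself
  are out of scope (the procedure contract accepts user implementations).
- The real-data column mapping for the hypertension/hypotension/
  tachycardia flags is recorded and overridable but not authoritative,
  and the published analysis's tuning scheme and sub-sample seed are
  unknown — real-data reproduction is expected in distribution, not
  digit-for-digit.
- Net benefit is computed at fixed thresholds; no decision-curve sweep.
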