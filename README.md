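# pmstability

Bootstrap instability analysis for clinical prediction models.

A clinical prediction model maps an individual's predictor values to an
estimated outcome risk. The model that gets published is, however, only one
draw from a *multiverse* of models: had the same development procedure been
applied to a different same-size sample from the same target population, a
different model — with different predictions for the same individual —
would have resulted. Whole-sample summaries such as the c-statistic can
look excellent while individual predictions swing wildly across that
multiverse, which matters whenever a prediction drives a treatment decision
for a person.

`pmstability` approximates the multiverse by bootstrap resampling:

1. develop the model on the development cohort and predict each
   individual's risk $\hat p_i$;
2. draw a bootstrap sample of size $n$ with replacement;
3. re-run the *entire* development procedure (including tuning) in the
   bootstrap sample;
4. apply the resulting model to the original cohort, giving $\hat p_{bi}$;
5. repeat for $b = 1, \dots, B$ (at least 200 recommended);
6. summarise the $n \times B$ matrix of predictions.

It reports, per individual, the **mean absolute prediction error**

$$\mathrm{MAPE}_i = \frac{1}{B}\sum_{b=1}^{B}\left|\hat p_{bi} - \hat p_i\right|,$$

2.5th–97.5th percentile **prediction instability intervals**, and the
**classification instability index**

$$\mathrm{CII}_i(t) = \frac{1}{B}\sum_{b=1}^{B}
\mathbb{1}\left[(\hat p_{bi} \ge t) \ne (\hat p_i \ge t)\right]$$

at a decision threshold $t$; and, per bootstrap model, the c-statistic,
the net benefit $\mathrm{TP}/n - (\mathrm{FP}/n)\,t/(1-t)$, and a smoothed
calibration curve on the original sample. Three standard plots come with
these: the prediction instability scatter, the classification instability
plot, and the calibration instability overlay.

The built-in development procedure is logistic regression with a lasso
penalty tuned by 10-fold cross-validation (the usual penalized development
strategy for risk models); any other procedure can be plugged in by
implementing the `DevelopmentProcedure` contract.

## Worked example

```python
from pmstability import (
    InstabilityAnalysis, generate_synthetic_cohort, gusto_like_spec,
)

# synthetic acute-MI cohort: 8 predictors, ~7% 30-day mortality
cohort = generate_synthetic_cohort(gusto_like_spec(n=2000, seed=1))
results = InstabilityAnalysis(cohort).fit(B=200, seed=7)
print(results.summary())
```

```
Prediction model instability analysis (bootstrap multiverse)
==============================================================
Development data: n = 2000, events = 154 (7.7%)
Procedure: lasso_logistic, 8 candidate predictors (~19 events per parameter)
Bootstrap replicates: B = 200 (redraws: 0), seed = 7

Original model
  retained predictors : 7/8
  c-statistic         : 0.819
  Nagelkerke R2       : 0.241

Individual-level prediction instability (MAPE)
  mean   : 0.0131
  median : 0.0078
  90th % : 0.0319
  max    : 0.0827

Bootstrap-model c-statistic on the original sample
  2.5th-97.5th percentile: 0.810 to 0.819

Decision threshold t = 0.1
  classification instability index: mean 0.046, max 0.615
  net benefit (original model)    : 0.0322
  net benefit 2.5th-97.5th %      : 0.0270 to 0.0323

Calibration instability (200 bootstrap curves, 0 skipped)
  max per-grid-point curve spread: 0.2503
```

Reading this: the model discriminates well (c-statistic 0.82) and the
c-statistic is stable across the multiverse (0.810–0.819) — yet one
individual's risk estimate moves by 0.083 on average across bootstrap
models, and some individuals near the 0.1 decision threshold would be
classified differently by most alternative models (max CII 0.62). With
only ~19 events per candidate predictor, individual-level instability is
substantial even though whole-sample performance looks fine. The same
analysis at larger `n` shows all instability summaries shrinking.

`results.save(out_dir)` writes per-individual and per-bootstrap CSV tables
plus a JSON run summary; `results.plot_prediction_instability(...)`,
`.plot_classification_instability(...)` and
`.plot_calibration_instability(...)` render the three plots (SVG + PNG).

The same pipeline is available from the shell:

```bash
pmstability simulate --n 2000 --seed 1 --out cohort.csv
pmstability run --data cohort.csv --outcome outcome --b 200 --seed 7 \
    --threshold 0.1 --out report/
pmstability run --synthetic --n 2000 --b 200 --seed 7 --out report2/
```

Runs are deterministic given `--seed`, and every figure's underlying
numbers are also written as CSV.

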