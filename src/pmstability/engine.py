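"""Bootstrap instability engine.

This is the core procedure: replay the model-development process across B
bootstrap resamples of the development cohort, apply every resulting model
back to the *original* cohort, and summarise, per individual, how much the
predicted risk moves across this multiverse of models.

Outline of the procedure:

1. develop the model on the original cohort and predict each individual's
   risk p̂_i;
2. draw a bootstrap sample of size n with replacement;
3. re-run the identical development process (including penalty tuning) in
   the bootstrap sample;
4. predict with the bootstrap model on the original cohort, giving p̂_bi;
5. repeat for b = 1..B (at least 200 recommended);
6. store the n×B matrix of predictions alongside p̂_i;
7. summarise: per-individual MAPE, percentile intervals, classification
   instability; per-bootstrap-model c-statistic, net benefit, calibration
   curve.

All randomness flows from one master seed via ``numpy.random.SeedSequence``
spawning, so the whole report is bitwise reproducible and per-column seeds
are pre-derived (parallel execution gives identical results to sequential).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import Cohort, subsample_cohort
from .development import DevelopmentProcedure, FittedModel
from .exceptions import (
    DegenerateCurveError,
    FitError,
    InstabilityInfeasibleError,
    ValidationError,
)
from .metrics import (
    CalibrationCurve,
    SmootherConfig,
    c_statistic,
    calibration_curve,
    net_benefit,
)

logger = logging.getLogger(__name__)

#: minimum recommended number of bootstrap replicates
RECOMMENDED_MIN_B = 200

#: empirical percentiles use linear interpolation between order statistics
PERCENTILE_METHOD = "linear"


@dataclass(frozen=True)
class BootstrapPredictions:
    """The multiverse of predictions for one development cohort.

    ``original[i]`` is the original model's predicted risk p̂_i;
    ``multiverse[i, b]`` is the prediction p̂_bi from the model developed in
    bootstrap sample b, applied to original-cohort individual i.
    """

    original: np.ndarray
    multiverse: np.ndarray
    original_model: FittedModel
    bootstrap_models: tuple[FittedModel, ...] = field(repr=False, default=())
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "original", np.asarray(self.original, dtype=float))
        object.__setattr__(self, "multiverse", np.asarray(self.multiverse, dtype=float))
        if self.multiverse.ndim != 2 or self.multiverse.shape[0] != len(self.original):
            raise ValidationError("multiverse must be an n x B matrix")
        if self.B < 1:
            raise ValidationError("at least one bootstrap replicate required")
        for arr, label in ((self.original, "original"), (self.multiverse, "bootstrap")):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValidationError(f"{label} predictions must lie in (0,1)")

    @property
    def n(self) -> int:
        return len(self.original)

    @property
    def B(self) -> int:
        return self.multiverse.shape[1]


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _one_bootstrap_column(
    cohort: Cohort, procedure: DevelopmentProcedure, child: np.random.SeedSequence
):
    """Draw one bootstrap sample, redevelop the model, predict on the original.

    Returns (predictions, model) or None when the resample is degenerate
    (single-class outcome or failed fit) — the caller redraws.
    """
    draw_ss, fit_ss = child.spawn(2)
    rng = np.random.default_rng(draw_ss)
    idx = rng.integers(0, cohort.n, cohort.n)
    sample = cohort.take(idx, new_ids=True)
    if not sample.has_both_classes:
        return None
    try:
        model = procedure.develop(sample, _derive_seed(fit_ss))
    except FitError as e:
        logger.debug("bootstrap fit failed: %s", e)
        return None
    return model.predict(cohort), model


def run_bootstrap(
    cohort: Cohort,
    procedure: DevelopmentProcedure,
    B: int,
    seed: int,
    max_redraws: int = 50,
    keep_models: bool = True,
    n_jobs: int = 1,
) -> BootstrapPredictions:
    """Steps 1-6 of the instability procedure: build the n×B multiverse.

    Each bootstrap sample is drawn with replacement at size exactly n, the
    development procedure is fully re-run (including tuning) in it, and the
    resulting model predicts on the original cohort. Degenerate resamples
    (no events, or a failed fit) are redrawn with a fresh derived seed and a
    logged count, capped at ``max_redraws`` per run.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if B < RECOMMENDED_MIN_B:
        warnings.warn(
            f"B={B} is below the recommended minimum of {RECOMMENDED_MIN_B} "
            "bootstrap replicates; instability summaries will be noisy",
            stacklevel=2,
        )
    if not cohort.has_both_classes:
        raise ValidationError("cohort must contain both outcome classes")

    master = np.random.SeedSequence(seed)
    original_ss, columns_ss = master.spawn(2)
    # pre-derive every child seed (primary + redraw pool) so that parallel
    # and sequential execution agree bitwise
    children = columns_ss.spawn(B + max_redraws)

    original_model = procedure.develop(cohort, _derive_seed(original_ss))
    original = original_model.predict(cohort)

    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_bootstrap_column)(cohort, procedure, children[b])
        for b in range(B)
    )
    redraws = 0
    next_spare = B
    for b in range(B):
        while results[b] is None:
            redraws += 1
            if redraws > max_redraws:
                raise InstabilityInfeasibleError(
                    f"exceeded {max_redraws} degenerate-resample redraws; the "
                    "cohort is too small or too event-sparse for this procedure"
                )
            results[b] = _one_bootstrap_column(
                cohort, procedure, children[next_spare]
            )
            next_spare += 1
    if redraws:
        logger.info("run_bootstrap: %d degenerate resample(s) redrawn", redraws)

    multiverse = np.column_stack([r[0] for r in results])
    models = tuple(r[1] for r in results) if keep_models else ()
    return BootstrapPredictions(
        original=original,
        multiverse=multiverse,
        original_model=original_model,
        bootstrap_models=models,
        provenance={
            "seed": seed,
            "B": B,
            "redraws": redraws,
            "procedure": procedure.describe(),
            "percentile_method": PERCENTILE_METHOD,
        },
    )


# ---------------------------------------------------------------------------
# Per-individual instability statistics
# ---------------------------------------------------------------------------


def mape_per_individual(
    preds: BootstrapPredictions, with_variance: bool = False
):
    """Mean absolute prediction error per individual.

    MAPE_i = (1/B) Σ_b |p̂_bi − p̂_i|: the average absolute difference
    between an individual's bootstrap-model predictions and their original
    prediction. With ``with_variance=True`` also returns the per-individual
    variance of the absolute errors.
    """
    abs_err = np.abs(preds.multiverse - preds.original[:, None])
    mape = abs_err.mean(axis=1)
    if with_variance:
        return mape, abs_err.var(axis=1)
    return mape


def prediction_intervals(
    preds: BootstrapPredictions, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual empirical percentile bounds of the B predictions.

    For level 0.95 these are the 2.5th and 97.5th percentiles of each
    individual's bootstrap predictions, with linear interpolation between
    order statistics.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0,1); got {level}")
    if preds.B < 2:
        raise ValidationError("need B >= 2 for percentile intervals")
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(preds.multiverse, alpha, axis=1, method=PERCENTILE_METHOD)
    upper = np.quantile(
        preds.multiverse, 1.0 - alpha, axis=1, method=PERCENTILE_METHOD
    )
    return lower, upper


def classification_instability_index(
    preds: BootstrapPredictions, threshold: float
) -> np.ndarray:
    """Probability that a bootstrap model classifies individual i differently.

    CII_i = (1/B) Σ_b 1[ (p̂_bi ≥ t) ≠ (p̂_i ≥ t) ], with risk ≥ threshold
    classified positive. High CII means the original model's treat/no-treat
    decision for that individual is unreliable across the multiverse.
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0,1); got {threshold}")
    orig_pos = preds.original[:, None] >= threshold
    boot_pos = preds.multiverse >= threshold
    return (boot_pos != orig_pos).mean(axis=1)


def subgroup_mape(
    preds: BootstrapPredictions, groups
) -> pd.DataFrame:
    """MAPE summaries within subgroups (e.g. for fairness checks).

    ``groups`` is one label per individual. Returns a table (sorted by
    group label) of group size, mean/median/90th-percentile/max MAPE.
    Underrepresented groups often show markedly higher MAPE.
    """
    groups = np.asarray(groups)
    if groups.shape != (preds.n,):
        raise ValidationError("one group label per individual required")
    if any(g is None for g in groups.tolist()) or (
        groups.dtype.kind == "f" and np.isnan(groups).any()
    ):
        raise ValidationError("every individual must carry a group label")
    mape = mape_per_individual(preds)
    rows = []
    for g in sorted(pd.unique(groups).tolist(), key=str):
        m = mape[groups == g]
        rows.append(
            {
                "group": g,
                "n": int(m.size),
                "mean_mape": float(m.mean()),
                "median_mape": float(np.quantile(m, 0.5, method=PERCENTILE_METHOD)),
                "p90_mape": float(np.quantile(m, 0.9, method=PERCENTILE_METHOD)),
                "max_mape": float(m.max()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-bootstrap-model instability of performance summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscriminationInstability:
    """Spread of the c-statistic across the multiverse."""

    original: float
    per_bootstrap: np.ndarray
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile


def discrimination_instability(
    preds: BootstrapPredictions, cohort: Cohort
) -> DiscriminationInstability:
    """c-statistic of each bootstrap model on the original cohort.

    Discrimination is a whole-sample summary, so it can look stable even
    when individual predictions are wildly unstable — compare its narrow
    spread against the per-individual MAPE before trusting a model.
    """
    cs = np.array(
        [c_statistic(preds.multiverse[:, b], cohort.outcome) for b in range(preds.B)]
    )
    lo, hi = np.quantile(cs, [0.025, 0.975], method=PERCENTILE_METHOD)
    return DiscriminationInstability(
        original=c_statistic(preds.original, cohort.outcome),
        per_bootstrap=cs,
        lower=float(lo),
        upper=float(hi),
    )


@dataclass(frozen=True)
class UtilityInstability:
    """Spread of net benefit across the multiverse, per decision threshold."""

    thresholds: tuple[float, ...]
    original: np.ndarray             # one NB per threshold
    per_bootstrap: np.ndarray        # B x T
    lower: np.ndarray                # 2.5th percentile per threshold
    upper: np.ndarray                # 97.5th percentile per threshold


def clinical_utility_instability(
    preds: BootstrapPredictions, cohort: Cohort, thresholds
) -> UtilityInstability:
    """Net benefit of each bootstrap model at each decision threshold."""
    thresholds = tuple(float(t) for t in thresholds)
    for t in thresholds:
        if not 0 < t < 1:
            raise ValidationError(f"threshold must be in (0,1); got {t}")
    nb = np.array(
        [
            [net_benefit(preds.multiverse[:, b], cohort.outcome, t) for t in thresholds]
            for b in range(preds.B)
        ]
    )
    lo, hi = np.quantile(nb, [0.025, 0.975], axis=0, method=PERCENTILE_METHOD)
    return UtilityInstability(
        thresholds=thresholds,
        original=np.array(
            [net_benefit(preds.original, cohort.outcome, t) for t in thresholds]
        ),
        per_bootstrap=nb,
        lower=np.asarray(lo),
        upper=np.asarray(hi),
    )


@dataclass(frozen=True)
class CalibrationInstability:
    """Overlay bundle of smoothed calibration curves across the multiverse."""

    original_curve: CalibrationCurve
    bootstrap_curves: tuple[CalibrationCurve, ...]
    n_skipped: int
    spread_grid: np.ndarray       # original curve's grid
    spread: np.ndarray            # per-grid-point max-min across curves

    @property
    def max_spread(self) -> float:
        return float(np.nanmax(self.spread)) if len(self.spread) else 0.0


def calibration_instability(
    preds: BootstrapPredictions,
    cohort: Cohort,
    smoother: SmootherConfig | None = None,
    max_curves: int = 200,
) -> CalibrationInstability:
    """Smoothed calibration curve per bootstrap model on the original cohort.

    At most ``max_curves`` curves are fitted (the first columns), enough for
    the overlay plot; the per-grid-point spread (max − min of all curves,
    including the original, on the original curve's grid) quantifies the
    visual variability. Degenerate curves are skipped with a logged count.
    """
    smoother = smoother or SmootherConfig()
    original_curve = calibration_curve(preds.original, cohort.outcome, smoother)
    curves = []
    skipped = 0
    for b in range(min(preds.B, max_curves)):
        try:
            curves.append(
                calibration_curve(preds.multiverse[:, b], cohort.outcome, smoother)
            )
        except (DegenerateCurveError, ValidationError):
            skipped += 1
    if skipped:
        logger.info("calibration_instability: %d degenerate curve(s) skipped", skipped)
    grid = original_curve.grid
    stack = [original_curve.smoothed_observed]
    for c in curves:
        stack.append(c(grid))
    stack = np.vstack(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid points
        spread = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
    return CalibrationInstability(
        original_curve=original_curve,
        bootstrap_curves=tuple(curves),
        n_skipped=skipped,
        spread_grid=grid,
        spread=spread,
    )


# ---------------------------------------------------------------------------
# Learning curve: instability as a function of development sample size
# ---------------------------------------------------------------------------


def learning_curve(
    cohort: Cohort,
    procedure: DevelopmentProcedure,
    sizes,
    B: int,
    seed: int,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """MAPE summaries across development sample sizes.

    For each size m, a random subsample of the cohort is drawn (the full
    cohort when m = n) and the entire bootstrap engine is re-run on it.
    Falling mean MAPE with size shows how much additional data would tame
    the current instability. Returns one row per size with the derived
    seeds recorded for replay.
    """
    sizes = list(sizes)
    rows = []
    children = np.random.SeedSequence(seed).spawn(max(len(sizes), 1))
    for m, child in zip(sizes, children):
        sub_ss, boot_ss = child.spawn(2)
        boot_seed = _derive_seed(boot_ss)
        if m == cohort.n:
            sub = cohort
            sub_seed = None
        else:
            sub_seed = _derive_seed(sub_ss)
            sub = subsample_cohort(cohort, m, sub_seed)
        preds = run_bootstrap(
            sub, procedure, B, boot_seed, keep_models=False, n_jobs=n_jobs
        )
        mape = mape_per_individual(preds)
        rows.append(
            {
                "size": int(m),
                "n_events": sub.n_events,
                "mean_mape": float(mape.mean()),
                "median_mape": float(np.quantile(mape, 0.5, method=PERCENTILE_METHOD)),
                "max_mape": float(mape.max()),
                "subsample_seed": sub_seed,
                "bootstrap_seed": boot_seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size",
            "n_events",
            "mean_mape",
            "median_mape",
            "max_mape",
            "subsample_seed",
            "bootstrap_seed",
        ],
    )
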