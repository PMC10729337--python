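"""Scalar performance and calibration machinery.

These are the standard summaries of a clinical risk model — discrimination
(c-statistic), explained variation (Nagelkerke R²), clinical utility (net
benefit at a decision threshold) and a smoothed calibration curve. Each is
used twice: once on the original model, and once per bootstrap model to
summarise how unstable the summary itself is across the multiverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix
from scipy.special import logit
from scipy.stats import rankdata

from .cohort import Cohort
from .exceptions import DegenerateCurveError, ValidationError


def _check_binary(outcomes: np.ndarray) -> np.ndarray:
    outcomes = np.asarray(outcomes)
    if not np.isin(outcomes, (0, 1)).all():
        raise ValidationError("outcomes must be coded 0/1")
    if outcomes.min() == outcomes.max():
        raise ValidationError("both outcome classes must be present")
    return outcomes


def c_statistic(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability (equals AUROC).

    The proportion of all event/non-event pairs where the event individual
    receives the higher predicted risk; tied risks count 1/2. Computed via
    the rank (Mann-Whitney) identity in O(n log n); midranks give the
    half-credit tie handling exactly.
    """
    outcomes = _check_binary(outcomes)
    risks = np.asarray(risks, dtype=float)
    if risks.shape != outcomes.shape:
        raise ValidationError("risks and outcomes must have equal length")
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    ranks = rankdata(risks)
    u = ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-15, 1 - 1e-15)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def nagelkerke_r2(model, cohort: Cohort) -> float:
    """Nagelkerke's rescaled Cox-Snell R² on a cohort.

    Cox-Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ₁)) divided by its attainable
    maximum 1 − exp((2/n)ℓ₀), with ℓ₀ the intercept-only (prevalence)
    log-likelihood and ℓ₁ the model's log-likelihood on the cohort.
    """
    y = _check_binary(cohort.outcome)
    n = cohort.n
    p1 = model.predict(cohort)
    ll1 = _bernoulli_loglik(y, p1)
    ll0 = _bernoulli_loglik(y, np.full(n, y.mean()))
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    r2_max = 1.0 - np.exp((2.0 / n) * ll0)
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


def net_benefit(
    risks: np.ndarray, outcomes: np.ndarray, threshold: float
) -> float:
    """Net benefit TP/n − (FP/n)·t/(1−t) at risk threshold t.

    Classification convention: risk ≥ t is "positive" (ties at the
    threshold classify positive). False positives are down-weighted by the
    threshold odds t/(1−t), the exchange rate implied by treating at t.
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0,1); got {threshold}")
    outcomes = np.asarray(outcomes)
    if not np.isin(outcomes, (0, 1)).all():
        raise ValidationError("outcomes must be coded 0/1")
    risks = np.asarray(risks, dtype=float)
    n = len(outcomes)
    positive = risks >= threshold
    tp = int(np.sum(positive & (outcomes == 1)))
    fp = int(np.sum(positive & (outcomes == 0)))
    return float(tp / n - (fp / n) * threshold / (1.0 - threshold))


def events_per_parameter(n_events: int, n_parameters: int) -> tuple[float, int]:
    """Events per candidate predictor parameter: (exact ratio, nearest int).

    A coarse sample-size heuristic: e.g. 2851 events over 8 parameters is
    about 356 events per parameter, while 35 over 8 is about 4.
    """
    if n_parameters < 1:
        raise ValidationError("n_parameters must be >= 1")
    if n_events < 0:
        raise ValidationError("n_events must be >= 0")
    ratio = n_events / n_parameters
    return float(ratio), int(round(ratio))


# ---------------------------------------------------------------------------
# Calibration curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmootherConfig:
    """Configuration of the calibration smoother.

    ``kind="spline"`` (default) fits a logistic regression of the outcome
    on a natural cubic spline basis of logit(risk) — stable in the tails
    and fast enough to run across hundreds of bootstrap curves.
    ``kind="lowess"`` substitutes a kernel smoother of the raw outcome.
    """

    kind: str = "spline"
    df: int = 4
    n_grid: int = 100
    trim: float = 0.005  # curve support: central 99% of predictions
    min_n: int = 50
    lowess_frac: float = 0.3

    def __post_init__(self):
        if self.kind not in ("spline", "lowess"):
            raise ValidationError("smoother kind must be 'spline' or 'lowess'")


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed observed event probability as a function of predicted risk."""

    grid: np.ndarray
    smoothed_observed: np.ndarray
    support_range: tuple[float, float]
    smoother: SmootherConfig = field(default_factory=SmootherConfig)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        obs = np.asarray(self.smoothed_observed, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("calibration grid must be strictly increasing")
        if np.any((obs < 0) | (obs > 1)):
            raise ValidationError("smoothed observed risks must lie in [0,1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "smoothed_observed", obs)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate by interpolation strictly inside the support range."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.support_range
        out = np.interp(x, self.grid, self.smoothed_observed)
        return np.where((x < lo) | (x > hi), np.nan, out)

    def max_deviation_from_diagonal(self) -> float:
        return float(np.max(np.abs(self.smoothed_observed - self.grid)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted": self.grid, "smoothed_observed": self.smoothed_observed}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def calibration_curve(
    risks: np.ndarray,
    outcomes: np.ndarray,
    smoother: SmootherConfig | None = None,
) -> CalibrationCurve:
    """Fit a smoothed calibration curve of observed vs predicted risk.

    The default smoother regresses the binary outcome on a natural cubic
    spline basis of logit(predicted risk) via a binomial GLM, then
    evaluates on an equally spaced grid over the central (1 − 2·trim)
    quantile range of the predictions — no extrapolation beyond support.
    """
    smoother = smoother or SmootherConfig()
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if len(risks) < smoother.min_n:
        raise ValidationError(
            f"need at least {smoother.min_n} observations for a calibration curve"
        )
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValidationError("risks must lie strictly inside (0,1)")
    if np.ptp(risks) == 0:
        raise DegenerateCurveError("all predicted risks identical")
    if outcomes.min() == outcomes.max():
        raise DegenerateCurveError("constant outcome; curve is not estimable")

    lo, hi = np.quantile(risks, [smoother.trim, 1.0 - smoother.trim])
    if hi <= lo:
        raise DegenerateCurveError("degenerate prediction support")
    grid = np.linspace(lo, hi, smoother.n_grid)

    if smoother.kind == "lowess":
        # it=0: robustness iterations would treat the minority outcome
        # class as outliers and smooth binary data toward the majority
        fitted = sm.nonparametric.lowess(
            outcomes, risks, frac=smoother.lowess_frac, it=0, xvals=grid
        )
        smoothed = np.clip(fitted, 0.0, 1.0)
    else:
        x = logit(risks)
        try:
            design = dmatrix(
                "cr(x, df=df)", {"x": x, "df": smoother.df}, return_type="dataframe"
            )
            fit = sm.GLM(outcomes, design, family=sm.families.Binomial()).fit()
            (grid_design,) = build_design_matrices(
                [design.design_info], {"x": logit(grid), "df": smoother.df}
            )
            smoothed = np.asarray(fit.predict(pd.DataFrame(grid_design)))
        except Exception as e:  # separation, singular basis, ...
            raise DegenerateCurveError(f"calibration smoother failed: {e}") from e
        if not np.isfinite(smoothed).all():
            raise DegenerateCurveError("calibration smoother returned non-finite values")

    return CalibrationCurve(
        grid=grid,
        smoothed_observed=np.clip(smoothed, 0.0, 1.0),
        support_range=(float(lo), float(hi)),
        smoother=smoother,
    )
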