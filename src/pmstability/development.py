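"""The model-development process as a first-class, replayable object.

The bootstrap instability procedure requires re-running the *entire*
development process — including penalty tuning — inside every bootstrap
sample. A :class:`DevelopmentProcedure` therefore encapsulates everything
needed to turn a cohort into a fitted risk model: the candidate predictor
set, the tuning scheme, and a deterministic seed policy. Invoking it twice
on the same data with the same seed yields bit-identical models.

The built-in procedure is logistic regression with a lasso penalty, the
standard penalized development strategy for clinical risk models. The
penalty is selected by k-fold cross-validation over a log-spaced grid,
minimizing out-of-fold deviance; predictors are standardized internally so
the penalty treats them symmetrically, and coefficients are reported back
on the original scale. Alternative strategies (elastic net, trees, ...)
can be registered by subclassing the same contract.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._lasso_path import deviance, fit_lasso_logistic, fit_lasso_path
from .cohort import Cohort
from .exceptions import ConfigurationError, FitError, ValidationError

#: defaults for the data-dependent lasso penalty grid (per-observation
#: lambda scale, glmnet convention: (1/n) sum loss + lambda * ||beta||_1):
#: log-spaced from lambda_max (smallest penalty that zeroes every
#: coefficient) down to min_ratio * lambda_max
DEFAULT_N_PENALTIES = 13
DEFAULT_PENALTY_MIN_RATIO = 1e-3
DEFAULT_CV_FOLDS = 10


@dataclass(frozen=True)
class TuningRecord:
    """What the tuner did: the grid searched and the penalty it selected."""

    selected_penalty: float
    grid: tuple[float, ...]
    cv_folds: int
    cv_deviance: tuple[float, ...] = ()  # mean out-of-fold deviance per grid point

    def to_dict(self) -> dict:
        return {
            "selected_penalty": self.selected_penalty,
            "grid": list(self.grid),
            "cv_folds": self.cv_folds,
            "cv_deviance": list(self.cv_deviance),
        }


@dataclass(frozen=True)
class FittedModel:
    """A developed risk model: intercept + per-candidate log-odds coefficients.

    Coefficients are on the original predictor scale; a zero coefficient
    means the penalty dropped that predictor. ``predict`` returns
    expit(intercept + X beta), always strictly inside (0, 1) for finite
    predictor values.
    """

    predictor_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    tuning: TuningRecord
    n_used: int
    n_events_used: int

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.shape != (len(self.predictor_names),):
            raise ValidationError("one coefficient per candidate predictor required")

    @property
    def retained(self) -> tuple[str, ...]:
        """Predictors with nonzero coefficients (survived the penalty)."""
        return tuple(
            n for n, c in zip(self.predictor_names, self.coefficients) if c != 0.0
        )

    def linear_predictor(self, cohort: Cohort) -> np.ndarray:
        X = _aligned_matrix(cohort, self.predictor_names)
        return self.intercept + X @ self.coefficients

    def predict(self, cohort: Cohort) -> np.ndarray:
        # clip away from 0/1: expit saturates in double precision for
        # |linear predictor| > ~37, and downstream contracts need (0,1)
        return np.clip(expit(self.linear_predictor(cohort)), 1e-12, 1 - 1e-12)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "predictor_names": list(self.predictor_names),
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "tuning": self.tuning.to_dict(),
                "n_used": self.n_used,
                "n_events_used": self.n_events_used,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"]),
            tuning=TuningRecord(
                selected_penalty=d["tuning"]["selected_penalty"],
                grid=tuple(d["tuning"]["grid"]),
                cv_folds=d["tuning"]["cv_folds"],
                cv_deviance=tuple(d["tuning"]["cv_deviance"]),
            ),
            n_used=d["n_used"],
            n_events_used=d["n_events_used"],
        )


def _aligned_matrix(cohort: Cohort, names: tuple[str, ...]) -> np.ndarray:
    missing = [n for n in names if n not in cohort.predictor_names]
    if missing:
        raise ConfigurationError(
            f"cohort lacks model predictors {missing}; "
            f"cohort has {list(cohort.predictor_names)}"
        )
    cols = [cohort.predictor_names.index(n) for n in names]
    return cohort.predictors[:, cols]


class DevelopmentProcedure(ABC):
    """Contract for a self-contained, replayable model-development process."""

    name: str
    candidate_predictors: tuple[str, ...]

    @abstractmethod
    def develop(self, cohort: Cohort, seed: int) -> FittedModel:
        """Run the full development process (including tuning) on a cohort."""

    def describe(self) -> dict:
        return {"name": self.name, "candidate_predictors": list(self.candidate_predictors)}


@dataclass(frozen=True)
class PenalizedLogisticProcedure(DevelopmentProcedure):
    """Lasso-penalized logistic regression with cross-validated penalty.

    Parameters
    ----------
    candidate_predictors : tuple of str
        Predictors offered to the penalty; a dropped predictor keeps a zero
        coefficient rather than vanishing from the model.
    penalty_grid : tuple of float, optional
        Explicit lambda values on the per-observation scale
        ((1/n) * deviance + lambda * ||beta||_1). A single-element grid
        skips cross-validation; a grid of exactly ``(0,)`` reduces to the
        unpenalized maximum-likelihood fit. When omitted (the default) the
        grid is data-dependent in the usual lasso fashion: ``n_penalties``
        values log-spaced from lambda_max (the smallest penalty that zeroes
        all coefficients on the fitting sample) down to
        ``penalty_min_ratio * lambda_max``, recomputed inside every
        bootstrap sample exactly as the tuning would be re-run in practice.
    cv_folds : int
        Folds for the deviance-minimizing penalty search (stratified on the
        outcome so rare events appear in every fold).
    """

    candidate_predictors: tuple[str, ...]
    penalty_grid: tuple[float, ...] | None = None
    n_penalties: int = DEFAULT_N_PENALTIES
    penalty_min_ratio: float = DEFAULT_PENALTY_MIN_RATIO
    cv_folds: int = DEFAULT_CV_FOLDS
    max_iter: int = 2000
    name: str = "lasso_logistic"

    def __post_init__(self):
        object.__setattr__(
            self, "candidate_predictors", tuple(self.candidate_predictors)
        )
        if self.penalty_grid is not None:
            grid = tuple(float(g) for g in self.penalty_grid)
            if not grid:
                raise ConfigurationError("penalty grid must be non-empty")
            if any(g < 0 for g in grid):
                raise ConfigurationError("penalties must be non-negative")
            if 0.0 in grid and len(grid) > 1:
                raise ConfigurationError(
                    "penalty 0 (unpenalized) is only supported as a single-element grid"
                )
            object.__setattr__(self, "penalty_grid", grid)
        if self.n_penalties < 2 or not 0 < self.penalty_min_ratio < 1:
            raise ConfigurationError("invalid automatic penalty-grid settings")

    def describe(self) -> dict:
        d = super().describe()
        d.update(
            penalty_grid=(
                list(self.penalty_grid) if self.penalty_grid is not None else None
            ),
            n_penalties=self.n_penalties,
            penalty_min_ratio=self.penalty_min_ratio,
            cv_folds=self.cv_folds,
        )
        return d

    def _auto_grid(self, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
        # smallest penalty with all-zero coefficients: max |Z'(y - ybar)| / n
        lam_max = float(np.max(np.abs(Z.T @ (y - y.mean()))) / len(y))
        if lam_max <= 0:
            lam_max = 1e-3
        return np.geomspace(lam_max, lam_max * self.penalty_min_ratio,
                            self.n_penalties)

    # -- fitting ---------------------------------------------------------
    def develop(self, cohort: Cohort, seed: int) -> FittedModel:
        if not cohort.has_both_classes:
            raise ValidationError("cohort must contain both outcome classes")
        X = _aligned_matrix(cohort, self.candidate_predictors)
        y = cohort.outcome
        n = cohort.n

        # standardize for penalty fairness; constant columns pass through
        # with unit scale (the penalty removes them anyway)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        Z = (X - mean) / scale

        if self.penalty_grid == (0.0,):
            coef_std, intercept_std = self._fit_unpenalized(Z, y)
            tuning = TuningRecord(0.0, self.penalty_grid, 0)
        elif self.penalty_grid is not None and len(self.penalty_grid) == 1:
            lam = self.penalty_grid[0]
            coef_std, intercept_std = self._fit_at(Z, y, lam)
            tuning = TuningRecord(lam, self.penalty_grid, 0)
        else:
            grid = (
                np.asarray(self.penalty_grid)
                if self.penalty_grid is not None
                else self._auto_grid(Z, y)
            )
            coef_std, intercept_std, tuning = self._fit_cv(Z, y, grid, n, seed)

        if not (np.isfinite(coef_std).all() and np.isfinite(intercept_std)):
            raise FitError(
                "penalized logistic fit produced non-finite coefficients",
                {"n": n, "n_events": cohort.n_events},
            )

        coef = coef_std / scale
        intercept = intercept_std - float(coef_std @ (mean / scale))
        return FittedModel(
            predictor_names=self.candidate_predictors,
            intercept=float(intercept),
            coefficients=coef,
            tuning=tuning,
            n_used=n,
            n_events_used=cohort.n_events,
        )

    def _fit_unpenalized(self, Z, y):
        est = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=1e-8
        ).fit(Z, y)
        return est.coef_[0].copy(), float(est.intercept_[0])

    def _fit_at(self, Z, y, lam):
        intercept, coef = fit_lasso_logistic(Z, y, lam)
        return coef, intercept

    def _fit_cv(self, Z, y, lams, n, seed):
        fold_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
        # rare events: never ask for more folds than minority-class members
        n_minority = int(min(y.sum(), len(y) - y.sum()))
        folds = max(2, min(self.cv_folds, n_minority))
        cv = StratifiedKFold(folds, shuffle=True, random_state=fold_seed)
        dev = np.zeros((folds, len(lams)))
        try:
            for k, (train, test) in enumerate(cv.split(Z, y)):
                b0s, betas = fit_lasso_path(Z[train], y[train], lams)
                dev[k] = [
                    deviance(Z[test], y[test], b0s[j], betas[j])
                    for j in range(len(lams))
                ]
        except ValueError as e:
            raise FitError(
                f"cross-validated lasso fit failed: {e}",
                {"n": n, "n_events": int(y.sum())},
            ) from e
        mean_dev = dev.mean(axis=0)
        # deviance-minimizing penalty; ties break toward the larger penalty
        best = np.flatnonzero(mean_dev == mean_dev.min())
        chosen = best[np.argmax(lams[best])]
        intercept, coef = fit_lasso_logistic(Z, y, float(lams[chosen]))
        tuning = TuningRecord(
            selected_penalty=float(lams[chosen]),
            grid=tuple(float(v) for v in lams),
            cv_folds=folds,
            cv_deviance=tuple(mean_dev),
        )
        return coef, intercept, tuning


def gusto_like_procedure(
    candidate_predictors: tuple[str, ...] | None = None, **kwargs
) -> PenalizedLogisticProcedure:
    """The default development procedure: 8-predictor cross-validated lasso."""
    from .cohort import GUSTO_LIKE_NAMES

    return PenalizedLogisticProcedure(
        candidate_predictors=candidate_predictors or GUSTO_LIKE_NAMES, **kwargs
    )


def develop_model(
    cohort: Cohort, procedure: DevelopmentProcedure, seed: int
) -> FittedModel:
    """Run the development procedure on a cohort; deterministic given seed."""
    return procedure.develop(cohort, seed)


def predict_risks(model: FittedModel, cohort: Cohort) -> np.ndarray:
    """Per-individual predicted event risks, expit(intercept + X beta)."""
    return model.predict(cohort)
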