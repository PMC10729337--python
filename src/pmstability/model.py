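"""Model/Results interface over the instability engine.

:class:`InstabilityAnalysis` is constructed from a development cohort and a
development procedure; its :meth:`~InstabilityAnalysis.fit` runs the whole
bootstrap procedure and returns an :class:`InstabilityResults` object that
carries every instability summary (per-individual MAPE, percentile
intervals, classification instability, per-bootstrap c-statistic, net
benefit, calibration curves), a text ``summary()``, CSV/JSON export, and
plotting methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine
from .cohort import Cohort
from .development import DevelopmentProcedure, FittedModel, gusto_like_procedure
from .engine import (
    BootstrapPredictions,
    CalibrationInstability,
    DiscriminationInstability,
    UtilityInstability,
)
from .exceptions import ConfigurationError, ValidationError
from .metrics import SmootherConfig, events_per_parameter, nagelkerke_r2

PERCENTILE_METHOD = engine.PERCENTILE_METHOD


class InstabilityAnalysis:
    """Bootstrap instability analysis of a model-development process.

    Parameters
    ----------
    cohort : Cohort
        The development dataset defining the target population.
    procedure : DevelopmentProcedure, optional
        The development process to replicate in every bootstrap sample.
        Defaults to cross-validated lasso logistic regression on all of the
        cohort's predictors.
    thresholds : sequence of float
        Decision threshold(s) for classification instability and net
        benefit (default: a single 0.1 threshold).
    interval_level : float
        Coverage of the per-individual percentile intervals (default 0.95,
        i.e. the 2.5th and 97.5th percentiles).

    Examples
    --------
    >>> from pmstability import gusto_like_spec, generate_synthetic_cohort
    >>> cohort = generate_synthetic_cohort(gusto_like_spec(n=2000, seed=1))
    >>> res = InstabilityAnalysis(cohort).fit(B=200, seed=7)
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(
        self,
        cohort: Cohort,
        procedure: DevelopmentProcedure | None = None,
        thresholds=(0.1,),
        interval_level: float = 0.95,
        smoother: SmootherConfig | None = None,
    ):
        if procedure is None:
            procedure = gusto_like_procedure(cohort.predictor_names)
        missing = [
            p for p in procedure.candidate_predictors
            if p not in cohort.predictor_names
        ]
        if missing:
            raise ConfigurationError(
                f"candidate predictors {missing} absent from cohort "
                f"{list(cohort.predictor_names)}"
            )
        if not 0 < interval_level < 1:
            raise ValidationError("interval_level must be in (0,1)")
        self.cohort = cohort
        self.procedure = procedure
        self.thresholds = tuple(float(t) for t in thresholds)
        self.interval_level = float(interval_level)
        self.smoother = smoother or SmootherConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        predictors=None,
        **kwargs,
    ) -> "InstabilityAnalysis":
        """Build an analysis straight from a pandas DataFrame."""
        from .cohort import Cohort, _infer_kinds

        if outcome not in df.columns:
            raise ConfigurationError(f"outcome column {outcome!r} not in DataFrame")
        if predictors is None:
            predictors = [c for c in df.columns if c not in (outcome, "id")]
        X = df[list(predictors)].to_numpy(dtype=float)
        ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
        cohort = Cohort(
            ids=ids,
            outcome=df[outcome].to_numpy(),
            predictors=X,
            predictor_names=tuple(predictors),
            predictor_kinds=_infer_kinds(X),
        )
        return cls(cohort, **kwargs)

    def fit(
        self,
        B: int = 200,
        seed: int = 0,
        max_curves: int = 200,
        compute_calibration: bool = True,
        n_jobs: int = 1,
    ) -> "InstabilityResults":
        """Run the bootstrap multiverse and compute every instability summary."""
        preds = engine.run_bootstrap(
            self.cohort, self.procedure, B=B, seed=seed, n_jobs=n_jobs
        )
        mape, mape_var = engine.mape_per_individual(preds, with_variance=True)
        lower, upper = engine.prediction_intervals(preds, self.interval_level)
        cii = {
            t: engine.classification_instability_index(preds, t)
            for t in self.thresholds
        }
        discrimination = engine.discrimination_instability(preds, self.cohort)
        utility = engine.clinical_utility_instability(
            preds, self.cohort, self.thresholds
        )
        calibration = None
        if compute_calibration and self.cohort.n >= self.smoother.min_n:
            calibration = engine.calibration_instability(
                preds, self.cohort, self.smoother, max_curves=max_curves
            )
        return InstabilityResults(
            analysis=self,
            predictions=preds,
            mape=mape,
            mape_variance=mape_var,
            interval_lower=lower,
            interval_upper=upper,
            cii=cii,
            discrimination=discrimination,
            utility=utility,
            calibration=calibration,
            seed=seed,
        )


@dataclass
class InstabilityResults:
    """Everything the bootstrap multiverse says about one developed model.

    Attributes of note: ``mape`` (per-individual mean absolute prediction
    error), ``interval_lower``/``interval_upper`` (per-individual percentile
    bounds), ``cii`` (dict threshold -> per-individual classification
    instability index), ``discrimination`` (per-bootstrap c-statistics),
    ``utility`` (per-bootstrap net benefits), ``calibration`` (curve
    bundle), and ``predictions`` (the raw n×B multiverse).
    """

    analysis: InstabilityAnalysis
    predictions: BootstrapPredictions
    mape: np.ndarray
    mape_variance: np.ndarray
    interval_lower: np.ndarray
    interval_upper: np.ndarray
    cii: dict[float, np.ndarray]
    discrimination: DiscriminationInstability
    utility: UtilityInstability
    calibration: CalibrationInstability | None
    seed: int

    # -- convenience accessors ------------------------------------------
    @property
    def cohort(self) -> Cohort:
        return self.analysis.cohort

    @property
    def original_model(self) -> FittedModel:
        return self.predictions.original_model

    @property
    def B(self) -> int:
        return self.predictions.B

    def mape_summary(self) -> dict:
        q = np.quantile(self.mape, [0.5, 0.9], method=PERCENTILE_METHOD)
        return {
            "mean": float(self.mape.mean()),
            "median": float(q[0]),
            "p90": float(q[1]),
            "max": float(self.mape.max()),
        }

    def subgroup_mape(self, groups) -> pd.DataFrame:
        """Per-subgroup MAPE summaries (fairness check)."""
        return engine.subgroup_mape(self.predictions, groups)

    def nagelkerke_r2(self) -> float:
        return nagelkerke_r2(self.original_model, self.cohort)

    def events_per_parameter(self) -> tuple[float, int]:
        return events_per_parameter(
            self.cohort.n_events, len(self.analysis.procedure.candidate_predictors)
        )

    # -- tables ----------------------------------------------------------
    def individual_frame(self) -> pd.DataFrame:
        """Per-individual table: prediction, MAPE, interval, CII."""
        df = pd.DataFrame(
            {
                "id": self.cohort.ids,
                "prediction": self.predictions.original,
                "mape": self.mape,
                "mape_variance": self.mape_variance,
                "interval_lower": self.interval_lower,
                "interval_upper": self.interval_upper,
            }
        )
        for t, v in self.cii.items():
            df[f"cii_{t:g}"] = v
        return df

    def bootstrap_frame(self) -> pd.DataFrame:
        """Per-bootstrap-model table: c-statistic, net benefit per threshold."""
        df = pd.DataFrame(
            {
                "b": np.arange(1, self.B + 1),
                "c_statistic": self.discrimination.per_bootstrap,
            }
        )
        for j, t in enumerate(self.utility.thresholds):
            df[f"net_benefit_{t:g}"] = self.utility.per_bootstrap[:, j]
        return df

    def curves_frame(self) -> pd.DataFrame:
        """All calibration curves in long form (curve 0 = original model)."""
        if self.calibration is None:
            raise ValidationError("calibration instability was not computed")
        frames = []
        for k, curve in enumerate(
            (self.calibration.original_curve, *self.calibration.bootstrap_curves)
        ):
            f = curve.to_frame()
            f.insert(0, "curve", k)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    # -- report ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable instability report."""
        c = self.cohort
        m = self.mape_summary()
        epp, epp_round = self.events_per_parameter()
        lines = [
            "Prediction model instability analysis (bootstrap multiverse)",
            "=" * 62,
            f"Development data: n = {c.n}, events = {c.n_events} "
            f"({100 * c.prevalence:.1f}%)",
            f"Procedure: {self.analysis.procedure.name}, "
            f"{len(self.analysis.procedure.candidate_predictors)} candidate predictors "
            f"(~{epp_round} events per parameter)",
            f"Bootstrap replicates: B = {self.B} "
            f"(redraws: {self.predictions.provenance.get('redraws', 0)}), "
            f"seed = {self.seed}",
            "",
            "Original model",
            f"  retained predictors : {len(self.original_model.retained)}"
            f"/{len(self.original_model.predictor_names)}",
            f"  c-statistic         : {self.discrimination.original:.3f}",
            f"  Nagelkerke R2       : {self.nagelkerke_r2():.3f}",
            "",
            "Individual-level prediction instability (MAPE)",
            f"  mean   : {m['mean']:.4f}",
            f"  median : {m['median']:.4f}",
            f"  90th % : {m['p90']:.4f}",
            f"  max    : {m['max']:.4f}",
            "",
            "Bootstrap-model c-statistic on the original sample",
            f"  2.5th-97.5th percentile: {self.discrimination.lower:.3f} "
            f"to {self.discrimination.upper:.3f}",
        ]
        for j, t in enumerate(self.utility.thresholds):
            cii_mean = float(self.cii[t].mean())
            cii_max = float(self.cii[t].max())
            lines += [
                "",
                f"Decision threshold t = {t:g}",
                f"  classification instability index: mean {cii_mean:.3f}, "
                f"max {cii_max:.3f}",
                f"  net benefit (original model)    : {self.utility.original[j]:.4f}",
                f"  net benefit 2.5th-97.5th %      : {self.utility.lower[j]:.4f} "
                f"to {self.utility.upper[j]:.4f}",
            ]
        if self.calibration is not None:
            lines += [
                "",
                "Calibration instability "
                f"({len(self.calibration.bootstrap_curves)} bootstrap curves, "
                f"{self.calibration.n_skipped} skipped)",
                f"  max per-grid-point curve spread: {self.calibration.max_spread:.4f}",
            ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path, save_multiverse: bool = False) -> Path:
        """Write the full report to a directory of CSV/JSON files.

        ``individuals.csv``, ``bootstrap_models.csv``, ``curves.csv`` (when
        calibration was computed), ``run_summary.json``, and optionally the
        raw ``multiverse.csv`` (n rows × B columns; needed to re-render the
        prediction instability scatter later).
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.individual_frame().to_csv(out_dir / "individuals.csv", index=False)
        self.bootstrap_frame().to_csv(out_dir / "bootstrap_models.csv", index=False)
        if self.calibration is not None:
            self.curves_frame().to_csv(out_dir / "curves.csv", index=False)
        if save_multiverse:
            pd.DataFrame(
                self.predictions.multiverse,
                columns=[f"b{b}" for b in range(1, self.B + 1)],
            ).to_csv(out_dir / "multiverse.csv", index=False)
        run = {
            "seed": self.seed,
            "B": self.B,
            "n": self.cohort.n,
            "n_events": self.cohort.n_events,
            "thresholds": list(self.analysis.thresholds),
            "interval_level": self.analysis.interval_level,
            "provenance": {
                k: v
                for k, v in self.predictions.provenance.items()
                if k != "procedure"
            },
            "procedure": self.analysis.procedure.describe(),
            "original_model": json.loads(self.original_model.to_json()),
            "mape_summary": self.mape_summary(),
            "c_statistic": {
                "original": self.discrimination.original,
                "lower": self.discrimination.lower,
                "upper": self.discrimination.upper,
            },
        }
        (out_dir / "run_summary.json").write_text(json.dumps(run, indent=2))
        return out_dir

    # -- plots -----------------------------------------------------------
    def plot_prediction_instability(self, out=None, ax=None):
        from .plots import plot_prediction_instability

        return plot_prediction_instability(self, out=out, ax=ax)

    def plot_classification_instability(self, threshold=None, out=None, ax=None):
        from .plots import plot_classification_instability

        if threshold is None:
            threshold = self.analysis.thresholds[0]
        return plot_classification_instability(self, threshold, out=out, ax=ax)

    def plot_calibration_instability(self, out=None, ax=None):
        from .plots import plot_calibration_instability

        if self.calibration is None:
            raise ValidationError("calibration instability was not computed")
        return plot_calibration_instability(self.calibration, out=out, ax=ax)
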