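import numpy as np
import pytest

from pmstability import (
    Bernoulli,
    BootstrapPredictions,
    Cohort,
    FittedModel,
    Normal,
    PenalizedLogisticProcedure,
    SyntheticCohortSpec,
    TuningRecord,
)
from pmstability.development import DevelopmentProcedure


def make_cohort(n=60, p=3, seed=0, prevalence=0.35):
    """Small random cohort with both outcome classes guaranteed."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    lp = np.log(prevalence / (1 - prevalence)) + X[:, 0]
    y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    return Cohort(
        ids=np.arange(n),
        outcome=y,
        predictors=X,
        predictor_names=tuple(f"x{j}" for j in range(p)),
        predictor_kinds=("continuous",) * p,
    )


def make_preds(original, multiverse, **prov):
    """BootstrapPredictions around hand-chosen arrays, with a stub model."""
    original = np.asarray(original, dtype=float)
    model = FittedModel(
        predictor_names=("x0",),
        intercept=0.0,
        coefficients=np.zeros(1),
        tuning=TuningRecord(0.0, (0.0,), 0),
        n_used=len(original),
        n_events_used=1,
    )
    return BootstrapPredictions(
        original=original,
        multiverse=np.asarray(multiverse, dtype=float),
        original_model=model,
        provenance=prov,
    )


class ConstantProcedure(DevelopmentProcedure):
    """Degenerate development process that ignores the data entirely."""

    name = "constant"

    def __init__(self, candidate_predictors, intercept=-2.0, coefficients=None):
        self.candidate_predictors = tuple(candidate_predictors)
        self.intercept = intercept
        self.coefficients = (
            np.zeros(len(self.candidate_predictors))
            if coefficients is None
            else np.asarray(coefficients, dtype=float)
        )

    def develop(self, cohort, seed):
        return FittedModel(
            predictor_names=self.candidate_predictors,
            intercept=self.intercept,
            coefficients=self.coefficients,
            tuning=TuningRecord(0.0, (0.0,), 0),
            n_used=cohort.n,
            n_events_used=cohort.n_events,
        )


@pytest.fixture
def small_cohort():
    return make_cohort(n=60, p=3, seed=1)


@pytest.fixture
def fast_procedure(small_cohort):
    """Single fixed penalty: no cross-validation, so bootstrap tests stay quick."""
    return PenalizedLogisticProcedure(
        small_cohort.predictor_names, penalty_grid=(0.02,)
    )


@pytest.fixture
def tiny_spec():
    return SyntheticCohortSpec(
        n=400,
        true_intercept=-1.0,
        true_coefficients=(0.8, -0.5),
        predictor_names=("a", "b"),
        predictor_generators=(Normal(0, 1), Bernoulli(0.3)),
        seed=11,
    )


@pytest.fixture(autouse=True)
def _quiet_small_B_warning():
    """Tests intentionally run tiny B; silence the advisory warning."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="B=.* is below the recommended minimum"
        )
        warnings.filterwarnings(
            "ignore", message="The least populated class"
        )
        yield
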