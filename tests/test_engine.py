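import numpy as np
import pytest

from pmstability import (
    InstabilityInfeasibleError,
    PenalizedLogisticProcedure,
    ValidationError,
    calibration_instability,
    classification_instability_index,
    clinical_utility_instability,
    discrimination_instability,
    learning_curve,
    mape_per_individual,
    prediction_intervals,
    run_bootstrap,
    subgroup_mape,
)
from pmstability.development import DevelopmentProcedure
from pmstability.engine import _derive_seed
from pmstability.exceptions import FitError

from conftest import ConstantProcedure, make_cohort, make_preds


# ---------------------------------------------------------------------------
# naive loop-based oracles
# ---------------------------------------------------------------------------

def naive_mape(original, multiverse):
    n, B = multiverse.shape
    out = np.zeros(n)
    for i in range(n):
        errors = [abs(multiverse[i, b] - original[i]) for b in range(B)]
        out[i] = np.mean(errors)
    return out


def naive_cii(original, multiverse, t):
    n, B = multiverse.shape
    out = np.zeros(n)
    for i in range(n):
        c = 0
        for b in range(B):
            if (multiverse[i, b] >= t) != (original[i] >= t):
                c += 1
        out[i] = c / B
    return out


def naive_intervals(multiverse, level):
    alpha = (1 - level) / 2
    lo = np.array([np.quantile(row, alpha, method="linear") for row in multiverse])
    hi = np.array([np.quantile(row, 1 - alpha, method="linear") for row in multiverse])
    return lo, hi


class TestRunBootstrap:
    def test_deterministic_bitwise(self, small_cohort, fast_procedure):
        a = run_bootstrap(small_cohort, fast_procedure, B=3, seed=5)
        b = run_bootstrap(small_cohort, fast_procedure, B=3, seed=5)
        np.testing.assert_array_equal(a.multiverse, b.multiverse)
        np.testing.assert_array_equal(a.original, b.original)
        assert a.multiverse.shape == (small_cohort.n, 3)

    def test_different_seed_differs(self, small_cohort, fast_procedure):
        a = run_bootstrap(small_cohort, fast_procedure, B=3, seed=5)
        b = run_bootstrap(small_cohort, fast_procedure, B=3, seed=6)
        assert not np.array_equal(a.multiverse, b.multiverse)

    def test_parallel_matches_sequential(self, small_cohort, fast_procedure):
        a = run_bootstrap(small_cohort, fast_procedure, B=4, seed=5, n_jobs=1)
        b = run_bootstrap(small_cohort, fast_procedure, B=4, seed=5, n_jobs=2)
        np.testing.assert_array_equal(a.multiverse, b.multiverse)

    def test_constant_procedure_gives_zero_instability(self, small_cohort):
        proc = ConstantProcedure(small_cohort.predictor_names)
        preds = run_bootstrap(small_cohort, proc, B=4, seed=0)
        assert np.all(preds.multiverse == preds.original[:, None])
        assert np.all(mape_per_individual(preds) == 0.0)

    def test_small_B_warns(self, small_cohort, fast_procedure):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(UserWarning):
                run_bootstrap(small_cohort, fast_procedure, B=3, seed=0)

    def test_degenerate_resamples_redrawn_and_logged(self):
        # 2 events in 12 rows: single-class resamples are common
        cohort = make_cohort(n=12, seed=0)
        outcome = np.zeros(12, dtype=int)
        outcome[[3, 7]] = 1
        cohort = type(cohort)(
            ids=cohort.ids, outcome=outcome, predictors=cohort.predictors,
            predictor_names=cohort.predictor_names,
            predictor_kinds=cohort.predictor_kinds,
        )
        proc = PenalizedLogisticProcedure(
            cohort.predictor_names, penalty_grid=(0.1,)
        )
        preds = run_bootstrap(cohort, proc, B=10, seed=4)
        assert preds.B == 10
        assert preds.provenance["redraws"] >= 1

    def test_redraw_cap_exceeded(self, small_cohort):
        class FailsInResamples(DevelopmentProcedure):
            """Fits the original cohort, then fails every bootstrap refit."""

            name = "broken"
            candidate_predictors = small_cohort.predictor_names

            def __init__(self):
                self.calls = 0

            def develop(self, cohort, seed):
                self.calls += 1
                if self.calls > 1:
                    raise FitError("nope")
                return ConstantProcedure(self.candidate_predictors).develop(
                    cohort, seed
                )

        with pytest.raises(InstabilityInfeasibleError):
            run_bootstrap(
                small_cohort, FailsInResamples(), B=2, seed=0, max_redraws=3
            )


class TestMape:
    def test_derived_arithmetic(self):
        preds = make_preds([0.2], [[0.1, 0.3, 0.2]])
        assert mape_per_individual(preds)[0] == pytest.approx(0.2 / 3)

    def test_zero_iff_multiverse_equals_original(self):
        preds = make_preds([0.2, 0.7], [[0.2, 0.2], [0.7, 0.7]])
        assert np.all(mape_per_individual(preds) == 0.0)
        preds2 = make_preds([0.2, 0.7], [[0.2, 0.2], [0.7, 0.70001]])
        assert mape_per_individual(preds2)[1] > 0.0

    def test_variance_of_absolute_errors(self):
        preds = make_preds([0.2], [[0.1, 0.3, 0.2]])
        mape, var = mape_per_individual(preds, with_variance=True)
        expected = np.var([0.1, 0.1, 0.0])
        assert var[0] == pytest.approx(expected)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, B = rng.integers(2, 20), rng.integers(1, 10)
            orig = rng.uniform(0.01, 0.99, n)
            mv = rng.uniform(0.01, 0.99, (n, B))
            preds = make_preds(orig, mv)
            np.testing.assert_array_equal(
                mape_per_individual(preds), naive_mape(orig, mv)
            )


class TestPredictionIntervals:
    def test_constant_row_zero_width(self):
        preds = make_preds([0.3], [[0.4, 0.4, 0.4]])
        lo, hi = prediction_intervals(preds, 0.95)
        assert lo[0] == hi[0] == 0.4

    def test_hundred_evenly_spaced_values(self):
        row = np.round(np.linspace(0.01, 0.99, 100), 4)
        preds = make_preds([0.5], row[None, :])
        lo, hi = prediction_intervals(preds, 0.95)
        assert lo[0] == pytest.approx(np.quantile(row, 0.025, method="linear"))
        assert hi[0] == pytest.approx(np.quantile(row, 0.975, method="linear"))

    def test_bounds_within_row_range(self):
        rng = np.random.default_rng(1)
        mv = rng.uniform(0.01, 0.99, (15, 8))
        preds = make_preds(rng.uniform(0.01, 0.99, 15), mv)
        lo, hi = prediction_intervals(preds, 0.9)
        assert np.all(lo >= mv.min(axis=1)) and np.all(hi <= mv.max(axis=1))
        assert np.all(lo <= hi)

    def test_invalid_level(self):
        preds = make_preds([0.3], [[0.4, 0.5]])
        with pytest.raises(ValidationError):
            prediction_intervals(preds, 1.5)


class TestClassificationInstability:
    def test_same_side_gives_zero(self):
        preds = make_preds([0.3], [[0.2, 0.4, 0.45]])
        assert classification_instability_index(preds, 0.5)[0] == 0.0

    def test_derived_count(self):
        preds = make_preds([0.12], [[0.05, 0.15, 0.09, 0.11]])
        assert classification_instability_index(preds, 0.1)[0] == 0.5

    def test_threshold_tie_is_positive_side(self):
        # original exactly at t counts positive; bootstrap below flips
        preds = make_preds([0.1], [[0.1, 0.0999]])
        assert classification_instability_index(preds, 0.1)[0] == 0.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mv = rng.uniform(0.01, 0.99, (10, 7))
        orig = rng.uniform(0.01, 0.99, 10)
        a = classification_instability_index(make_preds(orig, mv), 0.3)
        perm = rng.permutation(7)
        b = classification_instability_index(make_preds(orig, mv[:, perm]), 0.3)
        np.testing.assert_array_equal(a, b)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, B = rng.integers(2, 20), rng.integers(1, 10)
            orig = rng.uniform(0.01, 0.99, n)
            mv = rng.uniform(0.01, 0.99, (n, B))
            t = rng.uniform(0.05, 0.95)
            np.testing.assert_array_equal(
                classification_instability_index(make_preds(orig, mv), t),
                naive_cii(orig, mv, t),
            )


class TestDiscriminationAndUtility:
    def test_identical_columns_zero_spread(self, small_cohort):
        col = np.clip(
            0.1 + 0.8 * (small_cohort.predictors[:, 0] - small_cohort.predictors[:, 0].min())
            / np.ptp(small_cohort.predictors[:, 0]), 0.01, 0.99,
        )
        preds = make_preds(col, np.tile(col[:, None], (1, 5)))
        d = discrimination_instability(preds, small_cohort)
        assert d.lower == d.upper == d.per_bootstrap[0]
        u = clinical_utility_instability(preds, small_cohort, [0.2])
        assert np.all(u.lower == u.upper)

    def test_rank_invariance_across_columns(self, small_cohort):
        base = np.clip(
            0.1 + 0.8 * (small_cohort.predictors[:, 0] - small_cohort.predictors[:, 0].min())
            / np.ptp(small_cohort.predictors[:, 0]), 0.01, 0.99,
        )
        mv = np.column_stack([base, np.sqrt(base), base ** 2])
        preds = make_preds(base, mv)
        d = discrimination_instability(preds, small_cohort)
        assert np.allclose(d.per_bootstrap, d.per_bootstrap[0])

    def test_toy_net_benefit_replicated(self):
        cohort = make_cohort(n=4, seed=0)
        cohort = type(cohort)(
            ids=cohort.ids, outcome=np.array([1, 1, 0, 0]),
            predictors=cohort.predictors,
            predictor_names=cohort.predictor_names,
            predictor_kinds=cohort.predictor_kinds,
        )
        col = np.array([0.8, 0.6, 0.4, 0.2])
        preds = make_preds(col, np.tile(col[:, None], (1, 3)))
        u = clinical_utility_instability(preds, cohort, [0.5])
        assert np.all(u.per_bootstrap == 0.5)
        assert u.original[0] == 0.5


class TestCalibrationInstability:
    def test_identical_columns_zero_spread(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort(n=300, seed=5)
        col = np.clip(rng.beta(2, 5, 300), 0.01, 0.99)
        preds = make_preds(col, np.tile(col[:, None], (1, 4)))
        bundle = calibration_instability(preds, cohort)
        assert bundle.max_spread == pytest.approx(0.0, abs=1e-12)
        assert len(bundle.bootstrap_curves) == 4

    def test_max_curves_cap(self):
        rng = np.random.default_rng(6)
        cohort = make_cohort(n=200, seed=6)
        mv = np.clip(rng.beta(2, 5, (200, 7)), 0.01, 0.99)
        preds = make_preds(np.clip(rng.beta(2, 5, 200), 0.01, 0.99), mv)
        bundle = calibration_instability(preds, cohort, max_curves=3)
        assert len(bundle.bootstrap_curves) + bundle.n_skipped == 3

    def test_spread_nonnegative(self):
        rng = np.random.default_rng(7)
        cohort = make_cohort(n=200, seed=7)
        mv = np.clip(rng.beta(2, 5, (200, 5)), 0.01, 0.99)
        preds = make_preds(np.clip(rng.beta(2, 5, 200), 0.01, 0.99), mv)
        bundle = calibration_instability(preds, cohort)
        assert np.all(bundle.spread[np.isfinite(bundle.spread)] >= 0)


class TestSubgroupMape:
    def test_single_group_matches_global(self):
        rng = np.random.default_rng(8)
        preds = make_preds(
            rng.uniform(0.01, 0.99, 12), rng.uniform(0.01, 0.99, (12, 6))
        )
        table = subgroup_mape(preds, ["all"] * 12)
        mape = mape_per_individual(preds)
        assert table.loc[0, "mean_mape"] == pytest.approx(mape.mean())
        assert table.loc[0, "max_mape"] == pytest.approx(mape.max())
        assert table.loc[0, "n"] == 12

    def test_identical_groups_identical_summaries(self):
        rng = np.random.default_rng(9)
        orig = rng.uniform(0.01, 0.99, 10)
        mv = rng.uniform(0.01, 0.99, (10, 5))
        # duplicate every row into two groups
        preds = make_preds(np.r_[orig, orig], np.vstack([mv, mv]))
        table = subgroup_mape(preds, ["g1"] * 10 + ["g2"] * 10)
        a, b = table.iloc[0], table.iloc[1]
        assert a["mean_mape"] == b["mean_mape"]
        assert a["max_mape"] == b["max_mape"]

    def test_missing_label_rejected(self):
        preds = make_preds([0.2, 0.3], [[0.2, 0.3], [0.3, 0.4]])
        with pytest.raises(ValidationError):
            subgroup_mape(preds, [np.nan, 1.0])
        with pytest.raises(ValidationError):
            subgroup_mape(preds, ["a"])


class TestLearningCurve:
    def test_full_size_equals_direct_run(self, small_cohort, fast_procedure):
        table = learning_curve(
            small_cohort, fast_procedure, sizes=[small_cohort.n], B=3, seed=2
        )
        direct = run_bootstrap(
            small_cohort, fast_procedure, B=3,
            seed=int(table.loc[0, "bootstrap_seed"]),
        )
        assert table.loc[0, "mean_mape"] == pytest.approx(
            float(mape_per_individual(direct).mean())
        )
        assert table.loc[0, "subsample_seed"] is None or np.isnan(
            table.loc[0, "subsample_seed"]
        )

    def test_empty_sizes_gives_empty_table(self, small_cohort, fast_procedure):
        table = learning_curve(small_cohort, fast_procedure, sizes=[], B=2, seed=0)
        assert len(table) == 0
        assert "mean_mape" in table.columns

    def test_rows_and_seeds_recorded(self, fast_procedure):
        cohort = make_cohort(n=120, seed=10)
        proc = PenalizedLogisticProcedure(
            cohort.predictor_names, penalty_grid=(0.02,)
        )
        table = learning_curve(cohort, proc, sizes=[40, 120], B=3, seed=1)
        assert table["size"].tolist() == [40, 120]
        assert table.loc[0, "subsample_seed"] is not None


def test_seed_derivation_below_2_31():
    ss = np.random.SeedSequence(123)
    assert 0 <= _derive_seed(ss) < 2**31
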