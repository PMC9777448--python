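"""Fold construction, ridge training, prediction and accuracy metrics."""

import numpy as np
import pandas as pd
import pytest

from epiclock.clock import (
    ClockConfig,
    MethylationAgeClock,
    accuracy_metrics,
    age_balanced_folds,
    predict_age,
    train_clock,
)
from epiclock.io import MethylationMatrix, SampleSheet
from epiclock.preprocess import m_to_beta
from epiclock.simulate import CohortSpec, GroupSpec, simulate_targeted_cohort


def _noiseless_cohort(small_units, n=60, seed=5, delta=0.0, ages=(21, 80)):
    spec = CohortSpec(
        groups=(
            GroupSpec("CTR", n=n, age_low=ages[0], age_high=ages[1],
                      delta_accel=delta, sd_accel=0.0),
        ),
        missing_rate=0.0,
        seed=seed,
    )
    units = [
        u.__class__(u.unit_id, u.slope_m, u.intercept_m, 0.0, u.region_id)
        for u in small_units
    ]
    return simulate_targeted_cohort(units, spec)


class TestAgeBalancedFolds:
    def test_partition_of_ten(self):
        ages = np.linspace(20, 79, 10)
        folds = age_balanced_folds(ages, k_folds=5, seed=0)
        sizes = [f.size for f in folds]
        assert sizes == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_decade_balance(self):
        # 10 samples per decade, 5 folds -> exactly 2 per decade in each fold
        ages = np.repeat(np.arange(10, 110, 10), 10) + 3.0
        folds = age_balanced_folds(ages, k_folds=5, age_bin_width=10, seed=1)
        bins = np.floor(ages / 10).astype(int)
        for f in folds:
            counts = np.bincount(bins[f], minlength=bins.max() + 1)
            assert all(counts[np.unique(bins)] == 2)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            age_balanced_folds([30, 40, 50, 60], k_folds=5)

    def test_deterministic_given_seed(self):
        ages = np.random.default_rng(3).uniform(20, 80, 37)
        a = age_balanced_folds(ages, seed=9)
        b = age_balanced_folds(ages, seed=9)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_bin_imbalance_at_most_one(self):
        ages = np.random.default_rng(4).uniform(0, 100, 83)
        folds = age_balanced_folds(ages, k_folds=5, seed=2)
        bins = np.floor(ages / 10).astype(int)
        for b in np.unique(bins):
            per_fold = [np.isin(f, np.flatnonzero(bins == b)).sum() for f in folds]
            assert max(per_fold) - min(per_fold) <= 1


class TestTraining:
    def test_noiseless_recovery(self, small_units):
        cohort = _noiseless_cohort(small_units)
        model, report = train_clock(
            cohort.matrix, cohort.sheet, ClockConfig(seed=0)
        )
        pred = predict_age(model, cohort.matrix)
        ages = cohort.sheet.ages
        assert np.max(np.abs(pred.to_numpy() - ages.to_numpy())) < 0.1
        assert accuracy_metrics(pred, ages)["spearman_rho"] == pytest.approx(1.0)

    def test_constant_age_rejected(self, small_units):
        cohort = _noiseless_cohort(small_units, n=20, ages=(50, 50))
        with pytest.raises(ValueError, match="variance"):
            train_clock(cohort.matrix, cohort.sheet, ClockConfig(seed=0))

    def test_huge_penalty_shrinks_to_mean(self, small_units):
        cohort = _noiseless_cohort(small_units)
        model, _ = train_clock(
            cohort.matrix, cohort.sheet, ClockConfig(lambda_grid=(1e8,), seed=0)
        )
        assert np.max(np.abs(model.coef_)) < 1e-3
        pred = predict_age(model, cohort.matrix)
        mean_age = cohort.sheet.ages.mean()
        assert np.max(np.abs(pred.to_numpy() - mean_age)) < 1.0

    def test_zero_variance_unit_dropped(self, small_units):
        cohort = _noiseless_cohort(small_units)
        beta = cohort.matrix.beta.copy()
        beta["flat"] = 0.4
        m = MethylationMatrix(beta)
        with pytest.warns(UserWarning, match="zero-variance"):
            model, _ = train_clock(m, cohort.sheet, ClockConfig(seed=0))
        assert "flat" not in model.unit_ids_

    def test_training_window_filter(self, small_units):
        cohort = _noiseless_cohort(small_units, ages=(5, 95))
        model, report = train_clock(cohort.matrix, cohort.sheet, ClockConfig(seed=0))
        ages = cohort.sheet.ages.to_numpy()
        assert report.n_samples == int(((ages >= 20) & (ages <= 80)).sum())


class TestPrediction:
    def test_constant_model(self):
        model = MethylationAgeClock.from_json(_constant_model_json())
        X = pd.DataFrame({"u1": [0.2, 0.5], "u2": [0.7, 0.9]}, index=["a", "b"])
        np.testing.assert_allclose(model.predict(X), [50.0, 50.0])

    def test_column_permutation_invariance(self, small_units, small_cohort):
        complete = MethylationMatrix(small_cohort.matrix.beta.fillna(0.5))
        model, _ = train_clock(complete, small_cohort.sheet, ClockConfig(seed=0))
        permuted = MethylationMatrix(
            complete.beta[list(reversed(complete.unit_ids))]
        )
        np.testing.assert_array_equal(
            model.predict(complete.beta), model.predict(permuted.beta)
        )

    def test_missing_unit_raises(self, small_cohort):
        complete = MethylationMatrix(small_cohort.matrix.beta.fillna(0.5))
        model, _ = train_clock(complete, small_cohort.sheet, ClockConfig(seed=0))
        with pytest.raises(ValueError, match="missing model units"):
            model.predict(complete.beta.iloc[:, :-2])

    def test_reapplication_matches_fit_report(self, small_units):
        cohort = _noiseless_cohort(small_units)
        model, report = train_clock(cohort.matrix, cohort.sheet, ClockConfig(seed=0))
        pred = predict_age(model, cohort.matrix)
        np.testing.assert_allclose(
            pred.loc[report.training_predictions.index].to_numpy(),
            report.training_predictions.to_numpy(),
            atol=1e-9,
        )

    def test_serialization_round_trip_bit_identical(self, small_cohort):
        complete = MethylationMatrix(small_cohort.matrix.beta.fillna(0.5))
        model, _ = train_clock(complete, small_cohort.sheet, ClockConfig(seed=0))
        clone = MethylationAgeClock.from_json(model.to_json())
        np.testing.assert_array_equal(
            model.predict(complete.beta), clone.predict(complete.beta)
        )


def _constant_model_json() -> str:
    import json

    return json.dumps(
        {
            "format": "epiclock-model",
            "version": 1,
            "unit_ids": ["u1", "u2"],
            "coef": [0.0, 0.0],
            "intercept": 50.0,
            "unit_means": [0.0, 0.0],
            "unit_sds": [1.0, 1.0],
            "lambda": 1.0,
            "training_age_range": [20.0, 80.0],
            "eps": 0.001,
        }
    )


class TestAccuracyMetrics:
    def test_perfect_prediction(self):
        m = accuracy_metrics([21, 40, 60, 80], [21, 40, 60, 80])
        assert m == {"spearman_rho": 1.0, "mad_median": 0.0, "mad_mean": 0.0}

    def test_constant_offset(self):
        m = accuracy_metrics(np.array([21, 40, 60, 80]) + 4.0, [21, 40, 60, 80])
        assert m["spearman_rho"] == pytest.approx(1.0)
        assert m["mad_median"] == pytest.approx(4.0)
        assert m["mad_mean"] == pytest.approx(4.0)

    def test_known_rank_correlation(self):
        m = accuracy_metrics([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert m["spearman_rho"] == pytest.approx(0.8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy_metrics([1, 2, 3], [1, 2])


def test_ols_equivalence_in_small_lambda_limit():
    """With a vanishing penalty on a full-rank 30x5 design, the clock must
    match the closed-form least-squares fit."""
    rng = np.random.default_rng(8)
    n, p = 30, 5
    M = rng.normal(0, 1.5, size=(n, p))
    w = rng.normal(0, 5, size=p)
    ages = np.clip(55 + M @ w + rng.normal(0, 2, size=n), 21, 79)
    beta = pd.DataFrame(
        m_to_beta(M), index=[f"s{i}" for i in range(n)], columns=[f"u{j}" for j in range(p)]
    )
    clock = MethylationAgeClock(lambda_grid=(1e-8,), seed=0).fit(beta, ages)
    # independent closed-form oracle on the identical standardized design
    M2 = np.log2(beta.to_numpy() / (1 - beta.to_numpy()))
    Z = (M2 - M2.mean(axis=0)) / M2.std(axis=0)
    design = np.column_stack([np.ones(n), Z])
    theta, *_ = np.linalg.lstsq(design, ages, rcond=None)
    np.testing.assert_allclose(clock.predict(beta), design @ theta, atol=1e-6)
    np.testing.assert_allclose(clock.coef_, theta[1:], atol=1e-6)
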