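"""Elastic-net solver oracles, LOOCV grid search, training protocol,
prediction and evaluation metrics."""

import numpy as np
import pytest

from ampliclock.clock import (
    TrainConfig,
    calibrate_intercept,
    enet_fit,
    evaluate,
    loocv_grid_search,
    predict_age,
    split_cohort,
    train_clock,
)
from ampliclock.regions import ClockModel, CpGSite, bundled_clock
from ampliclock.simdata import GenerativeClock, cohort_beta_matrix, sample_cohort
from ampliclock.simdata import CohortSpec


@pytest.fixture(scope="module")
def fixture_5x3():
    rng = np.random.default_rng(4)
    X = rng.normal(50, 10, size=(5, 3))
    beta_true = np.array([0.5, -1.2, 0.3])
    y = 30 + X @ beta_true + rng.normal(0, 0.5, 5)
    return X, y


def _standardize(X):
    mu, sd = X.mean(0), X.std(0)
    return (X - mu) / sd, mu, sd


class TestEnetOracles:
    def test_full_shrinkage(self, fixture_5x3):
        X, y = fixture_5x3
        fit = enet_fit(X, y, alpha=1.0, lam=1e6)
        assert np.allclose(fit.coef, 0)
        assert fit.intercept == pytest.approx(y.mean())
        assert np.allclose(fit.predict(X), y.mean())

    def test_ridge_closed_form(self, fixture_5x3):
        X, y = fixture_5x3
        lam = 0.7
        fit = enet_fit(X, y, alpha=0.0, lam=lam, tol=1e-12)
        Xs, mu, sd = _standardize(X)
        n = len(y)
        yc = y - y.mean()
        b_std = np.linalg.solve(Xs.T @ Xs / n + lam * np.eye(3), Xs.T @ yc / n)
        coef = b_std / sd
        assert np.max(np.abs(fit.coef - coef)) < 1e-8
        assert fit.intercept == pytest.approx(y.mean() - coef @ mu, abs=1e-8)

    def test_ols_closed_form(self, fixture_5x3):
        X, y = fixture_5x3
        fit = enet_fit(X, y, alpha=0.5, lam=0.0, tol=1e-12)
        A = np.hstack([np.ones((len(y), 1)), X])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.max(np.abs(fit.coef - sol[1:])) < 1e-8
        assert fit.intercept == pytest.approx(sol[0], abs=1e-8)

    def test_matches_reference_solver(self, fixture_5x3):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = fixture_5x3
        alpha, lam = 0.5, 0.3
        Xs, mu, sd = _standardize(X)
        ref = sklearn_linear.ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-12,
            max_iter=100_000,
        ).fit(Xs, y)
        fit = enet_fit(X, y, alpha=alpha, lam=lam, tol=1e-12)
        assert np.max(np.abs(fit.coef_std - ref.coef_)) < 1e-6

    def test_objective_non_increasing(self, fixture_5x3):
        X, y = fixture_5x3
        fit = enet_fit(X, y, alpha=0.3, lam=0.1)
        diffs = np.diff(fit.objective)
        assert (diffs <= 1e-10).all()

    def test_l1_norm_shrinks_with_lambda(self, fixture_5x3):
        X, y = fixture_5x3
        for alpha in (0.5, 1.0):
            norms = [
                np.abs(enet_fit(X, y, alpha, lam).coef_std).sum()
                for lam in (0.0, 0.1, 1.0, 10.0, 100.0)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_missing_values_rejected(self, fixture_5x3):
        X, y = fixture_5x3
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            enet_fit(Xbad, y, 0.5, 0.1)


@pytest.fixture(scope="module")
def data_20():
    rng = np.random.default_rng(8)
    X = rng.normal(50, 8, size=(20, 4))
    y = 20 + X @ np.array([0.4, -0.2, 0.1, 0.0]) + rng.normal(0, 1, 20)
    return X, y


class TestLoocvGridSearch:
    def test_single_point_grid(self, data_20):
        X, y = data_20
        cfg = TrainConfig(alpha_grid=(0.3,), lambda_grid=(0.5,))
        a, l, surface = loocv_grid_search(X, y, cfg)
        assert (a, l) == (0.3, 0.5)
        assert len(surface) == 1

    def test_surface_equals_direct_recomputation(self, data_20):
        X, y = data_20
        cfg = TrainConfig(alpha_grid=(0.1, 1.0), lambda_grid=(0.05, 1.0))
        _, _, surface = loocv_grid_search(X, y, cfg)
        n = len(y)
        for _, row in surface.iterrows():
            se = 0.0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                fit = enet_fit(X[mask], y[mask], row["alpha"], row["lambda"])
                se += (fit.predict(X[i:i + 1])[0] - y[i]) ** 2
            assert row["cv_mse"] == pytest.approx(se / n, rel=1e-6)

    def test_cv_error_lower_at_small_lambda_on_clean_signal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(15, 3))
        y = X @ np.array([2.0, -1.0, 0.5])  # noise-free linear signal
        cfg = TrainConfig(alpha_grid=(0.5,), lambda_grid=(1e-4, 1e4))
        a, l, surface = loocv_grid_search(X, y, cfg)
        small = surface.loc[surface["lambda"] == 1e-4, "cv_mse"].iloc[0]
        huge = surface.loc[surface["lambda"] == 1e4, "cv_mse"].iloc[0]
        assert small < huge
        assert l == 1e-4

    def test_ties_break_toward_stronger_regularization(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(10, 2))
        y = np.full(10, 42.0)  # constant response: every grid point ties
        cfg = TrainConfig(alpha_grid=(0.2, 0.8), lambda_grid=(0.1, 1.0, 5.0))
        a, l, _ = loocv_grid_search(X, y, cfg)
        assert (a, l) == (0.2, 5.0)


class TestSplitCohort:
    def test_fraction_and_coverage(self):
        ages = sample_cohort(CohortSpec(n=191, seed=1))["age"].to_numpy()
        train, test = split_cohort(ages, 0.7, seed=2)
        assert len(train) in (133, 134)
        assert len(train) + len(test) == 191
        assert set(train) & set(test) == set()
        # per-stratum share within one sample of the target fraction
        strata = (np.floor(ages / 10) * 10).astype(int)
        for s in np.unique(strata):
            idx = set(np.where(strata == s)[0])
            n_train = len(idx & set(train))
            assert abs(n_train - 0.7 * len(idx)) <= 1.0

    def test_seed_deterministic(self):
        ages = np.linspace(20, 79, 60)
        a = split_cohort(ages, 0.7, seed=9)
        b = split_cohort(ages, 0.7, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


@pytest.fixture(scope="module")
def synthetic_cohort():
    model = bundled_clock()
    gen = GenerativeClock.from_model(model, intercept=10.0, beta_noise_sd=3.0)
    cohort = sample_cohort(CohortSpec(n=100, seed=21))
    ages = cohort["age"].to_numpy()
    X = cohort_beta_matrix(gen, ages, np.random.default_rng(22))
    return gen, X, ages


class TestTrainClock:
    def test_loocv_mae_on_noisy_betas(self, synthetic_cohort):
        gen, X, ages = synthetic_cohort
        cfg = TrainConfig(alpha_grid=(0.01, 0.5), lambda_grid=(0.01, 0.1, 1.2),
                          seed=1)
        result = train_clock(X, ages, cfg)
        assert result.loocv_metrics.mae <= 3.0
        assert len(result.loocv_predictions) == len(ages)

    def test_test_set_size_matches_fraction(self, synthetic_cohort):
        gen, X, ages = synthetic_cohort
        cfg = TrainConfig(alpha_grid=(0.5,), lambda_grid=(0.1,), seed=1)
        result = train_clock(X, ages, cfg)
        n_strata = len(np.unique((np.floor(ages / 10) * 10).astype(int)))
        assert abs(result.test_metrics.n - 0.3 * len(ages)) <= 0.5 * n_strata

    def test_noise_free_recovery_of_generating_coefficients(self):
        model = bundled_clock()
        gen = GenerativeClock.from_model(model, intercept=10.0,
                                         beta_noise_sd=0.0)
        ages = sample_cohort(CohortSpec(n=60, seed=31))["age"].to_numpy()
        X = cohort_beta_matrix(gen, ages, np.random.default_rng(32))
        cfg = TrainConfig(alpha_grid=(0.01,), lambda_grid=(1e-6,), seed=3,
                          tol=1e-10)
        result = train_clock(X, ages, cfg)
        dev = np.abs(np.array(result.model.coefficients)
                     - np.array(model.coefficients))
        assert dev.max() < 0.01
        assert result.model.intercept == pytest.approx(10.0, abs=0.5)


class TestPredictAge:
    def test_constant_model(self):
        sites = [CpGSite("NA", "C1", "chr1", 100)]
        model = ClockModel(sites=sites, coefficients=[0.0], intercept=40.0)
        pred = predict_age(model, np.array([[12.0], [99.0]]))
        assert np.allclose(pred, 40.0)

    def test_exact_inversion_of_generative_betas(self, clock_model):
        gen = GenerativeClock.from_model(clock_model, beta_noise_sd=0.0)
        ages = np.array([25.0, 44.0, 63.0, 71.0])
        X = cohort_beta_matrix(gen, ages, np.random.default_rng(1))
        pred = predict_age(gen.truth_model, X)
        assert np.max(np.abs(pred - ages)) < 1e-9

    def test_linearity_in_single_beta(self, clock_model):
        gen = GenerativeClock.from_model(clock_model, beta_noise_sd=0.0)
        X = cohort_beta_matrix(gen, [50.0], np.random.default_rng(2))
        X2 = X.copy()
        X2[0, 3] += 7.5
        delta = (predict_age(gen.truth_model, X2)
                 - predict_age(gen.truth_model, X))[0]
        assert delta == pytest.approx(clock_model.coefficients[3] * 7.5)

    def test_scale_conversion_is_invisible(self, clock_model):
        gen = GenerativeClock.from_model(clock_model, beta_noise_sd=2.0)
        X = cohort_beta_matrix(gen, [30.0, 60.0], np.random.default_rng(3))
        as_fraction = gen.truth_model.rescaled("fraction_0_1")
        assert np.allclose(
            predict_age(gen.truth_model, X), predict_age(as_fraction, X)
        )

    def test_missing_intercept_refused(self, clock_model):
        with pytest.raises(ValueError, match="calibrate"):
            predict_age(clock_model, np.zeros((1, 25)))

    def test_missing_cpg_named(self, clock_model, regions):
        import pandas as pd

        frame = pd.DataFrame(np.full((1, 24), 50.0),
                             columns=[s.key for s in clock_model.sites][:-1])
        model = ClockModel(sites=clock_model.sites,
                           coefficients=clock_model.coefficients,
                           intercept=0.0)
        with pytest.raises(KeyError, match="chr7:130734398"):
            predict_age(model, frame)


class TestCalibrateIntercept:
    def test_single_sample_exact(self, clock_model):
        betas = np.full((1, 25), 50.0)
        cal = calibrate_intercept(clock_model, betas, [44.0])
        assert predict_age(cal, betas)[0] == pytest.approx(44.0)

    def test_idempotent(self, clock_model):
        rng = np.random.default_rng(5)
        betas = rng.uniform(20, 80, size=(9, 25))
        ages = rng.uniform(25, 75, size=9)
        once = calibrate_intercept(clock_model, betas, ages)
        twice = calibrate_intercept(once, betas, ages)
        assert twice.intercept == once.intercept
        assert twice.provenance == once.provenance

    def test_median_robust_to_symmetric_outliers(self, clock_model):
        rng = np.random.default_rng(6)
        betas = rng.uniform(20, 80, size=(11, 25))
        ages = rng.uniform(25, 75, size=11)
        base = calibrate_intercept(clock_model, betas, ages)
        betas_out = np.vstack([betas, betas[:1], betas[:1]])
        ages_out = np.concatenate([ages, [ages[0] + 500, ages[0] - 500]])
        spiked = calibrate_intercept(clock_model, betas_out, ages_out)
        assert spiked.intercept == pytest.approx(base.intercept)

    def test_empty_calibration_rejected(self, clock_model):
        with pytest.raises(ValueError, match="at least one"):
            calibrate_intercept(clock_model, np.zeros((0, 25)), [])


class TestEvaluate:
    def test_perfect_predictions(self):
        actual = np.array([30.0, 40.0, 55.0, 61.0])
        rep = evaluate(actual, actual)
        assert rep.mae == 0.0
        assert rep.success_rate == 1.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_five_year_boundary_inclusive(self):
        actual = np.array([30.0, 40.0, 55.0])
        rep = evaluate(actual + 5.0, actual)
        assert rep.success_rate == 1.0
        assert rep.mae == 5.0

    def test_hand_computed_six_pair_fixture(self):
        predicted = np.array([25.0, 33.0, 41.0, 58.0, 66.0, 79.0])
        actual = np.array([23.0, 36.0, 40.0, 52.0, 65.0, 71.0])
        rep = evaluate(predicted, actual)
        # |err| = [2, 3, 1, 6, 1, 8]; sorted [1,1,2,3,6,8] -> median 2.5
        assert rep.mae == 2.5
        assert rep.mean_ae == pytest.approx(21 / 6)
        assert rep.success_rate == pytest.approx(4 / 6)
        # Pearson r recomputed from the definition
        pc = predicted - predicted.mean()
        ac = actual - actual.mean()
        r = (pc @ ac) / np.sqrt((pc @ pc) * (ac @ ac))
        assert rep.pearson_r == pytest.approx(r)
        assert 0 < rep.p_value < 0.01
        # decades 20/30/40/50/60/70 each hold one sample
        assert rep.per_category_mae == {
            20: 2.0, 30: 3.0, 40: 1.0, 50: 6.0, 60: 1.0, 70: 8.0,
        }

    def test_degenerate_correlation_absent(self):
        rep = evaluate([50.0], [48.0])
        assert rep.pearson_r is None and rep.p_value is None
        assert rep.n == 1
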