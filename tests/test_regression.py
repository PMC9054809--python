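"""Train/test protocol, model fitting, selection and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from mitocup.regression_suite import (diagnostics, fit_additive, fit_lm,
                                      fit_poly, log_transform_responses,
                                      split_data)


def _frame(n=100, seed=0, fn=lambda x: 2 * x, noise=0.1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=n)
    y = fn(x) + rng.normal(0, noise, size=n)
    return pd.DataFrame({"x": x, "y": y})


class TestSplitData:
    def test_split_sizes_and_disjointness(self):
        df = _frame(100)
        train, test, removed = split_data(df, "y", train_fraction=0.75, seed=1)
        assert len(train) == 75 and len(test) == 25 and removed == 0
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(df.index)

    def test_same_seed_identical_split(self):
        df = _frame(80)
        t1 = split_data(df, "y", seed=7)[0]
        t2 = split_data(df, "y", seed=7)[0]
        assert list(t1.index) == list(t2.index)

    def test_extreme_outlier_removed(self):
        df = _frame(60)
        df.loc[0, "y"] = df["y"].median() + 100 * (
            df["y"].quantile(0.75) - df["y"].quantile(0.25))
        train, test, removed = split_data(df, "y")
        assert removed == 1
        assert 0 not in set(train.index) | set(test.index)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_data(_frame(20), "y", train_fraction=1.5)


class TestFitLm:
    def test_recovers_exact_line(self):
        df = _frame(200, noise=1e-9)
        fit = fit_lm(df, "y", "x")
        assert fit.coefficients[1] == pytest.approx(2.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_response(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        fit = fit_lm(df, "y", "x")
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-9)

    def test_test_rmse_computed(self):
        df = _frame(100)
        train, test, _ = split_data(df, "y", seed=3)
        fit = fit_lm(train, "y", "x", test=test)
        assert np.isfinite(fit.rmse_test)


class TestFitPoly:
    def test_forced_degree_one_matches_lm(self):
        df = _frame(80, seed=2)
        lm = fit_lm(df, "y", "x")
        pm = fit_poly(df, "y", "x", degree=1)
        assert pm.fitted == pytest.approx(lm.fitted, abs=1e-8)

    @pytest.mark.parametrize("criterion", ["aic", "bic"])
    def test_cubic_degree_recovered(self, criterion):
        """Seeded cubic data selects degree 3 under both criteria."""
        rng = np.random.default_rng(123)
        x = rng.uniform(-1, 1, size=200)
        y = x ** 3
        df = pd.DataFrame({"x": x, "y": y + rng.normal(0, 0.05 * np.ptp(y),
                                                       size=200)})
        fit = fit_poly(df, "y", "x", criterion=criterion)
        assert fit.degree == 3

    def test_aic_reported(self):
        fit = fit_poly(_frame(50), "y", "x", degree=2)
        assert np.isfinite(fit.aic) and fit.adj_r2 <= fit.r2 + 1e-12


class TestFitAdditive:
    def test_near_linear_data_stays_close_to_lm(self):
        df = _frame(150, seed=5, noise=0.05)
        lm = fit_lm(df, "y", "x")
        am = fit_additive(df, "y", "x")
        assert am.r2 >= lm.r2 - 0.02
        xs = np.linspace(0.1, 0.9, 20)
        assert np.max(np.abs(am.predict(xs) - lm.predict(xs))) < 0.1

    def test_captures_nonlinearity_better_than_lm(self):
        df = _frame(250, seed=6, fn=lambda x: np.sin(6 * x), noise=0.05)
        train, test, _ = split_data(df, "y", seed=1)
        lm = fit_lm(train, "y", "x", test=test)
        am = fit_additive(train, "y", "x", test=test)
        assert am.rmse_test < lm.rmse_test
        assert am.edf > 2.0

    def test_matching_class_wins_on_simulated_data(self):
        """Linear truth -> LM/PM(1) best or tied; smooth nonlinear truth ->
        AM/PM beat LM on held-out RMSE in most replicates."""
        wins = 0
        reps = 5
        for seed in range(reps):
            df = _frame(220, seed=seed, fn=lambda x: np.cos(5 * x), noise=0.08)
            train, test, _ = split_data(df, "y", seed=seed)
            lm = fit_lm(train, "y", "x", test=test)
            am = fit_additive(train, "y", "x", test=test)
            if am.rmse_test < lm.rmse_test:
                wins += 1
        assert wins > reps / 2


class TestDiagnostics:
    def test_breusch_pagan_null_uniformity(self):
        """Type-I error of the heteroscedasticity test ~5% under the null."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(0, 1, size=150)
            y = 1 + 2 * x + rng.normal(0, 0.5, size=150)
            fit = fit_lm(pd.DataFrame({"x": x, "y": y}), "y", "x")
            if diagnostics(fit).bp_p < 0.05 or False:
                rejections += 1
        rate = rejections / reps
        assert 0.01 < rate < 0.10

    def test_breusch_pagan_power(self):
        """Variance proportional to the mean is detected."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            x = rng.uniform(0.2, 1, size=200)
            y = 2 * x + rng.normal(0, 1, size=200) * x * 1.5
            fit = fit_lm(pd.DataFrame({"x": x, "y": y}), "y", "x")
            if diagnostics(fit).bp_p < 0.05:
                hits += 1
        assert hits / 50 > 0.5

    def test_qq_vectors_track_normal_residuals(self):
        rng = np.random.default_rng(13)
        df = _frame(500, seed=13, noise=0.3)
        fit = fit_lm(df, "y", "x")
        d = diagnostics(fit)
        # ordered residuals hug the theoretical line
        corr = np.corrcoef(d.qq_theoretical, d.qq_ordered)[0, 1]
        assert corr > 0.99
        assert d.sw_p > 0.001

    def test_too_few_residuals(self):
        df = _frame(30)
        fit = fit_lm(df, "y", "x")
        fit.residuals = fit.residuals[:2]
        with pytest.raises(ValueError):
            diagnostics(fit)


class TestLogTransform:
    def test_values(self):
        df = pd.DataFrame({"adS": [np.e, 1.0], "adN": [1.0, 1.0],
                           "omega": [1.0, 1.0]})
        out, dropped = log_transform_responses(df)
        assert dropped == 0
        assert out["log_adS"].tolist() == pytest.approx([1.0, 0.0])

    def test_zero_rows_dropped_and_counted(self):
        df = pd.DataFrame({"adS": [1.0, 0.0, 2.0, 0.0]})
        out, dropped = log_transform_responses(df, responses=("adS",))
        assert dropped == 2 and len(out) == 2

    def test_all_nonpositive_rejected(self):
        df = pd.DataFrame({"adS": [0.0, -1.0]})
        with pytest.raises(ValueError):
            log_transform_responses(df, responses=("adS",))
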