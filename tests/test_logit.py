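"""Penalized score-space logistic regression and coefficient functions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from oracles import scipy_penalized_logistic
from wallcast.basis import BSplineBasis
from wallcast.fpca import fit_fpca, project_scores
from wallcast.logit import (
    coefficient_function,
    fit_flr,
    fit_ridge_logistic,
    penalized_loglik,
    predict_prob,
    variable_importance,
)
from wallcast.represent import FunctionalDataset


def _score_frame(rng, n, cols):
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)


def _labels(rng, X, b, b0=0.0):
    return (rng.random(len(X)) < expit(b0 + X @ b)).astype(float)


class TestRidgeSolver:
    def test_huge_lambda_shrinks_to_prevalence(self, rng):
        X = rng.normal(size=(400, 5))
        y = (rng.random(400) < 0.3).astype(float)
        params, _ = fit_ridge_logistic(X, y, lam=1e8)
        assert np.abs(params[1:]).max() <= 1e-4
        prev_logit = np.log(y.mean() / (1 - y.mean()))
        assert abs(params[0] - prev_logit) <= 1e-3

    def test_antisymmetric_dataset_zero_intercept(self, rng):
        Z = rng.normal(size=(100, 4))
        X = np.vstack([Z, -Z])
        y = np.concatenate([np.ones(100), np.zeros(100)])
        params, _ = fit_ridge_logistic(X, y, lam=0.5)
        assert abs(params[0]) <= 1e-6

    def test_recovers_known_coefficients(self, rng):
        b_true = np.array([1.0, -0.8, 0.5, 0.0, 0.3, -0.2, 0.7, -0.4])
        X = rng.normal(size=(5000, 8))
        y = _labels(rng, X, b_true)
        params, _ = fit_ridge_logistic(X, y, lam=1e-4)
        rel = np.linalg.norm(params[1:] - b_true) / np.linalg.norm(b_true)
        assert rel <= 0.10

    def test_agrees_with_generic_convex_optimizer(self, rng):
        for _ in range(3):
            X = rng.normal(size=(300, 8))
            y = _labels(rng, X, rng.normal(size=8))
            lam = 10 ** rng.uniform(-3, 2)
            ours, _ = fit_ridge_logistic(X, y, lam)
            oracle = scipy_penalized_logistic(X, y, lam)
            assert np.abs(ours - oracle).max() <= 1e-5

    def test_objective_monotone(self, rng):
        X = rng.normal(size=(300, 6))
        y = _labels(rng, X, rng.normal(size=6))
        _, trajectory = fit_ridge_logistic(X, y, lam=0.01)
        diffs = np.diff(trajectory)
        assert (diffs >= -1e-8 * (1 + np.abs(trajectory[:-1]))).all()

    def test_norm_decreases_with_lambda(self, rng):
        X = rng.normal(size=(500, 6))
        y = _labels(rng, X, rng.normal(size=6))
        norms = []
        for lam in (0.01, 0.1, 1.0, 10.0, 100.0):
            params, _ = fit_ridge_logistic(X, y, lam)
            norms.append(np.linalg.norm(params[1:]))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


class TestFitFLR:
    def test_single_class_error(self, rng):
        df = _score_frame(rng, 50, ["a:1"])
        with pytest.raises(ValueError, match="both classes"):
            fit_flr(df, np.ones(50))

    def test_cv_ties_pick_larger_lambda(self, rng):
        # two-class but pure-noise scores: many lambdas tie; the chosen one
        # must be the largest among those attaining the best mean F1
        df = _score_frame(rng, 80, ["a:1", "b:1"])
        y = np.array([0, 1] * 40, dtype=float)
        model = fit_flr(df, y, lambda_grid=np.array([1.0, 1.0]), n_folds=4, seed=0)
        assert model.lam == 1.0
        tab = model.cv_table
        best = tab["mean_f1"].max()
        assert model.lam == tab.loc[tab["mean_f1"] >= best - 1e-12, "lambda"].max()

    def test_model_groups_coefficients_by_variable(self, rng):
        df = _score_frame(rng, 300, ["a:1", "a:2", "b:1", "c:1", "c:2", "c:3"])
        y = _labels(rng, df.to_numpy(), np.array([1.0, 0, 0, 0, 0, 0]))
        model = fit_flr(df, y, lambda_grid=np.array([0.1]), n_folds=3)
        assert [len(model.coefs[v]) for v in ["a", "b", "c"]] == [2, 1, 3]


class TestPredict:
    def test_zero_scores_give_intercept(self, rng):
        df = _score_frame(rng, 200, ["a:1", "b:1"])
        y = _labels(rng, df.to_numpy(), np.array([0.8, -0.5]))
        model = fit_flr(df, y, lambda_grid=np.array([0.1]), n_folds=3)
        p = predict_prob(model, pd.DataFrame(np.zeros((1, 2)), columns=df.columns))
        assert p[0] == pytest.approx(expit(model.intercept))

    def test_antisymmetry(self, rng):
        df = _score_frame(rng, 200, ["a:1", "b:1"])
        y = _labels(rng, df.to_numpy(), np.array([0.8, -0.5]))
        model = fit_flr(df, y, lambda_grid=np.array([0.1]), n_folds=3)
        model.intercept = 0.0
        p1 = predict_prob(model, df)
        p2 = predict_prob(model, -df)
        assert p2 == pytest.approx(1.0 - p1)

    def test_missing_column_error(self, rng):
        df = _score_frame(rng, 100, ["a:1", "b:1"])
        y = np.array([0, 1] * 50, dtype=float)
        model = fit_flr(df, y, lambda_grid=np.array([1.0]), n_folds=2)
        with pytest.raises(ValueError, match="b:1"):
            predict_prob(model, df[["a:1"]])


class TestCoefficientFunction:
    @pytest.fixture()
    def fitted(self, rng):
        basis = BSplineBasis(10)
        coef = rng.normal(size=(60, 10))
        ds = FunctionalDataset("step_length", [f"r{i}" for i in range(60)], coef, basis)
        fb = fit_fpca(ds, variance_threshold=0.95)
        scores = project_scores(fb, ds)
        y = (rng.random(60) < expit(scores.iloc[:, 0] * 0.5)).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        model = fit_flr(scores, y, lambda_grid=np.array([0.5]), n_folds=3)
        return model, fb

    def test_unit_first_component_gives_u1(self, fitted):
        model, fb = fitted
        model.coefs["step_length"] = np.eye(fb.K)[0]
        cf = coefficient_function(model, fb, "step_length")
        assert cf.coefficients == pytest.approx(fb.eigenfunction_coefs[:, 0])

    def test_zero_coefficients_zero_function(self, fitted):
        model, fb = fitted
        model.coefs["step_length"] = np.zeros(fb.K)
        cf = coefficient_function(model, fb, "step_length")
        assert cf.coefficients == pytest.approx(np.zeros(fb.basis.n_basis), abs=1e-12)

    def test_parseval_norm_identity(self, fitted):
        model, fb = fitted
        cf = coefficient_function(model, fb, "step_length")
        l2 = fb.basis.l2_norm(cf.coefficients)
        assert l2 == pytest.approx(np.linalg.norm(model.coefs["step_length"]), abs=1e-8)

    def test_unretained_variable_error(self, fitted):
        model, fb = fitted
        with pytest.raises(ValueError, match="not in the fitted model"):
            coefficient_function(model, fb, "cadence")


class TestImportance:
    def test_single_active_variable_ranked_first(self, rng):
        df = _score_frame(rng, 200, ["a:1", "b:1", "c:1"])
        y = np.array([0, 1] * 100, dtype=float)
        model = fit_flr(df, y, lambda_grid=np.array([1.0]), n_folds=2)
        model.coefs = {"a": np.zeros(1), "b": np.array([2.0]), "c": np.zeros(1)}
        ranking = variable_importance(model)
        assert ranking[0][0] == "b"
        # ties broken alphabetically
        assert [v for v, _ in ranking[1:]] == ["a", "c"]

    def test_score_rescaling_caveat(self, rng):
        # scaling one variable's scores by c and its coefficients by 1/c
        # leaves predictions unchanged but divides its reported norm by c
        df = _score_frame(rng, 150, ["a:1", "b:1"])
        y = _labels(rng, df.to_numpy(), np.array([1.0, -0.6]))
        model = fit_flr(df, y, lambda_grid=np.array([0.2]), n_folds=3)
        p1 = predict_prob(model, df)
        norm_before = dict(variable_importance(model))["a"]
        c = 4.0
        scaled = df.copy()
        scaled["a:1"] *= c
        model.coefs["a"] = model.coefs["a"] / c
        p2 = predict_prob(model, scaled)
        assert p2 == pytest.approx(p1, abs=1e-12)
        assert dict(variable_importance(model))["a"] == pytest.approx(norm_before / c)
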