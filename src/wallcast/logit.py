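"""Functional logistic regression in FPC-score space with an L2 penalty.

The scalar-on-function model

    log pi/(1-pi) = beta0 + sum_j int_T x_j(t) beta_j(t) dt

with each coefficient function expanded in that variable's FPCA
eigenfunctions, ``beta_j(t) = b_j' u_j(t)``, reduces by orthonormality to a
plain logistic regression on the FPC scores:

    log pi/(1-pi) = beta0 + sum_j z_j' b_j .

Parameters are fit by maximising the penalized log-likelihood
``LL - (lambda/2) * sum_j ||b_j||^2`` (intercept unpenalized) with damped
Newton iterations; the ridge weight ``lambda`` is chosen by stratified
K-fold cross-validation maximising out-of-fold F1 for the HTW class, ties
resolved toward the larger (more regularised) ``lambda``.  Variable
importance is the L2 norm ``||b_j||``, which by Parseval equals the L2(T)
norm of the coefficient function ``beta_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .fpca import FPCABasis
from .screen import variable_of

DEFAULT_LAMBDA_GRID = np.logspace(-4, 3, 20)


@dataclass
class CoefficientFunction:
    """Distance-varying effect beta_j(t) of one variable on the HTW log-odds."""

    variable_name: str
    coefficients: np.ndarray  # spline coefficients of beta_j
    l2_norm: float


@dataclass
class FLRModel:
    """Fitted score-space functional logistic regression."""

    intercept: float
    coefs: dict[str, np.ndarray]          # variable -> b_j (length K_j)
    lam: float
    columns: list[str]                    # score columns in model order
    retained_variables: list[str]
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def coef_vector(self) -> np.ndarray:
        return np.concatenate([self.coefs[v] for v in self.retained_variables])

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "lambda": self.lam,
            "columns": self.columns,
            "retained_variables": self.retained_variables,
            "coefs": {v: b.tolist() for v, b in self.coefs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FLRModel":
        return cls(
            intercept=float(d["intercept"]),
            coefs={v: np.array(b, dtype=float) for v, b in d["coefs"].items()},
            lam=float(d["lambda"]),
            columns=list(d["columns"]),
            retained_variables=list(d["retained_variables"]),
        )


def penalized_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Penalized Bernoulli log-likelihood; params = [beta0, b]."""
    eta = params[0] + X @ params[1:]
    # log(1 + e^eta) computed stably
    ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    return ll - 0.5 * lam * float(params[1:] @ params[1:])


def fit_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, list[float]]:
    """Damped Newton maximisation of the penalized log-likelihood.

    Returns ``(params, objective_trajectory)`` with params = [beta0, b].
    The trajectory is non-decreasing (step halving); convergence is declared
    at penalized-gradient infinity norm <= tol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    params = np.zeros(d + 1)
    params[0] = _safe_logit(y.mean())
    trajectory = [penalized_loglik(params, X, y, lam)]
    for _ in range(max_iter):
        eta = params[0] + X @ params[1:]
        p = expit(eta)
        resid = y - p
        grad = np.concatenate([[resid.sum()], X.T @ resid - lam * params[1:]])
        if np.max(np.abs(grad)) <= tol:
            return params, trajectory
        w = np.maximum(p * (1.0 - p), 1e-12)
        Xw = X * w[:, None]
        H = np.empty((d + 1, d + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = H[1:, 0] = Xw.sum(axis=0)
        H[1:, 1:] = X.T @ Xw + lam * np.eye(d)
        step = np.linalg.solve(H, grad)
        # backtracking keeps the objective monotone up to float rounding
        t = 1.0
        base = trajectory[-1]
        slack = 1e-9 * (1.0 + abs(base))
        for _ in range(40):
            obj = penalized_loglik(params + t * step, X, y, lam)
            if obj >= base - slack:
                break
            t /= 2.0
        params = params + t * step
        trajectory.append(penalized_loglik(params, X, y, lam))
    grad_norm = np.max(np.abs(grad))
    raise RuntimeError(
        f"ridge logistic fit did not converge at lambda={lam:g} "
        f"(gradient norm {grad_norm:.2e} after {max_iter} iterations)"
    )


def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return float(np.log(p / (1.0 - p)))


def f1_score_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 with the positive (HTW) class = 1; 0 when no positives anywhere."""
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def fit_flr(
    scores: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> FLRModel:
    """Fit the score-space model with lambda chosen by F1 cross-validation."""
    y = np.asarray(labels, dtype=float)
    if scores.shape[0] != len(y):
        raise ValueError("labels and score rows are misaligned")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be strictly positive")
    lambda_grid = np.sort(lambda_grid)

    X = scores.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    mean_f1 = []
    for lam in lambda_grid:
        f1s = []
        for tr, te in folds:
            params, _ = fit_ridge_logistic(X[tr], y[tr], lam)
            prob = expit(params[0] + X[te] @ params[1:])
            f1s.append(f1_score_binary(y[te], (prob >= threshold).astype(float)))
        mean_f1.append(float(np.mean(f1s)))
    # ascending grid + ">=" selects the largest lambda among exact ties
    best = 0
    for i in range(1, len(lambda_grid)):
        if mean_f1[i] >= mean_f1[best]:
            best = i
    lam = float(lambda_grid[best])

    params, _ = fit_ridge_logistic(X, y, lam)
    variables = list(dict.fromkeys(variable_of(c) for c in scores.columns))
    coefs: dict[str, np.ndarray] = {}
    pos = 0
    b = params[1:]
    for v in variables:
        k = sum(1 for c in scores.columns if variable_of(c) == v)
        coefs[v] = b[pos : pos + k].copy()
        pos += k
    return FLRModel(
        intercept=float(params[0]),
        coefs=coefs,
        lam=lam,
        columns=list(scores.columns),
        retained_variables=variables,
        cv_table=pd.DataFrame({"lambda": lambda_grid, "mean_f1": mean_f1}),
    )


def predict_prob(model: FLRModel, scores: pd.DataFrame) -> np.ndarray:
    """HTW probabilities pi_i = logistic(beta0 + sum_j z_ij' b_j)."""
    missing = [c for c in model.columns if c not in scores.columns]
    if missing:
        raise ValueError(f"score table is missing model columns: {missing}")
    X = scores[model.columns].to_numpy(dtype=float)
    return expit(model.intercept + X @ model.coef_vector)


def coefficient_function(
    model: FLRModel, fbasis: FPCABasis, variable_name: str
) -> CoefficientFunction:
    """Spline representation of beta_j(t) = sum_k b_jk u_jk(t)."""
    if variable_name not in model.coefs:
        raise ValueError(f"variable {variable_name!r} is not in the fitted model")
    if fbasis.variable_name != variable_name:
        raise ValueError(
            f"FPCA basis is for {fbasis.variable_name!r}, not {variable_name!r}"
        )
    b = model.coefs[variable_name]
    if len(b) != fbasis.K:
        raise ValueError(
            f"coefficient length {len(b)} does not match FPCA K={fbasis.K}"
        )
    coefs = fbasis.eigenfunction_coefs[:, : fbasis.K] @ b
    return CoefficientFunction(variable_name, coefs, float(np.linalg.norm(b)))


def variable_importance(model: FLRModel) -> list[tuple[str, float]]:
    """Variables ranked by ||b_j||_2, descending; ties broken alphabetically."""
    norms = [(v, float(np.linalg.norm(model.coefs[v]))) for v in model.retained_variables]
    return sorted(norms, key=lambda t: (-t[1], t[0]))
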