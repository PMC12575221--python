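"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the rule statements, not from
the package implementation: a run-length pace-label scanner, a random
profile generator, a trapezoid-weighted grid PCA, and a generic convex
optimizer fit of the penalized logistic objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def brute_force_label(
    start_m: np.ndarray,
    length_m: np.ndarray,
    pace: np.ndarray,
    htw_ratio: float = 1.25,
    htw_run_km: float = 5.0,
    nhtw_ratio: float = 1.10,
    nhtw_run_km: float = 10.0,
) -> str:
    """Straightforward re-implementation of the three-way pace-label rule."""
    start_m = np.asarray(start_m, float)
    length_m = np.asarray(length_m, float)
    end_m = start_m + length_m
    if end_m[-1] < 30000.0 - 1e-9:
        return "EXCLUDED"
    # base pace: overlap-weighted mean over [5, 20) km
    num = den = 0.0
    for s, e, p in zip(start_m, end_m, pace):
        ov = min(e, 20000.0) - max(s, 5000.0)
        if ov > 0:
            num += p * ov
            den += ov
    base = num / den
    sel = [i for i in range(len(start_m)) if start_m[i] >= 25000.0 - 1e-9]
    ratios = [pace[i] / base for i in sel]
    lens = [length_m[i] for i in sel]

    def longest(cond) -> float:
        best = cur = 0.0
        for r, L in zip(ratios, lens):
            cur = cur + L if cond(r) else 0.0
            best = max(best, cur)
        return best / 1000.0

    if longest(lambda r: r > htw_ratio) >= htw_run_km:
        return "HTW"
    if longest(lambda r: r < nhtw_ratio) >= nhtw_run_km:
        return "NHTW"
    return "EXCLUDED"


def random_profile(rng: np.random.Generator):
    """A random contiguous segment pace profile stressing the label rule.

    Mixes 250/500/1000 m segments (so window edges at 5/20/25 km straddle
    segments), places relative-pace stretches at and around the 1.10 / 1.25
    thresholds with run lengths near 5 / 10 km, and varies total distance
    across the 30 km coverage limit and the finish line.
    """
    base = rng.uniform(280.0, 440.0)
    total = rng.choice([28000.0, 38000.0, 40500.0, 42195.0, 43000.0])
    starts, lengths, ratios = [], [], []
    pos = 0.0
    # stretches of near-threshold relative pace with near-critical lengths
    stretch_end = 0.0
    stretch_ratio = 1.0
    while pos < total:
        if pos >= stretch_end:
            stretch_ratio = rng.choice(
                [0.95, 1.0, 1.05, 1.09, 1.10, 1.12, 1.20, 1.25, 1.251, 1.30, 1.40]
            )
            stretch_end = pos + rng.choice([1500.0, 4000.0, 5000.0, 5250.0, 9750.0, 10000.0, 12000.0])
        seg = rng.choice([250.0, 500.0, 1000.0])
        seg = min(seg, total - pos)
        starts.append(pos)
        lengths.append(seg)
        ratios.append(stretch_ratio * (1.0 + rng.normal(0.0, 0.002)))
        pos += seg
    return (
        np.array(starts),
        np.array(lengths),
        base * np.array(ratios),
    )


def grid_pca(values: np.ndarray, grid: np.ndarray):
    """Trapezoid-weighted PCA of functions sampled on a grid.

    ``values`` is (n, len(grid)).  Returns eigenvalues (descending) and
    eigenfunctions as rows of grid values, L2-orthonormal under the
    trapezoid weights.
    """
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    n = values.shape[0]
    centered = values - values.mean(axis=0)
    B = centered * np.sqrt(w)
    cov = B.T @ B / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    funcs = (vecs[:, order] / np.sqrt(w)[:, None]).T
    return vals, funcs, w


def scipy_penalized_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Generic convex-optimizer fit of the L2-penalized logistic objective."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def neg_obj(params):
        eta = params[0] + X @ params[1:]
        nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
        return nll + 0.5 * lam * float(params[1:] @ params[1:])

    def grad(params):
        eta = params[0] + X @ params[1:]
        r = expit(eta) - y
        return np.concatenate([[r.sum()], X.T @ r + lam * params[1:]])

    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(neg_obj, x0, jac=grad, method="BFGS",
                   options={"gtol": 1e-11, "maxiter": 2000})
    return res.x
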