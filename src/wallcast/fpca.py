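"""Functional principal component analysis in B-spline coefficient space.

For each gait variable the training curves ``x_i(t)`` are decomposed as

    x_i(t) = mu(t) + sum_k z_ik u_k(t)

where ``mu`` is the cross-runner mean function, the eigenfunctions ``u_k``
are L2-orthonormal on the domain T, and the FPC scores ``z_ik`` are the L2
projections of the centred curves onto the eigenfunctions.  With curves held
as spline coefficient vectors ``c_i`` and basis Gram matrix ``G``, the L2
geometry is exact: the eigenproblem of the sample covariance of ``G^{1/2}
c_i`` yields eigenfunction coefficients ``G^{-1/2} w_k`` and scores
``(c_i - c_mean)^T G u_k``.

The retained count K is the smallest number of components whose cumulative
eigenvalue fraction reaches the variance threshold (0.99 by default), with a
floor of 1 and a cap of min(n_basis, n_train - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BSplineBasis
from .represent import FunctionalDataset


@dataclass
class FPCABasis:
    """Fitted FPCA system of one variable.

    ``eigenfunction_coefs`` is (n_basis, K): column k holds the spline
    coefficients of eigenfunction u_k.  ``eigenvalues`` is the full spectrum
    (descending); ``variance_explained`` its cumulative fractions.
    """

    variable_name: str
    basis: BSplineBasis
    mean_coef: np.ndarray
    eigenfunction_coefs: np.ndarray
    eigenvalues: np.ndarray
    K: int
    variance_explained: np.ndarray
    gram: np.ndarray = field(repr=False)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def to_dict(self) -> dict:
        return {
            "variable_name": self.variable_name,
            "basis": self.basis.to_dict(),
            "mean_coef": self.mean_coef.tolist(),
            "eigenfunction_coefs": self.eigenfunction_coefs.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "K": int(self.K),
            "variance_explained": self.variance_explained.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPCABasis":
        basis = BSplineBasis.from_dict(d["basis"])
        return cls(
            variable_name=d["variable_name"],
            basis=basis,
            mean_coef=np.array(d["mean_coef"]),
            eigenfunction_coefs=np.array(d["eigenfunction_coefs"]),
            eigenvalues=np.array(d["eigenvalues"]),
            K=int(d["K"]),
            variance_explained=np.array(d["variance_explained"]),
            gram=basis.gram(),
        )


def _gram_sqrt(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(G)
    vals = np.maximum(vals, 1e-14)
    root = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
    inv_root = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return root, inv_root


def fit_fpca(train: FunctionalDataset, variance_threshold: float = 0.99) -> FPCABasis:
    """Estimate mean function, eigenfunctions and eigenvalues from training curves."""
    C = np.asarray(train.coefficients, dtype=float)
    n = C.shape[0]
    if n < 2:
        raise ValueError("FPCA requires at least 2 training functions")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(f"variance_threshold {variance_threshold} not in (0, 1]")
    basis = train.basis
    G = basis.gram()
    root, inv_root = _gram_sqrt(G)

    mean_coef = C.mean(axis=0)
    Cc = C - mean_coef
    M = Cc @ root
    cov = (M.T @ M) / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    U = inv_root @ vecs[:, order]  # spline coefficients of eigenfunctions

    # deterministic eigenfunction signs: make the integral of u_k positive,
    # falling back to the largest-magnitude coefficient when it vanishes
    b_int = G.sum(axis=1)
    for k in range(U.shape[1]):
        integral = float(U[:, k] @ b_int)
        if abs(integral) > 1e-10:
            sign = np.sign(integral)
        else:
            sign = np.sign(U[np.argmax(np.abs(U[:, k])), k]) or 1.0
        U[:, k] *= sign

    total = vals.sum()
    if total <= 0.0:
        cumfrac = np.ones_like(vals)
        K = 1
    else:
        cumfrac = np.cumsum(vals) / total
        K = int(np.searchsorted(cumfrac, variance_threshold - 1e-12) + 1)
    K = max(1, min(K, basis.n_basis, n - 1))

    return FPCABasis(
        variable_name=train.variable_name,
        basis=basis,
        mean_coef=mean_coef,
        eigenfunction_coefs=U,
        eigenvalues=vals,
        K=K,
        variance_explained=cumfrac,
        gram=G,
    )


def project_scores(fbasis: FPCABasis, functions: FunctionalDataset) -> pd.DataFrame:
    """FPC scores z_ik = <x_i - mu, u_k> for the retained K components.

    Returns a DataFrame indexed by runner id with columns ``variable:k``
    (components 1-based).
    """
    if functions.basis != fbasis.basis:
        raise ValueError(
            f"basis mismatch: functions use {functions.basis}, FPCA fitted on {fbasis.basis}"
        )
    Cc = np.asarray(functions.coefficients, dtype=float) - fbasis.mean_coef
    Z = Cc @ fbasis.gram @ fbasis.eigenfunction_coefs[:, : fbasis.K]
    cols = [f"{fbasis.variable_name}:{k + 1}" for k in range(fbasis.K)]
    return pd.DataFrame(Z, index=pd.Index(functions.runner_ids, name="runner_id"), columns=cols)


def reconstruct(fbasis: FPCABasis, scores: np.ndarray) -> np.ndarray:
    """Spline coefficients of mu + sum_k z_k u_k for one score vector."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (fbasis.K,):
        raise ValueError(f"score length {scores.shape} does not match K={fbasis.K}")
    return fbasis.mean_coef + fbasis.eigenfunction_coefs[:, : fbasis.K] @ scores


def score_frame(
    fpca_bases: dict[str, FPCABasis], datasets: dict[str, FunctionalDataset]
) -> pd.DataFrame:
    """Concatenate per-variable FPC scores into one runner x (variable:k) table."""
    frames = [project_scores(fpca_bases[v], datasets[v]) for v in fpca_bases]
    return pd.concat(frames, axis=1)
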