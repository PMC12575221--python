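"""Functional representation of segment-sampled gait series.

Segment averages (observed at segment midpoints) are converted into smooth
functions of race distance by unpenalized least-squares B-spline fitting.
The basis dimension per variable is chosen by generalized cross-validation
(GCV) on training runners; regularisation comes from dimension selection
rather than a roughness penalty.  Standardization is pointwise on an
equispaced evaluation grid (default 512 points), with mean and SD functions
estimated from the training set only and applied unchanged to test curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BSplineBasis

#: default evaluation grid size for standardization and exports
DEFAULT_GRID = 512

#: the basis specification type used throughout (order, knots, domain)
BasisSpec = BSplineBasis


@dataclass
class FunctionalSample:
    """One runner-variable curve as a coefficient vector in a spline basis."""

    runner_id: str
    variable_name: str
    coefficients: np.ndarray
    basis: BSplineBasis

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.n_basis,):
            raise ValueError(
                f"coefficient length {self.coefficients.shape} does not match "
                f"basis dimension {self.basis.n_basis}"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.basis.evaluate(self.coefficients, x)

    def to_dict(self) -> dict:
        return {
            "runner_id": self.runner_id,
            "variable": self.variable_name,
            "basis": self.basis.to_dict(),
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionalSample":
        return cls(
            d["runner_id"],
            d["variable"],
            np.asarray(d["coefficients"], dtype=float),
            BSplineBasis.from_dict(d["basis"]),
        )


@dataclass
class FunctionalDataset:
    """Curves of one variable for many runners, sharing a basis.

    ``coefficients`` is (n_runners, n_basis), rows aligned with ``runner_ids``.
    """

    variable_name: str
    runner_ids: list[str]
    coefficients: np.ndarray
    basis: BSplineBasis

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.basis.evaluate(self.coefficients, x)

    def subset(self, ids: list[str]) -> "FunctionalDataset":
        index = {r: i for i, r in enumerate(self.runner_ids)}
        rows = [index[r] for r in ids]
        return FunctionalDataset(
            self.variable_name, list(ids), self.coefficients[rows], self.basis
        )

    def sample(self, runner_id: str) -> FunctionalSample:
        i = self.runner_ids.index(runner_id)
        return FunctionalSample(runner_id, self.variable_name, self.coefficients[i], self.basis)


@dataclass
class StandardizationParams:
    """Pointwise mean and SD functions of one variable on the evaluation grid."""

    variable_name: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    SD_FLOOR = 1e-8


def gcv_score(y: np.ndarray, design: np.ndarray) -> float:
    """GCV of an unpenalized least-squares fit: (SSE/m) / (1 - df/m)^2.

    ``df`` equals the basis dimension (the trace of the hat matrix for a
    full-rank unpenalized fit).
    """
    m, p = design.shape
    if p >= m:
        raise ValueError(f"GCV undefined for df={p} >= m={m} observations")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    return (sse / m) / (1.0 - p / m) ** 2


def select_basis_dimension(
    series_set: list[tuple[np.ndarray, np.ndarray]],
    candidates: list[int],
    domain: tuple[float, float] = (0.0, 21.0),
    order: int = 4,
) -> int:
    """Pick the basis dimension minimising mean GCV over a set of series.

    ``series_set`` is a list of ``(x, y)`` pairs (segment midpoints in km and
    segment values).  Series with no more observation points than the largest
    candidate are skipped with a warning.  Ties favour the smaller dimension.
    """
    if not candidates:
        raise ValueError("empty candidate list for basis dimension selection")
    candidates = sorted(set(int(c) for c in candidates))
    top = max(candidates)
    usable = [(np.asarray(x, float), np.asarray(y, float)) for x, y in series_set]
    kept = [(x, y) for x, y in usable if len(x) > top]
    skipped = len(usable) - len(kept)
    if skipped:
        warnings.warn(
            f"{skipped} series with <= {top} observations skipped in GCV selection"
        )
    if not kept:
        raise ValueError(
            f"no series has more than max(candidates)={top} observation points"
        )

    # group series sharing an abscissa so each design matrix is built once
    groups: dict[tuple, list[np.ndarray]] = {}
    for x, y in kept:
        groups.setdefault(tuple(np.round(x, 9)), []).append(y)

    mean_gcv = []
    for p in candidates:
        basis = BSplineBasis(n_basis=p, domain=domain, order=order)
        scores: list[float] = []
        for xkey, ys in groups.items():
            x = np.array(xkey)
            B = basis.design_matrix(x)
            m = len(x)
            Y = np.column_stack(ys)
            coef, *_ = np.linalg.lstsq(B, Y, rcond=None)
            sse = np.sum((Y - B @ coef) ** 2, axis=0)
            scores.extend((sse / m) / (1.0 - p / m) ** 2)
        mean_gcv.append(float(np.mean(scores)))
    return candidates[int(np.argmin(mean_gcv))]


def smooth_to_function(
    x: np.ndarray,
    y: np.ndarray,
    basis: BSplineBasis,
    runner_id: str = "",
    variable_name: str = "",
) -> FunctionalSample:
    """Least-squares projection of one segment series onto the spline basis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < basis.n_basis:
        raise ValueError(
            f"{len(x)} observation points < n_basis={basis.n_basis}; "
            "use a smaller basis"
        )
    B = basis.design_matrix(x)
    coef, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
    if rank < basis.n_basis:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {basis.n_basis}); "
            "reduce n_basis or use denser sampling"
        )
    return FunctionalSample(runner_id, variable_name, coef, basis)


def smooth_dataset(
    x: np.ndarray,
    values: np.ndarray,
    basis: BSplineBasis,
    runner_ids: list[str],
    variable_name: str,
) -> FunctionalDataset:
    """Vectorised smoothing of many runners sharing one abscissa.

    ``values`` is (n_runners, m) with columns aligned to ``x``.
    """
    B = basis.design_matrix(np.asarray(x, dtype=float))
    if B.shape[0] < basis.n_basis:
        raise ValueError(
            f"{B.shape[0]} observation points < n_basis={basis.n_basis}"
        )
    coef, _, rank, _ = np.linalg.lstsq(B, np.asarray(values, float).T, rcond=None)
    if rank < basis.n_basis:
        raise ValueError(f"rank-deficient design (rank {rank} < {basis.n_basis})")
    return FunctionalDataset(variable_name, list(runner_ids), coef.T, basis)


def standardize(
    train: FunctionalDataset,
    apply_to: FunctionalDataset | None = None,
    n_grid: int = DEFAULT_GRID,
) -> tuple[FunctionalDataset, StandardizationParams]:
    """Pointwise z-scoring of curves using training-set mean/SD functions.

    The standardized grid values are refit into the same spline basis so that
    downstream FPCA stays in coefficient space.  Pointwise SD uses ddof=1; a
    zero SD anywhere is floored at 1e-8 with a warning.
    """
    if len(train.runner_ids) == 0:
        raise ValueError(f"no training curves for variable {train.variable_name!r}")
    basis = train.basis
    grid = basis.grid(n_grid)
    train_vals = train.evaluate(grid)
    mean = train_vals.mean(axis=0)
    sd = train_vals.std(axis=0, ddof=1) if len(train.runner_ids) > 1 else np.zeros_like(mean)
    if np.any(sd < StandardizationParams.SD_FLOOR):
        warnings.warn(
            f"zero pointwise SD for variable {train.variable_name!r}; floored at 1e-8"
        )
        sd = np.maximum(sd, StandardizationParams.SD_FLOOR)
    params = StandardizationParams(train.variable_name, grid, mean, sd)
    target = train if apply_to is None else apply_to
    return apply_standardization(target, params), params


def standardized_values(
    dataset: FunctionalDataset, params: StandardizationParams
) -> np.ndarray:
    """Exact pointwise z-scores of the curves on the standardization grid."""
    return (dataset.evaluate(params.grid) - params.mean) / params.sd


def apply_standardization(
    dataset: FunctionalDataset, params: StandardizationParams
) -> FunctionalDataset:
    """Transform curves with previously estimated mean/SD functions.

    The z-scored grid values are projected back onto the spline basis (a
    z-scored curve is a ratio of splines, not itself a spline); the projection
    is linear, so the training mean of the returned curves is exactly zero.
    """
    basis = dataset.basis
    B = basis.design_matrix(params.grid)
    z = standardized_values(dataset, params)
    coef, *_ = np.linalg.lstsq(B, z.T, rcond=None)
    return FunctionalDataset(dataset.variable_name, list(dataset.runner_ids), coef.T, basis)
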