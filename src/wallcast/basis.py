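"""B-spline basis systems on the race-distance domain.

All functional objects in this package (smoothed gait curves, FPCA mean and
eigenfunctions, logistic coefficient functions) are represented as coefficient
vectors in a clamped B-spline basis on an interval of race distance,
``T = [0, 21] km`` by default.  The Gram matrix of the basis is computed
exactly (Gauss-Legendre per knot span), which lets inner products,
L2 norms and FPCA orthonormalisation be done in coefficient space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis with equally spaced interior knots.

    Parameters
    ----------
    n_basis : int
        Number of basis functions (>= order).
    domain : tuple of float
        Interval of race distance in km.
    order : int
        Spline order (degree + 1); 4 = cubic.
    """

    n_basis: int
    domain: tuple[float, float] = (0.0, 21.0)
    order: int = 4
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_basis < self.order:
            raise ValueError(
                f"n_basis={self.n_basis} must be >= spline order {self.order}"
            )
        a, b = self.domain
        if not b > a:
            raise ValueError(f"domain {self.domain} must be an increasing interval")
        n_interior = self.n_basis - self.order
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        knots = np.concatenate([np.full(self.order, a), interior, np.full(self.order, b)])
        object.__setattr__(self, "knots", knots)

    @property
    def degree(self) -> int:
        return self.order - 1

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``x`` -> (len(x), n_basis)."""
        x = np.asarray(x, dtype=float)
        a, b = self.domain
        if x.min() < a - 1e-12 or x.max() > b + 1e-12:
            raise ValueError(
                f"evaluation points outside basis domain [{a}, {b}]: "
                f"range [{x.min()}, {x.max()}]"
            )
        x = np.clip(x, a, b)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def evaluate(self, coefficients: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Evaluate the spline(s) with given coefficient vector(s) at ``x``.

        ``coefficients`` may be a single vector or a (n, n_basis) matrix; the
        result is (len(x),) or (n, len(x)) accordingly.
        """
        B = self.design_matrix(x)
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.ndim == 1:
            return B @ coefficients
        return coefficients @ B.T

    def gram(self) -> np.ndarray:
        """Exact Gram matrix G_ij = int_T B_i(t) B_j(t) dt.

        Gauss-Legendre with ``order`` nodes per knot span is exact for the
        degree 2*(order-1) product integrand.
        """
        nodes, weights = leggauss(self.order)
        spans = np.unique(self.knots)
        G = np.zeros((self.n_basis, self.n_basis))
        for lo, hi in zip(spans[:-1], spans[1:]):
            mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
            x = mid + half * nodes
            B = self.design_matrix(x)
            G += (B.T * (half * weights)) @ B
        return G

    def integrals(self) -> np.ndarray:
        """int_T B_i(t) dt for each basis function.

        By the partition of unity, these are the row sums of the Gram matrix.
        """
        return self.gram().sum(axis=1)

    def grid(self, n: int = 512) -> np.ndarray:
        """Equispaced evaluation grid of ``n`` points over the domain."""
        return np.linspace(self.domain[0], self.domain[1], n)

    def inner_products(self, coef_a: np.ndarray, coef_b: np.ndarray) -> np.ndarray:
        """L2 inner products on T between splines given by coefficient rows."""
        G = self.gram()
        coef_a = np.atleast_2d(np.asarray(coef_a, dtype=float))
        coef_b = np.atleast_2d(np.asarray(coef_b, dtype=float))
        out = coef_a @ G @ coef_b.T
        return out.squeeze()

    def l2_norm(self, coefficients: np.ndarray) -> float:
        """L2(T) norm of the spline with the given coefficients."""
        val = self.inner_products(coefficients, coefficients)
        return float(np.sqrt(max(float(val), 0.0)))

    def to_dict(self) -> dict:
        return {
            "n_basis": self.n_basis,
            "domain": list(self.domain),
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return cls(n_basis=int(d["n_basis"]), domain=tuple(d["domain"]), order=int(d["order"]))


def simpson_weights(grid: np.ndarray) -> np.ndarray:
    """Composite Simpson weights for an odd-length equispaced grid."""
    n = len(grid)
    if n < 3 or n % 2 == 0:
        raise ValueError("Simpson quadrature needs an odd number of grid points >= 3")
    h = (grid[-1] - grid[0]) / (n - 1)
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-rule weights for an arbitrary sorted grid."""
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w
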