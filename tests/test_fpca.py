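"""FPCA: eigen-system correctness, projection, reconstruction, recovery."""

import numpy as np
import pytest

from oracles import grid_pca
from wallcast.basis import BSplineBasis
from wallcast.fpca import fit_fpca, project_scores, reconstruct
from wallcast.represent import FunctionalDataset


def _orthonormal_modes(basis: BSplineBasis, rng, k=3) -> np.ndarray:
    """k L2-orthonormal smooth functions as spline coefficient columns."""
    G = basis.gram()
    raw = rng.normal(size=(basis.n_basis, k))
    coefs = np.zeros_like(raw)
    for j in range(k):
        v = raw[:, j]
        for i in range(j):
            v = v - (coefs[:, i] @ G @ v) * coefs[:, i]
        coefs[:, j] = v / np.sqrt(v @ G @ v)
    return coefs


def three_mode_dataset(rng, n=500, p=12, sds=(3.0, 1.0, 0.5), noise=0.1):
    basis = BSplineBasis(p)
    modes = _orthonormal_modes(basis, rng)
    mean = rng.normal(size=p)
    loadings = rng.normal(size=(n, 3)) * np.array(sds)
    coef = mean + loadings @ modes.T + noise * rng.normal(size=(n, p))
    ids = [f"r{i}" for i in range(n)]
    return FunctionalDataset("x", ids, coef, basis), modes, loadings


class TestFitFPCA:
    def test_identical_functions_degenerate(self):
        basis = BSplineBasis(8)
        ds = FunctionalDataset("x", list("abc"), np.tile(np.arange(8.0), (3, 1)), basis)
        fb = fit_fpca(ds)
        assert fb.K == 1
        assert fb.eigenvalues == pytest.approx(np.zeros(len(fb.eigenvalues)), abs=1e-12)
        assert project_scores(fb, ds).to_numpy() == pytest.approx(0.0, abs=1e-8)

    def test_rank_one_structure(self, rng):
        basis = BSplineBasis(10)
        f = _orthonormal_modes(basis, rng, k=1)[:, 0]
        a = rng.normal(size=20)
        ds = FunctionalDataset(
            "x", [f"r{i}" for i in range(20)], 1.5 + np.outer(a, f), basis
        )
        fb = fit_fpca(ds)
        assert fb.K == 1
        assert fb.variance_explained[0] == pytest.approx(1.0, abs=1e-10)
        G = basis.gram()
        cosine = abs(fb.eigenfunction_coefs[:, 0] @ G @ f)
        assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_pca_oracle(self, rng):
        ds, _, _ = three_mode_dataset(rng)
        fb = fit_fpca(ds)
        grid = ds.basis.grid(512)
        vals_oracle, funcs_oracle, w = grid_pca(ds.evaluate(grid), grid)
        keep = 3
        assert fb.eigenvalues[:keep] == pytest.approx(vals_oracle[:keep], rel=1e-3)
        for k in range(keep):
            ours = ds.basis.evaluate(fb.eigenfunction_coefs[:, k], grid)
            cos = abs(np.sum(w * ours * funcs_oracle[k]))
            cos /= np.sqrt(np.sum(w * ours**2) * np.sum(w * funcs_oracle[k] ** 2))
            assert cos >= 0.999

    def test_orthonormality_and_decorrelation(self, rng):
        ds, _, _ = three_mode_dataset(rng)
        fb = fit_fpca(ds)
        G = ds.basis.gram()
        U = fb.eigenfunction_coefs[:, : fb.K]
        assert U.T @ G @ U == pytest.approx(np.eye(fb.K), abs=1e-6)
        Z = project_scores(fb, ds).to_numpy()
        cov = np.cov(Z, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() / np.abs(np.diag(cov)).max() <= 1e-6
        # training score means vanish
        assert np.abs(Z.mean(axis=0)).max() <= 1e-6 * Z.std(axis=0).max()

    def test_variance_bookkeeping(self, rng):
        ds, _, _ = three_mode_dataset(rng)
        fb = fit_fpca(ds)
        G = ds.basis.gram()
        Cc = ds.coefficients - ds.coefficients.mean(axis=0)
        total = np.trace(Cc @ G @ Cc.T) / (len(ds.runner_ids) - 1)
        assert fb.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_mode_recovery(self, rng):
        ds, modes, _ = three_mode_dataset(rng, n=500, noise=0.1)
        fb = fit_fpca(ds)
        G = ds.basis.gram()
        for k in range(3):
            cos = abs(modes[:, k] @ G @ fb.eigenfunction_coefs[:, k])
            assert cos >= 0.95

    def test_too_few_functions(self):
        basis = BSplineBasis(8)
        ds = FunctionalDataset("x", ["a"], np.ones((1, 8)), basis)
        with pytest.raises(ValueError, match="at least 2"):
            fit_fpca(ds)


class TestProjectReconstruct:
    def test_training_scores_consistent(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=50)
        fb = fit_fpca(ds)
        z1 = project_scores(fb, ds).to_numpy()
        z2 = project_scores(fb, ds).to_numpy()
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_project_mean_is_zero(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=50)
        fb = fit_fpca(ds)
        mean_ds = FunctionalDataset("x", ["mu"], fb.mean_coef[None, :], ds.basis)
        assert project_scores(fb, mean_ds).to_numpy() == pytest.approx(0.0, abs=1e-8)

    def test_project_mean_plus_two_u1(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=50)
        fb = fit_fpca(ds)
        x = fb.mean_coef + 2.0 * fb.eigenfunction_coefs[:, 0]
        z = project_scores(fb, FunctionalDataset("x", ["a"], x[None, :], ds.basis)).to_numpy()[0]
        expected = np.zeros(fb.K)
        expected[0] = 2.0
        assert z == pytest.approx(expected, abs=1e-8)

    def test_reconstruct_zero_scores_gives_mean(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=50)
        fb = fit_fpca(ds)
        assert reconstruct(fb, np.zeros(fb.K)) == pytest.approx(fb.mean_coef)

    def test_reconstruction_error_equals_discarded_energy(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=200)
        fb = fit_fpca(ds, variance_threshold=0.99)
        G = ds.basis.gram()
        Z = project_scores(fb, ds).to_numpy()
        errs = []
        for i in range(len(ds.runner_ids)):
            recon = reconstruct(fb, Z[i])
            diff = ds.coefficients[i] - recon
            errs.append(diff @ G @ diff)
        n = len(ds.runner_ids)
        mean_err = np.sum(errs) / (n - 1)
        discarded = fb.eigenvalues[fb.K :].sum()
        assert mean_err == pytest.approx(discarded, rel=1e-6)
        assert mean_err <= (1 - 0.99) * fb.eigenvalues.sum() + 1e-12

    def test_full_rank_exact_recovery(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=40, p=8, noise=0.05)
        fb = fit_fpca(ds, variance_threshold=1.0)
        fb.K = min(ds.basis.n_basis, len(ds.runner_ids) - 1)
        Z = project_scores(fb, ds).to_numpy()
        recon = reconstruct(fb, Z[0])
        assert recon == pytest.approx(ds.coefficients[0], abs=1e-8)

    def test_basis_mismatch_error(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=20)
        fb = fit_fpca(ds)
        other = FunctionalDataset("x", ["a"], np.ones((1, 9)), BSplineBasis(9))
        with pytest.raises(ValueError, match="basis mismatch"):
            project_scores(fb, other)

    def test_score_length_mismatch_error(self, rng):
        ds, _, _ = three_mode_dataset(rng, n=20)
        fb = fit_fpca(ds)
        with pytest.raises(ValueError, match="score length"):
            reconstruct(fb, np.zeros(fb.K + 1))
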