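"""Penalized FPCA: oracles, orthonormality, score and reconstruction laws."""

import numpy as np
import pytest
from scipy.linalg import eigh

from irfda.fpca import (
    FpcaBasis,
    compute_scores,
    covariance_function,
    explained_variance,
    fit_fpca,
    mean_function,
    reconstruct,
    select_k,
    trapezoid_weights,
)
from irfda.preprocess import SpectralGrid

from conftest import make_gridded


def dense_pca_oracle(data, k):
    """Independent unpenalized FPCA: eigh of W^1/2 Sigma W^1/2.

    Returns (eigenvalues, eigenfunctions rows) with quadrature-normalized,
    sign-fixed eigenfunctions.
    """
    x = np.vstack([gs.values for gs in data])
    grid = data[0].grid
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    xc = x - x.mean(axis=0)
    sigma = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = eigh(sigma * np.outer(sw, sw))
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0, None)
    phi = (evecs[:, order] / sw[:, None]).T
    for i in range(phi.shape[0]):
        j = int(np.argmax(np.abs(phi[i])))
        if phi[i, j] < 0:
            phi[i] = -phi[i]
    return lam, phi


def rank1_dataset(grid, n, seed=0):
    """Curves mean + f * phi with known smooth phi and random scalars f."""
    rng = np.random.default_rng(seed)
    x = grid.wavenumbers
    span = x[-1] - x[0]
    mean = np.exp(-0.5 * ((x - x[0] - 0.3 * span) / (0.1 * span)) ** 2)
    phi = np.sin(2 * np.pi * (x - x[0]) / span)
    w = trapezoid_weights(grid)
    phi = phi / np.sqrt(np.sum(w * phi**2))  # unit quadrature norm
    f = rng.normal(0.0, 2.0, size=n)
    data = [make_gridded(mean + f[i] * phi, grid, f"r{i}") for i in range(n)]
    return data, mean, phi, f


class TestMeanAndCovariance:
    def test_mean_of_single_spectrum_is_itself(self, small_grid, rng):
        y = rng.normal(size=small_grid.points)
        np.testing.assert_array_equal(mean_function([make_gridded(y, small_grid)]), y)

    def test_mean_of_opposite_pair_is_zero(self, small_grid, rng):
        y = rng.normal(size=small_grid.points)
        data = [make_gridded(y, small_grid), make_gridded(-y, small_grid)]
        np.testing.assert_allclose(mean_function(data), 0.0, atol=1e-15)

    def test_mean_matches_loop_oracle(self, smooth_dataset):
        data = smooth_dataset(20)
        looped = np.zeros(data[0].grid.points)
        for gs in data:
            looped = looped + gs.values
        looped /= len(data)
        np.testing.assert_allclose(mean_function(data), looped, atol=1e-12)

    def test_covariance_of_identical_pair_is_zero(self, small_grid, rng):
        y = rng.normal(size=small_grid.points)
        data = [make_gridded(y, small_grid), make_gridded(y.copy(), small_grid)]
        np.testing.assert_allclose(covariance_function(data, y), 0.0, atol=1e-15)

    def test_covariance_matches_double_loop(self):
        grid = SpectralGrid(500, 512, 4)  # p = 4
        vecs = np.array([[1.0, 2.0, 0.5, -1.0], [0.0, 1.0, 1.5, 2.0], [3.0, -1.0, 0.0, 1.0]])
        data = [make_gridded(v, grid, f"t{i}") for i, v in enumerate(vecs)]
        mean = vecs.mean(axis=0)
        expected = np.zeros((4, 4))
        for s in range(4):
            for t in range(4):
                expected[s, t] = sum(
                    (vecs[i, s] - mean[s]) * (vecs[i, t] - mean[t]) for i in range(3)
                ) / 2.0
        got = covariance_function(data, mean)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.all(np.diag(got) >= 0)

    def test_covariance_needs_two(self, small_grid, rng):
        y = rng.normal(size=small_grid.points)
        with pytest.raises(ValueError):
            covariance_function([make_gridded(y, small_grid)], y)


class TestFitFpca:
    def test_zero_penalty_equals_dense_oracle(self, smooth_dataset):
        data = smooth_dataset(25)  # p = 80, n = 25
        basis = fit_fpca(data, penalty=0.0, k_max=10)
        lam, phi = dense_pca_oracle(data, 10)
        np.testing.assert_allclose(basis.eigenvalues, lam, atol=1e-8 * max(1, lam[0]))
        w = basis.quadrature_weights
        for k in range(10):
            if lam[k] < 1e-10 * lam[0]:
                continue
            ip = abs(np.sum(w * basis.eigenfunctions[k] * phi[k]))
            assert ip == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_recovery(self, small_grid):
        data, _, phi, _ = rank1_dataset(small_grid, n=40)
        basis = fit_fpca(data, penalty=0.0, k_max=5)
        w = basis.quadrature_weights
        ip = abs(np.sum(w * basis.eigenfunctions[0] * phi))
        assert ip >= 0.999
        assert basis.eigenvalues[1] <= 1e-8 * basis.eigenvalues[0]

    def test_eigenvalues_descending_nonnegative(self, smooth_dataset):
        basis = fit_fpca(smooth_dataset(15), penalty=1e-2, k_max=10)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)
        assert np.all(basis.eigenvalues >= 0)

    @pytest.mark.parametrize("penalty", [0.0, 1e-3, 1e-1, 10.0])
    def test_orthonormal_under_quadrature(self, smooth_dataset, penalty):
        basis = fit_fpca(smooth_dataset(20), penalty=penalty, k_max=8)
        w = basis.quadrature_weights
        gram = (basis.eigenfunctions * w) @ basis.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_penalty_monotonically_smooths_leading_component(self, smooth_dataset, rng):
        # jagged curves give the roughness penalty something to remove
        data = [
            make_gridded(gs.values + rng.normal(0, 0.3, size=gs.values.size), gs.grid)
            for gs in smooth_dataset(30)
        ]
        h = data[0].grid.step
        roughs = []
        for penalty in [0.0, 1e-1, 1.0, 10.0, 100.0]:
            basis = fit_fpca(data, penalty=penalty, k_max=3)
            d2 = np.diff(basis.eigenfunctions[0], 2) / h**2
            roughs.append(float(np.sum(d2**2) * h))
        # nonincreasing up to re-orthonormalization rounding
        for a, b in zip(roughs, roughs[1:]):
            assert b <= a * (1 + 1e-3)
        assert roughs[-1] < 0.5 * roughs[0]  # the ladder does smooth overall

    def test_sign_convention(self, smooth_dataset):
        basis = fit_fpca(smooth_dataset(12), penalty=0.0, k_max=5)
        for phi in basis.eigenfunctions:
            assert phi[np.argmax(np.abs(phi))] > 0

    def test_k_max_too_large_rejected(self, smooth_dataset):
        data = smooth_dataset(5)
        with pytest.raises(ValueError):
            fit_fpca(data, penalty=0.0, k_max=10)  # n - 1 = 4 < 10


class TestScores:
    def test_mean_spectrum_scores_zero(self, smooth_dataset):
        data = smooth_dataset(10)
        basis = fit_fpca(data, penalty=0.0, k_max=5)
        mean_gs = make_gridded(basis.mean, data[0].grid, "mean")
        sm = compute_scores(basis, [mean_gs], 5)
        np.testing.assert_allclose(sm.scores, 0.0, atol=1e-10)

    def test_rank_one_scores_recover_generators(self, small_grid):
        data, _, _, f = rank1_dataset(small_grid, n=60)
        basis = fit_fpca(data, penalty=0.0, k_max=3)
        sm = compute_scores(basis, data, 1)
        got = sm.scores[:, 0]
        sign = np.sign(np.sum(got * (f - f.mean())))
        centered = f - f.mean()
        np.testing.assert_allclose(sign * got, centered, rtol=0.01, atol=0.01)

    def test_score_columns_uncorrelated(self, smooth_dataset):
        data = smooth_dataset(200, seed=77)
        basis = fit_fpca(data, penalty=0.0, k_max=6)
        sm = compute_scores(basis, data, 6)
        c = np.cov(sm.scores, rowvar=False)
        scale = np.sqrt(np.outer(np.diag(c), np.diag(c)))
        off = (c / scale)[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_variance_decomposition(self, smooth_dataset):
        # sample variance of score column k equals lambda_k
        data = smooth_dataset(120, seed=5)
        basis = fit_fpca(data, penalty=0.0, k_max=5)
        sm = compute_scores(basis, data, 5)
        for k in range(5):
            var = np.sum(sm.scores[:, k] ** 2) / (len(data) - 1)
            assert var == pytest.approx(basis.eigenvalues[k], rel=0.02)

    def test_grid_mismatch_rejected(self, smooth_dataset, rng):
        basis = fit_fpca(smooth_dataset(10), penalty=0.0, k_max=3)
        other = SpectralGrid(500, 700, 4)
        gs = make_gridded(rng.normal(size=other.points), other)
        with pytest.raises(ValueError):
            compute_scores(basis, [gs], 3)


class TestSelectK:
    @pytest.mark.parametrize(
        "eigenvalues, threshold, expected",
        [
            ((3.0, 1.0), 0.7, 1),  # 3/4 = 0.75 >= 0.7
            ((1.0, 1.0, 1.0, 1.0, 1.0), 0.8, 4),  # 4/5 = 0.8
            ((5.0, 3.0, 1.0, 1.0), 0.8, 2),
        ],
    )
    def test_examples(self, eigenvalues, threshold, expected):
        assert select_k(np.array(eigenvalues), threshold) == expected

    def test_cumulative_proportions_monotone_end_at_one(self, rng):
        lam = np.sort(rng.uniform(0, 5, size=12))[::-1]
        cum = explained_variance(lam)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.zeros(4), 0.8)


class TestReconstruct:
    def test_k_zero_returns_mean(self, smooth_dataset):
        data = smooth_dataset(10)
        basis = fit_fpca(data, penalty=0.0, k_max=5)
        sm = compute_scores(basis, data, 5)
        rec = reconstruct(basis, sm, 0)
        for row in rec:
            np.testing.assert_array_equal(row, basis.mean)

    def test_rank_one_reconstruction_error_tiny(self, small_grid):
        data, _, _, _ = rank1_dataset(small_grid, n=40)
        basis = fit_fpca(data, penalty=0.0, k_max=3)
        sm = compute_scores(basis, data, 1)
        rec = reconstruct(basis, sm, 1)
        x = np.vstack([gs.values for gs in data])
        w = basis.quadrature_weights
        err = np.sum(w * (x - rec) ** 2)
        energy = np.sum(w * (x - basis.mean) ** 2)
        assert err < 1e-4 * energy

    def test_error_nonincreasing_in_k(self, smooth_dataset):
        data = smooth_dataset(25)
        basis = fit_fpca(data, penalty=0.0, k_max=10)
        sm = compute_scores(basis, data, 10)
        x = np.vstack([gs.values for gs in data])
        w = basis.quadrature_weights
        prev = np.inf
        for k in range(11):
            rec = reconstruct(basis, sm, k)
            err = float(np.sum(w * (x - rec) ** 2))
            assert err <= prev + 1e-9
            prev = err


class TestSerialization:
    def test_round_trip(self, smooth_dataset, tmp_path):
        basis = fit_fpca(smooth_dataset(12), penalty=1e-2, k_max=6)
        path = tmp_path / "basis.npz"
        basis.save(path)
        back = FpcaBasis.load(path)
        assert back.grid == basis.grid
        assert back.penalty == basis.penalty
        np.testing.assert_array_equal(back.mean, basis.mean)
        np.testing.assert_array_equal(back.eigenfunctions, basis.eigenfunctions)
        np.testing.assert_array_equal(back.eigenvalues, basis.eigenvalues)
        assert back.basis_id == basis.basis_id
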