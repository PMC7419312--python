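"""Roughness-penalized functional principal component analysis.

Spectra on the common grid are treated as discretized curves.  The sample
covariance operator is diagonalized under the trapezoid-rule inner product,
with smoothing imposed through a second-derivative roughness penalty via
the half-inverse construction: the symmetric eigenproblem is solved for

    (I + tau * R)^(-1/2)  W^(1/2) Sigma W^(1/2)  (I + tau * R)^(-1/2)

where W holds the quadrature weights and R discretizes the integrated
squared second derivative.  Eigenvectors are mapped back to grid functions
and re-orthonormalized under the quadrature inner product, so the returned
basis is orthonormal for every penalty (exactly the plain weighted PCA at
tau = 0).

PC scores are trapezoid-rule integrals of centered curves against the
eigenfunctions; the truncation order K is chosen as the smallest number of
components explaining a given fraction of total variance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .preprocess import GriddedSpectrum, SpectralGrid


@dataclass(frozen=True)
class FpcaBasis:
    """Mean function, eigenfunctions and eigenvalues on a common grid.

    Eigenfunctions are rows of ``eigenfunctions`` (one per component),
    orthonormal under the trapezoid inner product; eigenvalues are the
    variances carried by each component, descending and clamped at zero.
    """

    grid: SpectralGrid
    mean: np.ndarray
    eigenfunctions: np.ndarray  # (k_max, p)
    eigenvalues: np.ndarray  # (k_max,)
    penalty: float
    quadrature_weights: np.ndarray  # (p,)

    def __post_init__(self) -> None:
        p = self.grid.points
        if self.mean.shape != (p,):
            raise ValueError("mean length does not match grid")
        if self.eigenfunctions.shape[1] != p:
            raise ValueError("eigenfunction length does not match grid")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be descending")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be nonnegative")

    @property
    def k_max(self) -> int:
        return int(self.eigenvalues.size)

    @property
    def basis_id(self) -> str:
        """Content hash identifying this basis in downstream artifacts."""
        h = hashlib.sha256()
        for arr in (self.mean, self.eigenfunctions, self.eigenvalues):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(repr((self.grid.start, self.grid.stop, self.grid.step, self.penalty)).encode())
        return h.hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            grid=np.array([self.grid.start, self.grid.stop, self.grid.step]),
            mean=self.mean,
            eigenfunctions=self.eigenfunctions,
            eigenvalues=self.eigenvalues,
            penalty=np.array([self.penalty]),
            quadrature_weights=self.quadrature_weights,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FpcaBasis":
        with np.load(path) as z:
            g = z["grid"]
            return cls(
                grid=SpectralGrid(float(g[0]), float(g[1]), float(g[2])),
                mean=z["mean"],
                eigenfunctions=z["eigenfunctions"],
                eigenvalues=z["eigenvalues"],
                penalty=float(z["penalty"][0]),
                quadrature_weights=z["quadrature_weights"],
            )


@dataclass(frozen=True)
class ScoreMatrix:
    """PC scores: one row per compound, one column per component."""

    compound_ids: tuple[str, ...]
    scores: np.ndarray  # (n, K)

    @property
    def k(self) -> int:
        return int(self.scores.shape[1])


def trapezoid_weights(grid: SpectralGrid) -> np.ndarray:
    """Quadrature weights of the trapezoid rule on the uniform grid."""
    w = np.full(grid.points, grid.step)
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def _stack(data: list[GriddedSpectrum]) -> tuple[np.ndarray, SpectralGrid]:
    if not data:
        raise ValueError("empty dataset")
    grid = data[0].grid
    for gs in data[1:]:
        if gs.grid != grid:
            raise ValueError("all spectra must share one grid")
    return np.vstack([gs.values for gs in data]), grid


def mean_function(data: list[GriddedSpectrum]) -> np.ndarray:
    """Pointwise sample mean curve across compounds."""
    x, _ = _stack(data)
    return x.mean(axis=0)


def covariance_function(data: list[GriddedSpectrum], mean: np.ndarray) -> np.ndarray:
    """Sample covariance surface sigma(s, t) with divisor n - 1."""
    x, _ = _stack(data)
    if x.shape[0] < 2:
        raise ValueError("covariance requires at least 2 spectra")
    xc = x - mean
    sigma = xc.T @ xc / (x.shape[0] - 1)
    return 0.5 * (sigma + sigma.T)


def second_difference_operator(grid: SpectralGrid) -> np.ndarray:
    """Central-difference approximation of the second derivative, (p-2) x p."""
    p = grid.points
    h = grid.step
    d2 = np.zeros((p - 2, p))
    idx = np.arange(p - 2)
    d2[idx, idx] = 1.0
    d2[idx, idx + 1] = -2.0
    d2[idx, idx + 2] = 1.0
    return d2 / h**2


def fit_fpca(
    data: list[GriddedSpectrum],
    penalty: float = 1e-2,
    k_max: int = 50,
) -> FpcaBasis:
    """Estimate the penalized FPCA basis from preprocessed spectra.

    ``penalty`` weights the integrated squared second derivative of the
    eigenfunctions (on the rescaled-absorbance scale); ``k_max`` components
    are retained, at most min(n - 1, p).
    """
    x, grid = _stack(data)
    n, p = x.shape
    if n < 2:
        raise ValueError("FPCA requires at least 2 spectra")
    if k_max > min(n - 1, p):
        raise ValueError(f"k_max={k_max} exceeds min(n-1, p)={min(n - 1, p)}")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")

    mean = x.mean(axis=0)
    sigma = covariance_function(data, mean)
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)

    m = sigma * np.outer(sw, sw)
    if penalty > 0:
        d2 = second_difference_operator(grid)
        # R approximates the integral of the squared second derivative
        rough = grid.step * (d2.T @ d2)
        evals_r, vecs_r = eigh(rough)
        half_inv = vecs_r @ ((1.0 / np.sqrt(1.0 + penalty * np.clip(evals_r, 0, None)))[:, None] * vecs_r.T)
        m = half_inv @ m @ half_inv
        m = 0.5 * (m + m.T)

    evals, evecs = eigh(m)
    order = np.argsort(evals)[::-1][:k_max]
    lam = np.clip(evals[order], 0.0, None)
    u = evecs[:, order]

    if penalty > 0:
        u = half_inv @ u
    phi = u / sw[:, None]  # back to grid functions
    phi = _orthonormalize(phi, w)

    # deterministic sign: largest-magnitude grid value positive
    for k in range(phi.shape[1]):
        j = int(np.argmax(np.abs(phi[:, k])))
        if phi[j, k] < 0:
            phi[:, k] = -phi[:, k]

    return FpcaBasis(
        grid=grid,
        mean=mean,
        eigenfunctions=phi.T.copy(),
        eigenvalues=lam,
        penalty=penalty,
        quadrature_weights=w,
    )


def _orthonormalize(phi: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Modified Gram-Schmidt under the quadrature inner product.

    A no-op (up to rounding) at zero penalty; restores exact quadrature
    orthonormality after penalized smoothing.
    """
    phi = phi.copy()
    k = phi.shape[1]
    for j in range(k):
        for i in range(j):
            proj = float(np.sum(w * phi[:, i] * phi[:, j]))
            phi[:, j] -= proj * phi[:, i]
        norm = float(np.sqrt(np.sum(w * phi[:, j] ** 2)))
        if norm <= 1e-12:
            raise ValueError(f"eigenfunction {j} degenerated during orthonormalization")
        phi[:, j] /= norm
    return phi


def compute_scores(basis: FpcaBasis, data: list[GriddedSpectrum], k: int | None = None) -> ScoreMatrix:
    """Trapezoid-rule PC scores of centered curves against the basis."""
    x, grid = _stack(data)
    if grid != basis.grid:
        raise ValueError("data grid does not match basis grid")
    if k is None:
        k = basis.k_max
    if k > basis.k_max:
        raise ValueError(f"K={k} exceeds available components {basis.k_max}")
    xc = x - basis.mean
    scores = (xc * basis.quadrature_weights) @ basis.eigenfunctions[:k].T
    return ScoreMatrix(tuple(gs.compound_id for gs in data), scores)


def select_k(eigenvalues: np.ndarray, threshold: float = 0.80) -> int:
    """Smallest K whose cumulative variance proportion reaches the threshold."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-10) or np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be nonnegative and descending")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    cum = np.cumsum(lam) / total
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def explained_variance(eigenvalues: np.ndarray) -> np.ndarray:
    """Cumulative proportions of variance explained (ends at 1)."""
    lam = np.asarray(eigenvalues, dtype=float)
    return np.cumsum(lam) / lam.sum()


def reconstruct(basis: FpcaBasis, scores: ScoreMatrix, k: int) -> np.ndarray:
    """Truncated Karhunen-Loeve expansion: mean + sum of K score-weighted PCs."""
    if k > scores.k:
        raise ValueError(f"K={k} exceeds score columns {scores.k}")
    if k == 0:
        return np.tile(basis.mean, (scores.scores.shape[0], 1))
    return basis.mean + scores.scores[:, :k] @ basis.eigenfunctions[:k]
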