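import numpy as np
import pytest

from irfda.io import Spectrum
from irfda.preprocess import GriddedSpectrum, SpectralGrid


@pytest.fixture
def small_grid() -> SpectralGrid:
    """An 80-point analysis grid for fast linear-algebra tests."""
    return SpectralGrid(500.0, 816.0, 4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_gridded(values: np.ndarray, grid: SpectralGrid, cid: str = "x") -> GriddedSpectrum:
    return GriddedSpectrum(cid, np.asarray(values, dtype=float), grid)


@pytest.fixture
def smooth_dataset(small_grid, rng):
    """Smooth random curves: sums of a few broad Gaussians plus structure."""

    def build(n: int, seed: int | None = None) -> list[GriddedSpectrum]:
        gen = np.random.default_rng(seed) if seed is not None else rng
        x = small_grid.wavenumbers
        out = []
        for i in range(n):
            y = np.zeros_like(x)
            for _ in range(4):
                c = gen.uniform(x[0], x[-1])
                w = gen.uniform(20, 80)
                a = gen.uniform(0.5, 2.0)
                y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
            out.append(make_gridded(y, small_grid, f"s{i}"))
        return out

    return build


def make_spectrum(x, y, cid: str = "s") -> Spectrum:
    return Spectrum(cid, np.asarray(x, float), np.asarray(y, float))
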