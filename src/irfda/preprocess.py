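"""Spectral preprocessing: unit-SD rescaling, common-grid interpolation,
linear baseline correction.

The canonical analysis grid spans 500-4000 cm^-1 with a 4 cm^-1 step
(876 points).  Each spectrum is rescaled to unit sample standard deviation
on its native grid, linearly interpolated to the common grid (constant
extrapolation at the edges), and, when visibly tilted, detrended by the
straight line through its global minimum and its right endpoint.  No
smoothing is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Spectrum

logger = logging.getLogger(__name__)


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has zero variance and cannot be rescaled."""


class CoverageError(ValueError):
    """Raised when a spectrum does not overlap the analysis grid at all."""


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavenumber grid, inclusive of both endpoints."""

    start: float = 500.0
    stop: float = 4000.0
    step: float = 4.0

    def __post_init__(self) -> None:
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError(
                f"step {self.step} does not evenly divide [{self.start}, {self.stop}]"
            )

    @property
    def points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.points)


DEFAULT_GRID = SpectralGrid()


@dataclass(frozen=True)
class GriddedSpectrum:
    """Preprocessed absorbance evaluated on the common grid."""

    compound_id: str
    values: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.points,):
            raise ValueError(
                f"values length {v.shape} does not match grid ({self.grid.points},)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("gridded values contain non-finite entries")


def rescale_unit_sd(spectrum: Spectrum) -> Spectrum:
    """Rescale absorbance to unit sample standard deviation (ddof=1)."""
    sd = float(np.std(spectrum.absorbance, ddof=1))
    if sd <= 0.0 or not np.isfinite(sd):
        raise DegenerateSpectrumError(
            f"{spectrum.compound_id}: zero variance, cannot rescale"
        )
    return Spectrum(spectrum.compound_id, spectrum.wavenumbers, spectrum.absorbance / sd)


def interpolate_to_grid(spectrum: Spectrum, grid: SpectralGrid = DEFAULT_GRID) -> GriddedSpectrum:
    """Linearly interpolate onto the common grid.

    Grid points outside the native range take the nearest endpoint value
    (constant extrapolation).  A spectrum entirely outside the grid raises
    :class:`CoverageError`.
    """
    wn = spectrum.wavenumbers
    if wn[-1] < grid.start or wn[0] > grid.stop:
        raise CoverageError(
            f"{spectrum.compound_id}: native range [{wn[0]}, {wn[-1]}] "
            f"does not overlap grid [{grid.start}, {grid.stop}]"
        )
    values = np.interp(grid.wavenumbers, wn, spectrum.absorbance)
    return GriddedSpectrum(spectrum.compound_id, values, grid)


def baseline_slope_triggered(gs: GriddedSpectrum, trigger_ratio: float = 0.5) -> bool:
    """Decide whether the spectrum is tilted enough to warrant detrending.

    The ordinary-least-squares slope of absorbance against wavenumber is
    computed; correction triggers when |slope| * (grid span) exceeds
    ``trigger_ratio`` times the value range.  Flat spectra never trigger.
    """
    x = gs.grid.wavenumbers
    v = gs.values
    vrange = float(v.max() - v.min())
    if vrange == 0.0:
        return False
    slope = float(np.polyfit(x, v, 1)[0])
    span = gs.grid.stop - gs.grid.start
    return abs(slope) * span > trigger_ratio * vrange


def baseline_correct(
    gs: GriddedSpectrum,
    trigger_ratio: float = 0.5,
    enabled: bool = True,
    force: bool = False,
) -> GriddedSpectrum:
    """Remove the linear trend between the lowest point and the right end.

    The anchor line passes through the global-minimum point (earliest index
    on ties) and the right endpoint; it is subtracted so both anchors map
    to exactly zero.  Correction is applied only when the slope trigger
    fires (or ``force`` is set); otherwise the input is returned unchanged.
    """
    if not enabled:
        return gs
    if not force and not baseline_slope_triggered(gs, trigger_ratio):
        return gs
    x = gs.grid.wavenumbers
    v = gs.values
    i_min = int(np.argmin(v))  # argmin takes the earliest index on ties
    i_right = v.size - 1
    if i_min == i_right:
        line = np.full_like(v, v[i_right])
    else:
        slope = (v[i_right] - v[i_min]) / (x[i_right] - x[i_min])
        line = v[i_min] + slope * (x - x[i_min])
    return GriddedSpectrum(gs.compound_id, v - line, gs.grid)


@dataclass
class PreprocessResult:
    spectra: list[GriddedSpectrum]
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def preprocess_dataset(
    spectra: list[Spectrum],
    grid: SpectralGrid = DEFAULT_GRID,
    trigger_ratio: float = 0.5,
    baseline_enabled: bool = True,
) -> PreprocessResult:
    """Run rescale -> interpolate -> baseline-correct over a dataset.

    Compounds that fail (zero variance, no grid coverage) are dropped with
    a warning and reported in the rejects list rather than imputed.
    """
    if not spectra:
        raise ValueError("preprocess_dataset requires a non-empty input")
    out: list[GriddedSpectrum] = []
    rejects: list[tuple[str, str]] = []
    for sp in spectra:
        try:
            scaled = rescale_unit_sd(sp)
            gridded = interpolate_to_grid(scaled, grid)
            corrected = baseline_correct(gridded, trigger_ratio, baseline_enabled)
        except DegenerateSpectrumError:
            rejects.append((sp.compound_id, "zero variance"))
            warnings.warn(f"dropping {sp.compound_id}: zero variance", stacklevel=2)
            continue
        except CoverageError:
            rejects.append((sp.compound_id, "no grid coverage"))
            warnings.warn(f"dropping {sp.compound_id}: no grid coverage", stacklevel=2)
            continue
        out.append(corrected)
    return PreprocessResult(out, rejects)
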