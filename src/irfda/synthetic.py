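"""Synthetic IR spectrum generator with group-characteristic bands.

Each functional group contributes absorption bands at positions taken
from standard IR correlation tables (amide carbonyl near 1665 cm^-1 with
an N-H stretch near 3300; the aniline N-H pair near 3350/3450 on top of
the aromatic bands; aromatic C-H and ring modes near 3030/1600/1500 with
an out-of-plane bend near 750; piperidine C-N near 1100 with CH2
stretches near 2850/2930).  All compounds share weak aliphatic backbone
bands.  A spectrum is the sum of jittered Gaussian (or Lorentzian) peaks
over the active groups, an optional linear baseline slope, and additive
Gaussian noise, sampled on an irregular native wavenumber grid whose
start varies between roughly 243 and 560 cm^-1.

The aniline band set deliberately equals the benzene set plus the N-H
pair, so aniline/benzene confusability — a feature of real aromatic
chemistry — is present in the synthetic corpus as well.

Beyond the group bands, every compound carries its own random skeletal
(fingerprint) bands, emulating the idiosyncratic vibrational structure
of the rest of the molecule.  These keep the sample covariance full of
slowly decaying directions, as observed in real corpora, instead of
collapsing onto the handful of group-template directions; they persist
when measurement noise and band jitter are switched off because they
are molecular structure, not noise.

Class structure follows the observed corpus: nine mutually exclusive
composition classes with highly imbalanced counts (piperidine rare).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import JOINT_CLASSES, class_flags
from .io import GROUPS, LabelRecord, Spectrum

#: Class counts of the reference corpus (training / testing rows).
REFERENCE_TRAIN_COUNTS = {
    "amide_only": 30,
    "aniline_only": 139,
    "benzene_only": 217,
    "piperidine_only": 18,
    "amide_aniline": 24,
    "amide_benzene": 22,
    "aniline_benzene": 15,
    "benzene_piperidine": 8,
    "none": 33,
}
REFERENCE_TEST_COUNTS = {
    "amide_only": 7,
    "aniline_only": 35,
    "benzene_only": 54,
    "piperidine_only": 5,
    "amide_aniline": 6,
    "amide_benzene": 5,
    "aniline_benzene": 4,
    "benzene_piperidine": 2,
    "none": 8,
}


@dataclass(frozen=True)
class Band:
    """One absorption band: center (cm^-1), width (cm^-1), peak intensity."""

    center: float
    width: float
    intensity: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if not 500.0 <= self.center <= 4000.0:
            raise ValueError(f"band center {self.center} outside [500, 4000] cm^-1")
        if self.width <= 0 or self.intensity <= 0:
            raise ValueError("band width and intensity must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, x: np.ndarray, center: float, intensity: float) -> np.ndarray:
        if self.shape == "gaussian":
            return intensity * np.exp(-0.5 * ((x - center) / self.width) ** 2)
        return intensity * self.width**2 / ((x - center) ** 2 + self.width**2)


_AROMATIC = (
    Band(3030.0, 30.0, 0.30),  # aromatic C-H stretch
    Band(1600.0, 25.0, 0.50),  # ring stretch
    Band(1500.0, 25.0, 0.50),  # ring stretch
    Band(1030.0, 20.0, 0.30),  # in-plane C-H bend
    Band(750.0, 25.0, 0.60),  # C-H out-of-plane bend
    Band(690.0, 20.0, 0.70),  # out-of-plane ring bend
)


@dataclass(frozen=True)
class BandLibrary:
    """Per-group band lists plus backbone bands shared by every compound."""

    groups: dict[str, tuple[Band, ...]]
    backbone: tuple[Band, ...]

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in library: {sorted(unknown)}")

    def save(self, path: str | Path) -> None:
        lines = ["group\tcenter\twidth\tintensity\tshape"]
        for name, bands in [("backbone", self.backbone)] + [
            (g, self.groups[g]) for g in GROUPS
        ]:
            for b in bands:
                lines.append(f"{name}\t{b.center:g}\t{b.width:g}\t{b.intensity:g}\t{b.shape}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BandLibrary":
        groups: dict[str, list[Band]] = {g: [] for g in GROUPS}
        backbone: list[Band] = []
        lines = Path(path).read_text().splitlines()
        for ln in lines[1:]:
            if not ln.strip():
                continue
            name, center, width, intensity, shape = ln.split("\t")
            band = Band(float(center), float(width), float(intensity), shape)
            if name == "backbone":
                backbone.append(band)
            else:
                groups[name].append(band)
        return cls({g: tuple(v) for g, v in groups.items()}, tuple(backbone))


def default_band_library() -> BandLibrary:
    """Fixed band library grounded in standard IR correlation tables."""
    return BandLibrary(
        groups={
            "amide": (
                Band(1665.0, 35.0, 1.00),  # amide I, C=O stretch
                Band(1550.0, 40.0, 0.45),  # amide II, N-H bend
                Band(3300.0, 70.0, 0.55),  # N-H stretch
            ),
            "aniline": _AROMATIC
            + (
                Band(3450.0, 50.0, 0.50),  # N-H2 asymmetric stretch
                Band(3350.0, 50.0, 0.45),  # N-H2 symmetric stretch
            ),
            "benzene": _AROMATIC,
            "piperidine": (
                Band(1120.0, 35.0, 0.70),  # C-N stretch
                Band(2850.0, 40.0, 0.85),  # CH2 symmetric stretch (ring CH2 x5)
                Band(2930.0, 40.0, 0.85),  # CH2 asymmetric stretch
                Band(860.0, 25.0, 0.45),  # ring breathing
            ),
        },
        backbone=(
            Band(2900.0, 60.0, 0.35),  # aliphatic C-H stretch
            Band(1450.0, 40.0, 0.20),  # C-H bend
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the reference corpus conditions."""

    train_counts: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_TRAIN_COUNTS)
    )
    test_counts: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_TEST_COUNTS)
    )
    noise_sd: float = 0.02  # relative to the strongest band intensity (1.0)
    baseline_slope_range: tuple[float, float] = (1e-4, 4e-4)  # per cm^-1
    baseline_zero_prob: float = 0.6  # fraction of compounds with no slope
    intensity_jitter: float = 0.10  # lognormal sigma on band intensities
    center_jitter: float = 5.0  # cm^-1 SD on band centers
    # compound-specific fingerprint structure (independent of the labels);
    # drawn from windows that avoid the group-characteristic band regions
    skeletal_bands_lambda: float = 20.0  # Poisson mean number of bands
    skeletal_center_windows: tuple[tuple[float, float], ...] = (
        (1150.0, 1420.0),
        (1750.0, 2750.0),
    )
    skeletal_width_range: tuple[float, float] = (12.0, 45.0)
    skeletal_intensity_range: tuple[float, float] = (0.05, 0.35)
    spacing_range: tuple[float, float] = (1.0, 6.0)  # native grid spacing, cm^-1
    start_range: tuple[float, float] = (500.0, 560.0)  # typical native start
    low_start_prob: float = 0.15  # chance of an extended range starting near 243
    low_start_range: tuple[float, float] = (243.0, 500.0)
    native_stop: float = 4000.7
    seed: int = 0

    def __post_init__(self) -> None:
        for counts in (self.train_counts, self.test_counts):
            unknown = set(counts) - set(JOINT_CLASSES)
            if unknown:
                raise ValueError(f"unknown classes {sorted(unknown)}")
            if any(v < 0 for v in counts.values()):
                raise ValueError("class counts must be nonnegative")
        if self.noise_sd < 0 or self.intensity_jitter < 0 or self.center_jitter < 0:
            raise ValueError("noise and jitter settings must be nonnegative")


def scaled_class_counts(base: dict[str, int], total: int) -> dict[str, int]:
    """Rescale class counts to a new total by largest remainder."""
    classes = list(base)
    raw = np.array([base[c] for c in classes], dtype=float)
    exact = raw * total / raw.sum()
    floors = np.floor(exact).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(exact - floors)[::-1]
    for i in order[:remainder]:
        floors[i] += 1
    return {c: int(k) for c, k in zip(classes, floors)}


def reduced_config(train_total: int = 400, test_total: int = 200, **kwargs) -> SimConfig:
    """Corpus-proportioned configuration at a smaller problem size."""
    return SimConfig(
        train_counts=scaled_class_counts(REFERENCE_TRAIN_COUNTS, train_total),
        test_counts=scaled_class_counts(REFERENCE_TEST_COUNTS, test_total),
        **kwargs,
    )


def _native_grid(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if rng.uniform() < config.low_start_prob:
        start = rng.uniform(*config.low_start_range)
    else:
        start = rng.uniform(*config.start_range)
    spacings = rng.uniform(*config.spacing_range, size=4096)
    x = start + np.concatenate([[0.0], np.cumsum(spacings)])
    return x[x <= config.native_stop]


def simulate_spectrum(
    groups: set[str] | frozenset[str],
    library: BandLibrary,
    config: SimConfig,
    rng: np.random.Generator,
    compound_id: str = "synthetic",
    split: str = "train",
) -> tuple[Spectrum, LabelRecord]:
    """Draw one labeled synthetic spectrum for the given active groups."""
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown functional groups: {sorted(unknown)}")
    x = _native_grid(config, rng)
    y = np.zeros_like(x)
    bands: list[Band] = list(library.backbone)
    for g in GROUPS:  # deterministic iteration order
        if g in groups:
            bands.extend(library.groups[g])
    for band in bands:
        center = band.center + rng.normal(0.0, config.center_jitter) if config.center_jitter else band.center
        intensity = band.intensity * float(np.exp(rng.normal(0.0, config.intensity_jitter))) if config.intensity_jitter else band.intensity
        y = y + band.profile(x, center, intensity)
    # idiosyncratic skeletal bands of this particular molecule
    if config.skeletal_bands_lambda > 0:
        windows = config.skeletal_center_windows
        spans = np.array([hi - lo for lo, hi in windows])
        for _ in range(rng.poisson(config.skeletal_bands_lambda)):
            lo, hi = windows[rng.choice(len(windows), p=spans / spans.sum())]
            c = rng.uniform(lo, hi)
            wdt = rng.uniform(*config.skeletal_width_range)
            inten = rng.uniform(*config.skeletal_intensity_range)
            y = y + inten * np.exp(-0.5 * ((x - c) / wdt) ** 2)
    if rng.uniform() >= config.baseline_zero_prob:
        slope = rng.uniform(*config.baseline_slope_range)
        y = y + slope * (x - x[0])
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=x.size)
    y = np.clip(y, 0.0, None)  # absorbance is nonnegative
    flags = {g: g in groups for g in GROUPS}
    record = LabelRecord(
        compound_id=compound_id,
        has_amide=flags["amide"],
        has_aniline=flags["aniline"],
        has_benzene=flags["benzene"],
        has_piperidine=flags["piperidine"],
        split=split,
    )
    return Spectrum(compound_id, x, y), record


def simulate_dataset(
    config: SimConfig,
    library: BandLibrary | None = None,
) -> tuple[list[Spectrum], list[LabelRecord]]:
    """Generate the configured class mix for both splits, seeded."""
    library = library or default_band_library()
    total = sum(config.train_counts.values()) + sum(config.test_counts.values())
    if total < 2:
        raise ValueError("need at least 2 compounds in total")
    nonzero = sum(
        1
        for c in JOINT_CLASSES
        if config.train_counts.get(c, 0) + config.test_counts.get(c, 0) > 0
    )
    if nonzero < 2:
        raise ValueError("need at least two nonempty classes")
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    records: list[LabelRecord] = []
    for split, counts in (("train", config.train_counts), ("test", config.test_counts)):
        for cls in JOINT_CLASSES:
            flags = class_flags(cls)
            groups = {g for g, f in zip(GROUPS, flags) if f}
            for i in range(counts.get(cls, 0)):
                cid = f"syn-{split}-{cls}-{i:04d}"
                sp, rec = simulate_spectrum(
                    groups, library, config, rng, compound_id=cid, split=split
                )
                spectra.append(sp)
                records.append(rec)
    return spectra, records
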