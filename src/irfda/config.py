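"""Run configuration: defaults, plain-text key-value files, content hash.

A config file is flat ``key = value`` lines with dotted keys, ``#``
comments allowed, e.g.::

    grid.start = 500
    fpca.penalty = 0.01
    glm.oversample.piperidine = 100
    seed = 7
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .io import GROUPS
from .preprocess import SpectralGrid


@dataclass(frozen=True)
class RunConfig:
    grid: SpectralGrid = SpectralGrid(500.0, 4000.0, 4.0)
    baseline_enabled: bool = True
    baseline_trigger_ratio: float = 0.5
    fpca_penalty: float = 1e-2
    fpca_k_max: int = 50
    fpca_variance_threshold: float = 0.80
    glm_threshold: float = 0.5
    glm_max_iter: int = 100
    glm_ridge_on_separation: float = 1e-4
    # per-group oversampling target for positive training rows; only the
    # rare piperidine class is rebalanced by default
    glm_oversample: dict[str, int] = field(default_factory=lambda: {"piperidine": 100})
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.glm_oversample) - set(GROUPS)
        if unknown:
            raise ValueError(f"oversample targets for unknown groups {sorted(unknown)}")

    def to_flat_dict(self) -> dict[str, object]:
        d: dict[str, object] = {
            "grid.start": self.grid.start,
            "grid.stop": self.grid.stop,
            "grid.step": self.grid.step,
            "baseline.enabled": self.baseline_enabled,
            "baseline.trigger_ratio": self.baseline_trigger_ratio,
            "fpca.penalty": self.fpca_penalty,
            "fpca.k_max": self.fpca_k_max,
            "fpca.variance_threshold": self.fpca_variance_threshold,
            "glm.threshold": self.glm_threshold,
            "glm.max_iter": self.glm_max_iter,
            "glm.ridge_on_separation": self.glm_ridge_on_separation,
            "seed": self.seed,
        }
        for g, t in sorted(self.glm_oversample.items()):
            d[f"glm.oversample.{g}"] = t
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def parse_config_file(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Parse a key-value config file, overriding defaults (or ``base``)."""
    cfg = base or RunConfig()
    grid = {"start": cfg.grid.start, "stop": cfg.grid.stop, "step": cfg.grid.step}
    oversample = dict(cfg.glm_oversample)
    updates: dict[str, object] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("grid."):
            grid[key[5:]] = float(value)
        elif key.startswith("glm.oversample."):
            oversample[key.rsplit(".", 1)[1]] = int(value)
        elif key == "baseline.enabled":
            updates["baseline_enabled"] = value.lower() in ("1", "true", "yes")
        elif key == "baseline.trigger_ratio":
            updates["baseline_trigger_ratio"] = float(value)
        elif key == "fpca.penalty":
            updates["fpca_penalty"] = float(value)
        elif key == "fpca.k_max":
            updates["fpca_k_max"] = int(value)
        elif key == "fpca.variance_threshold":
            updates["fpca_variance_threshold"] = float(value)
        elif key == "glm.threshold":
            updates["glm_threshold"] = float(value)
        elif key == "glm.max_iter":
            updates["glm_max_iter"] = int(value)
        elif key == "glm.ridge_on_separation":
            updates["glm_ridge_on_separation"] = float(value)
        elif key == "seed":
            updates["seed"] = int(value)
        else:
            raise ValueError(f"{path}:{line_no}: unknown config key {key!r}")
    return replace(
        cfg,
        grid=SpectralGrid(grid["start"], grid["stop"], grid["step"]),
        glm_oversample=oversample,
        **updates,
    )
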