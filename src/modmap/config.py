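"""Analysis configuration with validation, YAML round-tripping and
deterministic per-stage seed derivation.

All randomness in a run flows from the single ``rng_seed``: each stage gets
its own child seed derived with :class:`numpy.random.SeedSequence` under a
fixed stage index (see ``STAGE_SEEDS``), so stages re-run in isolation
reproduce the full pipeline exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AnalysisConfig", "RunConfig", "ConfigError", "stage_rng", "STAGE_SEEDS"]

STAGE_SEEDS = {
    "simulate": 0,
    "detect": 1,
    "significance": 2,
    "strength": 3,
    "dimensionality": 4,
}


class ConfigError(ValueError):
    """A configuration value is outside its allowed range."""


def stage_rng(rng_seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage."""
    if stage not in STAGE_SEEDS:
        raise KeyError(f"unknown stage {stage!r}")
    child = np.random.SeedSequence(rng_seed).spawn(len(STAGE_SEEDS))[STAGE_SEEDS[stage]]
    return np.random.default_rng(child)


@dataclass
class AnalysisConfig:
    """Parameters of the per-experiment analysis.

    Defaults follow the standard acquisition geometry the pipeline targets
    (15 Hz, ~5.5 um pixels, 4x downsampling to ~22 um analysis pixels,
    band-pass SDs 30/195 um, 1.8–2.2 mm long-range ring).
    """

    window_s: float = 30.0
    register: bool = False
    detection_method: str = "gaussian3sd"
    min_area_mm2: float = 0.01
    min_active_fraction: float = 0.40
    s_low_um: float = 30.0
    s_high_um: float = 195.0
    ds_factor: int = 4
    bin_width_mm: float | None = None
    ring_mm: tuple[float, float] = (1.8, 2.2)
    n_events_use: int = 100
    n_surrogates: int = 100
    n_subsets: int = 10
    subset_size: int = 100
    n_control_sets: int = 100
    rng_seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if not (10.0 <= self.window_s <= 64.0):
            raise ConfigError(f"window_s={self.window_s} outside [10, 64] s")
        if self.detection_method not in ("gaussian3sd", "percentile80"):
            raise ConfigError(f"unknown detection_method {self.detection_method!r}")
        if not (0 < self.s_low_um < self.s_high_um):
            raise ConfigError("require 0 < s_low_um < s_high_um")
        if self.ds_factor < 1:
            raise ConfigError("ds_factor must be >= 1")
        if not (0 < self.ring_mm[0] < self.ring_mm[1]):
            raise ConfigError("ring_mm must satisfy 0 < lo < hi")
        if not (0 < self.min_active_fraction < 1):
            raise ConfigError("min_active_fraction must be in (0, 1)")
        for name in ("n_events_use", "n_surrogates", "n_subsets", "subset_size", "n_control_sets"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        return self


@dataclass
class RunConfig:
    """One end-to-end pipeline run (paths, labels, simulation, analysis)."""

    outdir: str = "run"
    movie: str | None = None
    roi: str | None = None
    pixel_um: float | None = None
    frame_rate_hz: float | None = None
    age_group: str = ""
    area: str = ""
    simulate: dict | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> "RunConfig":
        self.analysis.validate()
        if self.movie is None and self.simulate is None:
            raise ConfigError("either a movie path or a 'simulate' block is required")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"]["ring_mm"] = list(self.analysis.ring_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        a = d.pop("analysis", {}) or {}
        if "ring_mm" in a:
            a["ring_mm"] = tuple(a["ring_mm"])
        cfg = cls(**d, analysis=AnalysisConfig(**a))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
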