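"""Pipeline configuration: every tunable threshold in one validated object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(Exception):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the generate -> segment -> qc -> quantify -> stats pipeline.

    Defaults follow the processing conventions for coccolith work: 5-plane
    depth blocks, a Ca gate of one detected ion per (pixel, block), a 10%
    residual-CV target over at least half the depth range, and alpha = 0.05
    for the cohort statistics.  ``delta`` is the (44Ca)2+ dimer yield ratio
    (session constant; 0 disables the correction).
    """

    block_size_planes: int = 5
    gate_min_ca: int = 1
    cv_target: float = 0.10
    min_fraction: float = 0.5
    ca_quantile: float | None = None  # None => Otsu threshold on accumulated Ca
    enrichment_factor: float = 3.0
    min_area_px: int = 20
    align_max_shift_px: int = 4
    align_block_planes: int = 50
    alpha: float = 0.05
    delta: float = 0.0
    calibration: str | None = None  # path to calib.json; None => built-in default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size_planes < 1:
            raise ConfigError("block_size_planes must be >= 1")
        if self.gate_min_ca < 0:
            raise ConfigError("gate_min_ca must be >= 0")
        if not (0 < self.cv_target):
            raise ConfigError("cv_target must be > 0")
        if not (0 < self.min_fraction <= 1):
            raise ConfigError("min_fraction must be in (0, 1]")
        if self.ca_quantile is not None and not (0 < self.ca_quantile < 1):
            raise ConfigError("ca_quantile must be in (0, 1)")
        if self.enrichment_factor <= 1:
            raise ConfigError("enrichment_factor must be > 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.delta < 0:
            raise ConfigError("delta must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
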