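"""Run configuration: one master seed plus per-module parameter blocks.

Every parameter has a default except the flow-cytometry control channel,
which must be supplied whenever a flow-calling stage runs (the channel scale
of a cytometer run is instrument- and gain-dependent, so there is no safe
constant). Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

ALL_STAGES = ("simulate", "concordance", "snp-call", "ploidy-call", "report")


@dataclass
class SimulateConfig:
    length: int = 600
    n_plants_per_cultivar: int = 10
    n_ratoon_obs_per_plant: int = 2
    composition: list[list[int]] = field(
        default_factory=lambda: [[2, 95], [4, 5]]
    )
    cv: float = 0.03
    debris_fraction: float = 0.10
    n_nuclei: int = 5000
    n_channels: int = 256
    deletion_start: int = 91
    deletion_length: int = 12
    n_cytology_cells: int = 10
    miscount_prob: float = 0.1


@dataclass
class ConcordanceConfig:
    threshold: float = 1.0
    percent: bool = False


@dataclass
class VariantsConfig:
    frame_offset: int = 1
    reference_label: str = "Ancestral"


@dataclass
class PloidyConfig:
    control_channel: float | None = None  # mandatory for flow runs
    control_ploidy: int = 3
    basic_number: int = 11
    tolerance: int = 1
    smooth_window: int = 5
    min_prominence_frac: float = 0.05
    max_rel_deviation: float = 0.2
    control_band_frac: float = 0.1
    min_channel_frac: float = 0.25


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "musavar_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    variants: VariantsConfig = field(default_factory=VariantsConfig)
    ploidy: PloidyConfig = field(default_factory=PloidyConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "ploidy-call" in self.stages and self.ploidy.control_channel is None:
            raise ConfigError(
                "ploidy.control_channel is required when the flow-calling "
                "stage is enabled"
            )

    def stage_seed(self, stage: str) -> int:
        """Per-stage sub-seed: stages rerun in isolation reproducibly."""
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % 2**31

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {
    "simulate": SimulateConfig,
    "concordance": ConcordanceConfig,
    "variants": VariantsConfig,
    "ploidy": PloidyConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    known_top = {"seed", "outdir", "stages", *_BLOCKS}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("seed", "outdir", "stages"):
        if key in data:
            setattr(cfg, key, data[key])
    for block, cls in _BLOCKS.items():
        if block not in data:
            continue
        block_data = data[block] or {}
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(block_data) - fields
        if unknown:
            raise ConfigError(
                f"unknown keys in {block!r} block: {sorted(unknown)}"
            )
        setattr(cfg, block, cls(**block_data))
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)
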