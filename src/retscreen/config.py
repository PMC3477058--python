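"""Serializable configuration for both screening pipelines."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .dr_grading import GradingThresholds
from .exceptions import ConfigError, ParameterError
from .types import DiffusionParams, MorphScales, SnakeParams


@dataclass(frozen=True)
class FundusConfig:
    """Tunables of the fundus detectors."""

    scales: MorphScales = field(default_factory=MorphScales)
    scale_with_width: bool = True
    preprocess: bool = True
    clahe_clip_limit: float = 0.01
    vessel_min_area_px: int | None = None
    confirm_exudates_green: bool = True
    mahm_vessel_margin_px: int = 2

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ConfigError("fundus.clahe_clip_limit: must be positive")
        if self.vessel_min_area_px is not None and self.vessel_min_area_px < 1:
            raise ConfigError("fundus.vessel_min_area_px: must be >= 1")
        if self.mahm_vessel_margin_px < 0:
            raise ConfigError("fundus.mahm_vessel_margin_px: must be >= 0")


@dataclass(frozen=True)
class OctConfig:
    """Tunables of the OCT boundary chain."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    snake: SnakeParams = field(default_factory=SnakeParams)
    snake_posterior: bool = False
    posterior_n_sd: float = 1.0
    anterior_margin_px: int = 4
    rpe_depth_px: int = 60
    axial_um_per_px: float = 6.0

    def __post_init__(self):
        if self.axial_um_per_px <= 0:
            raise ConfigError("oct.axial_um_per_px: must be positive")
        if self.anterior_margin_px < 0:
            raise ConfigError("oct.anterior_margin_px: must be >= 0")
        if self.rpe_depth_px < 1:
            raise ConfigError("oct.rpe_depth_px: must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through JSON."""

    fundus: FundusConfig = field(default_factory=FundusConfig)
    grading: GradingThresholds = field(default_factory=GradingThresholds)
    oct: OctConfig = field(default_factory=OctConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, payload, prefix):
            if payload is None:
                return klass()
            if not isinstance(payload, dict):
                raise ConfigError(f"{prefix}: expected a mapping")
            kwargs = {}
            fields = {f.name: f for f in dataclasses.fields(klass)}
            for key, value in payload.items():
                if key not in fields:
                    raise ConfigError(f"{prefix}.{key}: unknown field")
                ftype = fields[key].default_factory if fields[key].default_factory is not dataclasses.MISSING else None
                if ftype is not None and isinstance(value, dict):
                    kwargs[key] = build(ftype, value, f"{prefix}.{key}")
                else:
                    kwargs[key] = value
            try:
                return klass(**kwargs)
            except (ParameterError, ConfigError, TypeError) as exc:
                raise ConfigError(f"{prefix}: {exc}") from exc

        out_kwargs = {}
        known = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise ConfigError(f"config.{key}: unknown section")
            out_kwargs[key] = build(known[key].default_factory, value, f"config.{key}")
        return cls(**out_kwargs)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config: invalid JSON ({exc})") from exc
        return cls.from_dict(data)
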