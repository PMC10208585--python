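"""Pipeline configuration: one YAML file resolves every stage's parameters.

Unknown keys are rejected so typos fail loudly instead of silently falling
back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import CameraModel, RotationalRig
from .stereo import MatchConfig
from .vesselness import (DEFAULT_BETA, DEFAULT_MIN_AREA, DEFAULT_SCALES,
                         DEFAULT_THRESHOLD)

__all__ = ["VesselnessParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class VesselnessParams:
    scales: tuple[float, ...] = DEFAULT_SCALES
    beta: float = DEFAULT_BETA
    threshold: float = DEFAULT_THRESHOLD
    min_area_px: int = DEFAULT_MIN_AREA
    log_compress: bool = True


def _build(cls, payload: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    converted = {}
    for key, val in payload.items():
        converted[key] = tuple(val) if isinstance(val, list) else val
    return cls(**converted)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from one file plus
    command-line overrides."""

    camera: CameraModel = field(default_factory=CameraModel)
    rig: RotationalRig = field(default_factory=lambda: RotationalRig(
        stage_distance_mm=440.0, baseline_mm=60.0))
    match: MatchConfig | None = None
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    phantom_kind: str = "cylinder"
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload or {})
        known = {"camera", "rig", "match", "vesselness", "phantom_kind",
                 "seed", "input_dir", "output_dir"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        if "camera" in payload:
            kwargs["camera"] = _build(CameraModel, payload["camera"], "camera")
        if "rig" in payload:
            kwargs["rig"] = _build(RotationalRig, payload["rig"], "rig")
        if payload.get("match") is not None:
            kwargs["match"] = _build(MatchConfig, payload["match"], "match")
        if "vesselness" in payload:
            kwargs["vesselness"] = _build(VesselnessParams,
                                          payload["vesselness"], "vesselness")
        for key in ("phantom_kind", "seed", "input_dir", "output_dir"):
            if key in payload:
                kwargs[key] = payload[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "camera": asdict(self.camera),
            "rig": asdict(self.rig),
            "vesselness": asdict(self.vesselness),
            "phantom_kind": self.phantom_kind,
            "seed": self.seed,
        }
        if self.match is not None:
            out["match"] = asdict(self.match)
        if self.input_dir:
            out["input_dir"] = str(self.input_dir)
        if self.output_dir:
            out["output_dir"] = str(self.output_dir)
        return out


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline configuration; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return PipelineConfig.from_dict(payload)
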