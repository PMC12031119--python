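"""Structured pipeline configuration loaded from YAML.

Every empirical threshold of the selection algorithm lives here so that a
sensitivity analysis is a loop over configs.  Unknown keys are rejected to
catch typos early.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .device import DeviceConfig
from .epoching import WindowGrid
from .rates import RateSettings
from .selection import SelectionCriteria
from .simulate import ArtifactEvent, BodySegment, Breathing, Heartbeat, SceneSpec


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in '{path}' block")
    # YAML gives lists where the dataclasses want tuples
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass(frozen=True)
class PipelineConfig:
    device: DeviceConfig = field(default_factory=DeviceConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    grid: WindowGrid = field(default_factory=WindowGrid)
    rates: RateSettings = field(default_factory=RateSettings)
    restrict_min_m: float = 0.4
    restrict_max_m: float = 3.0
    chirp_mode: str = "median"  # "median" | "first"

    def __post_init__(self) -> None:
        if self.chirp_mode not in ("median", "first"):
            raise ValueError("chirp_mode must be 'median' or 'first'")
        if self.restrict_max_m < self.restrict_min_m:
            raise ValueError("restrict_max_m < restrict_min_m")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        blocks = {
            "device": DeviceConfig, "criteria": SelectionCriteria,
            "grid": WindowGrid, "rates": RateSettings,
        }
        kwargs = {}
        for name, sub in blocks.items():
            if name in data:
                kwargs[name] = _build(sub, data.pop(name), name)
        top = {"restrict_min_m", "restrict_max_m", "chirp_mode"}
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown top-level keys {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def scene_from_dict(data: dict) -> SceneSpec:
    """Build a SceneSpec from a YAML scene description."""
    data = dict(data or {})
    segments = []
    for seg in data.pop("segments", []):
        seg = dict(seg)
        if "breathing" in seg and seg["breathing"] is not None:
            seg["breathing"] = _build(Breathing, seg["breathing"], "breathing")
        if "heartbeat" in seg and seg["heartbeat"] is not None:
            seg["heartbeat"] = _build(Heartbeat, seg["heartbeat"], "heartbeat")
        segments.append(_build(BodySegment, seg, "segment"))
    events = [_build(ArtifactEvent, ev, "artifact")
              for ev in data.pop("artifact_events", [])]
    spec = _build(SceneSpec, data, "scene")
    return dataclasses.replace(spec, segments=tuple(segments),
                               artifact_events=tuple(events))


def scene_from_yaml(path) -> SceneSpec:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()) or {})
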