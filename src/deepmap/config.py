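"""Pipeline configuration.

One JSON document with namespaced sections (``stimulus``, ``capture``,
``ep``, ``deep``, ``map``, ``validate``); every default below can be
overridden from file or from keyword arguments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class StimulusConfig:
    threshold_mv: float = 2.0          # absolute peak height for a pacing artifact
    coincidence_window_ms: float = 2.0 # artifacts must align across channels
    coincidence_fraction: float = 0.8  # fraction of channels that must agree
    refractory_ms: float = 50.0        # suppress double-detections of one artifact
    jitter_fraction: float = 0.05      # S1 interval tolerance band
    s2_shortening_fraction: float = 0.10  # interval >=10% shorter => S2


@dataclass
class CaptureConfig:
    window_ms: tuple[float, float] = (20.0, 140.0)  # post-stimulus QRS window
    threshold: float = 0.90
    leads: list[str] | None = None  # None => all surface leads


@dataclass
class EpConfig:
    band_hz: tuple[float, float] = (30.0, 300.0)
    search_start_ms: float = 10.0        # post-stimulus
    search_end_fraction: float = 0.9     # of the S1 interval
    morphology_half_width_ms: float = 10.0
    noise_floor_multiple: float = 3.0
    min_amplitude_mv: float = 0.01       # absolute floor when noise estimate ~ 0
    blank_ms: float = 5.0                # artifact blanking half-width
    stability_latency_sd_ms: float = 5.0
    stability_correlation: float = 0.85
    s2_match_threshold: float = 0.7


@dataclass
class DeepConfig:
    display_threshold_ms: float = 10.0   # strict: displayed <=> value > threshold


@dataclass
class MapConfig:
    radius_mm: float = 10.0              # IDW influence radius
    sphere_r_min: float = 1.0            # mm
    sphere_k: float = 0.05               # mm per ms of decrement
    projection_limit_mm: float = 15.0
    scar_threshold_mv: float = 0.5       # export metadata only
    border_threshold_mv: float = 1.5


@dataclass
class ValidateConfig:
    match_tolerance_ms: float = 10.0
    change_tolerance_ms: float = 5.0


@dataclass
class PipelineConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    ep: EpConfig = field(default_factory=EpConfig)
    deep: DeepConfig = field(default_factory=DeepConfig)
    map: MapConfig = field(default_factory=MapConfig)
    validate: ValidateConfig = field(default_factory=ValidateConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section, values in data.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            for key, val in values.items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                current = getattr(sub, key)
                if isinstance(current, tuple) and isinstance(val, list):
                    val = tuple(val)
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
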