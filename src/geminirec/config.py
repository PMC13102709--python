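"""Run configuration: YAML-backed, strictly validated.

Unknown keys are rejected rather than ignored, so typos in a config file
surface immediately instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content, with the field path."""


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path or 'top level'}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        sub = _SECTIONS.get((cls, f.name))
        kwargs[f.name] = _build(sub, val, f"{path}.{f.name}" if path else f.name) if sub else val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path or 'top level'}: {exc}") from exc


@dataclass
class ProtocolConfig:
    """Stamp schedule and signal description for simulate/decode runs."""

    switches: list = field(default_factory=lambda: [[0.0, "stamp1"], [11.0, "stamp2"]])
    pulses: list = field(default_factory=list)
    signal_channel: str = "signal"
    signal_events: list = field(default_factory=list)  # [on, off, amplitude]
    delay: float = 0.0
    boost: bool = False
    nucleation_time: float = -8.0
    end_time: float = 22.0


@dataclass
class NoiseConfig:
    psf_sigma: float = 1.0
    shot_noise: float = 200.0
    read_noise_sd: float = 0.01
    background: float = 1.0
    radial_jitter_sd: float = 0.0


@dataclass
class ParticlesConfig:
    n: int = 1
    k_mean: float = 4000.0  # px^3/h for rendered scenes
    k_cv: float = 0.2
    image_shape: list = field(default_factory=lambda: [256, 256])
    gain: float = 100.0
    record_resolution: float = 0.25


@dataclass
class TrackerSection:
    d_max: float = 30.0
    w_area: float = 1.0
    w_intensity: float = 1.0
    min_separation: int = 10
    min_area: int = 20


@dataclass
class ProfileConfig:
    width: int = 3
    step: float = 0.5
    filter_order: int = 3
    cutoff: float = 0.2
    n_directions: int = 6


@dataclass
class RunConfig:
    """Top-level configuration for CLI runs."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    particles: ParticlesConfig = field(default_factory=ParticlesConfig)
    tracker: TrackerSection = field(default_factory=TrackerSection)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    seed: int | None = None
    out_dir: str = "."
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return asdict(self)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("seed is required for stochastic runs (set 'seed')")
        return int(self.seed)


_SECTIONS = {
    (RunConfig, "protocol"): ProtocolConfig,
    (RunConfig, "noise"): NoiseConfig,
    (RunConfig, "particles"): ParticlesConfig,
    (RunConfig, "tracker"): TrackerSection,
    (RunConfig, "profile"): ProfileConfig,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file; CLI flag overrides win over file values."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = val
        else:
            data[key] = val
    return _build(RunConfig, data, "")
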