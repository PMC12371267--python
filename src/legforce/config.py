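"""Run configuration: every analysis constant in one validated object.

The defaults reproduce the study procedure with zero overrides: a 10 Hz
fourth-order zero-lag low-pass on force, 30-400 Hz band-pass plus 59-61 Hz
band-stop on EMG, 10-90% rise thresholds searched in [-0.5, +1] s around the
target step-up, steady-state windows at onset +2..+4 s, MVC averaged over
4-8 s, hold variability per 1-s segment after the first 5 s, and median
frequency per 2-s segment in the 30-400 Hz band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ForceFilterConfig",
    "EMGFilterConfig",
    "MetricsConfig",
    "ExclusionConfig",
    "EMGSpectraConfig",
    "StatsConfig",
    "AnalysisConfig",
    "load_config",
    "default_config",
]


class ConfigError(ValueError):
    """A configuration document violated the schema."""


@dataclass
class ForceFilterConfig:
    enabled: bool = True
    cutoff_hz: float = 10.0
    order: int = 4
    zero_lag: bool = True

    def validate(self) -> None:
        if self.cutoff_hz <= 0:
            raise ConfigError(f"force_filter.cutoff_hz must be > 0, got {self.cutoff_hz}")
        if self.order < 1:
            raise ConfigError(f"force_filter.order must be >= 1, got {self.order}")


@dataclass
class EMGFilterConfig:
    band_hz: tuple[float, float] = (30.0, 400.0)
    bandstop_hz: tuple[float, float] = (59.0, 61.0)
    order: int = 4
    zero_lag: bool = True
    expected_rate_hz: float = 2000.0
    sensor_delay_s: float = 500e-6

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ConfigError(f"emg_filter.band_hz must be increasing positive, got {self.band_hz}")
        slo, shi = self.bandstop_hz
        if not 0 < slo < shi:
            raise ConfigError(f"emg_filter.bandstop_hz invalid: {self.bandstop_hz}")
        if self.order < 1:
            raise ConfigError(f"emg_filter.order must be >= 1, got {self.order}")


@dataclass
class MetricsConfig:
    rise_frac_lo: float = 0.1
    rise_frac_hi: float = 0.9
    rise_window_s: tuple[float, float] = (-0.5, 1.0)   # relative to step-up
    ss_window_s: tuple[float, float] = (2.0, 4.0)      # relative to step-up
    fall_window_s: tuple[float, float] = (4.0, 6.0)    # STEP segment time
    mvc_window_s: tuple[float, float] = (4.0, 8.0)     # trial time
    hold_skip_s: float = 5.0
    hold_segment_s: float = 1.0
    hold_final_n: int = 10

    def validate(self) -> None:
        if not 0 <= self.rise_frac_lo < self.rise_frac_hi <= 1:
            raise ConfigError(
                f"metrics rise fractions must satisfy 0 <= lo < hi <= 1, "
                f"got {self.rise_frac_lo}, {self.rise_frac_hi}"
            )
        for name in ("rise_window_s", "ss_window_s", "fall_window_s", "mvc_window_s"):
            a, b = getattr(self, name)
            if not a < b:
                raise ConfigError(f"metrics.{name} must be increasing, got {(a, b)}")
        if self.hold_skip_s < 0 or self.hold_segment_s <= 0:
            raise ConfigError("metrics hold windows must be non-negative / positive")


@dataclass
class ExclusionConfig:
    pre_window_s: float = 0.5      # early-rise / elevated-baseline look-back
    post_window_s: float = 0.5     # no-rise deadline after the step-up
    early_fall_s: float = 1.0      # early-fall margin before the step-down
    pulse_pre_s: float = 0.25      # pulse early-rise look-back
    pulse_post_s: float = 0.5      # pulse late-fall deadline after step-down
    pulse_fall_frac: float = 0.90  # descent-onset level for the pulse fall screen
    baseline_frac: float = 0.10    # "steps up / down" threshold fraction
    no_rise_frac: float = 0.10     # threshold fraction for the no-rise screen
    rise_anchor_frac: float = 0.50  # half-rise level tying a crossing to the response

    def validate(self) -> None:
        for name in ("pre_window_s", "post_window_s", "early_fall_s", "pulse_pre_s", "pulse_post_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"exclusion.{name} must be >= 0")
        for name in ("baseline_frac", "no_rise_frac", "rise_anchor_frac", "pulse_fall_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"exclusion.{name} must be in (0, 1]")


@dataclass
class EMGSpectraConfig:
    window_s: float = 2.0
    band_hz: tuple[float, float] = (30.0, 400.0)
    estimator: str = "periodogram"
    baseline_window_s: float = 10.0

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigError(f"emg.window_s must be > 0, got {self.window_s}")
        lo, hi = self.band_hz
        if not 0 <= lo < hi:
            raise ConfigError(f"emg.band_hz invalid: {self.band_hz}")
        if self.estimator not in ("periodogram", "welch"):
            raise ConfigError(f"emg.estimator must be periodogram|welch, got {self.estimator!r}")


@dataclass
class StatsConfig:
    first_n_responses: int = 5
    alpha: float = 0.05
    sphericity_correction: bool = False   # Greenhouse-Geisser when True

    def validate(self) -> None:
        if self.first_n_responses < 1:
            raise ConfigError("stats.first_n_responses must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"stats.alpha must be in (0, 1), got {self.alpha}")


@dataclass
class AnalysisConfig:
    force_filter: ForceFilterConfig = field(default_factory=ForceFilterConfig)
    emg_filter: EMGFilterConfig = field(default_factory=EMGFilterConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    emg: EMGSpectraConfig = field(default_factory=EMGSpectraConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> "AnalysisConfig":
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate()
        return self


def _coerce_section(cls, name: str, data: Any):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        default = known[key].default
        # YAML lists stand in for the tuple-typed window/band settings.
        if isinstance(value, list):
            value = tuple(value)
        if isinstance(default, bool) and not isinstance(value, bool):
            raise ConfigError(f"{name}.{key} must be a boolean, got {value!r}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def from_dict(data: dict | None) -> AnalysisConfig:
    """Build a config from a (possibly partial) nested mapping.

    Missing sections and keys take defaults; unknown keys are rejected with a
    message naming the key.
    """
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config document must be a mapping, got {type(data).__name__}")
    sections = {f.name: f.default_factory for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, factory in sections.items():
        if name in data:
            kwargs[name] = _coerce_section(type(factory()), name, data[name])
        else:
            kwargs[name] = factory()
    return AnalysisConfig(**kwargs).validate()


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Read a YAML (or JSON, a YAML subset) config file; ``None`` -> defaults."""
    if path is None:
        return default_config()
    text = Path(path).read_text()
    return from_dict(yaml.safe_load(text))


def default_config() -> AnalysisConfig:
    return AnalysisConfig().validate()


def to_dict(config: AnalysisConfig) -> dict:
    return dataclasses.asdict(config)
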