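"""Pipeline configuration.

Every tunable default of the analysis lives here, keyed hierarchically
(``signal``, ``segmentation``, ``model``, ``stats``).  Configurations are
plain frozen dataclasses; :func:`load_config` reads a YAML file and
:func:`config_from_dict` builds a :class:`PipelineConfig` from nested
mappings, rejecting unknown keys and range-checking every value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "SignalConfig",
    "SegmentationConfig",
    "ModelConfig",
    "StatsConfig",
    "PipelineConfig",
    "config_from_dict",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass(frozen=True)
class SignalConfig:
    """Envelope reduction, quality control and artifact screening."""

    #: rectify-and-average block length in raw nerve samples (25 kHz -> 25 Hz)
    ra_window: int = 1000
    #: odd frame length (envelope samples) of the first-order Savitzky-Golay
    #: smoother applied to the relaxation-phase envelope; 25 samples = 1 s
    savgol_frame: int = 25
    #: artifact rule: flag |first difference| > k * MAD(differences)
    artifact_k: float = 8.0
    #: exclude the whole measurement when more than this fraction is flagged
    artifact_exclude_fraction: float = 0.01
    #: inclusion threshold on the ten-highest/ten-lowest SNR estimate
    snr_min: float = 0.5

    def validate(self) -> None:
        if self.ra_window < 1:
            raise ConfigError("signal.ra_window must be >= 1")
        if self.savgol_frame < 3 or self.savgol_frame % 2 == 0:
            raise ConfigError("signal.savgol_frame must be odd and >= 3")
        if self.artifact_k <= 0:
            raise ConfigError("signal.artifact_k must be > 0")
        if not 0 < self.artifact_exclude_fraction <= 1:
            raise ConfigError("signal.artifact_exclude_fraction must be in (0, 1]")
        if self.snr_min < 0:
            raise ConfigError("signal.snr_min must be >= 0")


@dataclass(frozen=True)
class SegmentationConfig:
    """Voiding/baseline/onset landmark detection."""

    #: band (Hz) in which urethral-sphincter HFO are sought in the pressure
    hfo_band: tuple[float, float] = (3.0, 12.0)
    #: centred sliding-RMS window (s) for the HFO envelope
    hfo_rms_window_s: float = 1.0
    #: detection threshold = k * median HFO-band envelope
    hfo_threshold_k: float = 4.0
    #: absolute floor (cmH2O RMS) under the median, so noise-free traces
    #: cannot trigger on numerical residue
    hfo_threshold_floor: float = 0.05
    #: minimum sustained supra-threshold duration (s) to call a void
    hfo_min_duration_s: float = 0.5
    #: window after HFO cessation searched for the pressure maximum t2 (s)
    t2_search_s: float = 5.0
    #: width of the consecutive windows of the baseline rule (s)
    baseline_window_s: float = 1.0
    #: baseline rule: stop at the first inter-window mean difference below
    #: this value (cmH2O)
    baseline_delta: float = 2.0
    #: contraction onset: pressure must exceed passive-phase median by this
    #: margin (cmH2O)
    onset_margin: float = 2.0
    #: smoothing window (s) applied before the backward onset walk
    onset_smooth_s: float = 1.0
    #: allowed non-monotonicity (cmH2O) in the backward rise check
    onset_tolerance: float = 0.5
    #: fallback onset = t1 - this interval (s) when no rise is found
    onset_fallback_s: float = 15.0
    #: if true, capacity uses the contraction onset instead of t1
    capacity_from_onset: bool = False

    def validate(self) -> None:
        lo, hi = self.hfo_band
        if not 0 < lo < hi:
            raise ConfigError("segmentation.hfo_band must satisfy 0 < low < high")
        for name in (
            "hfo_rms_window_s",
            "hfo_threshold_k",
            "hfo_threshold_floor",
            "hfo_min_duration_s",
            "t2_search_s",
            "baseline_window_s",
            "baseline_delta",
            "onset_smooth_s",
            "onset_fallback_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"segmentation.{name} must be > 0")
        if self.onset_margin < 0 or self.onset_tolerance < 0:
            raise ConfigError("segmentation onset margin/tolerance must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Decay and linear afferent-model fitting."""

    #: exclude relaxation samples within eps (cmH2O) of the baseline before
    #: the log-domain decay fit
    decay_epsilon: float = 0.5
    #: minimum usable samples for any fit
    min_fit_samples: int = 10
    #: the volume model consumes the model-derived afferent estimate; set to
    #: False to regress the raw envelope on volume instead
    volume_uses_estimate: bool = True
    #: tail length (s) averaged for the asymptotic-pressure estimate passed
    #: to the decay fit
    asymptote_tail_s: float = 3.0

    def validate(self) -> None:
        if self.decay_epsilon <= 0:
            raise ConfigError("model.decay_epsilon must be > 0")
        if self.min_fit_samples < 3:
            raise ConfigError("model.min_fit_samples must be >= 3")
        if self.asymptote_tail_s <= 0:
            raise ConfigError("model.asymptote_tail_s must be > 0")


@dataclass(frozen=True)
class StatsConfig:
    """Two-group comparison."""

    #: significance level for the Mann-Whitney U test
    alpha: float = 0.05
    #: exact enumeration is used when n_a + n_b is at most this and there
    #: are no ties; otherwise the tie-corrected normal approximation
    exact_max_n: int = 12

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("stats.alpha must be in (0, 1)")
        if self.exact_max_n < 2:
            raise ConfigError("stats.exact_max_n must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> "PipelineConfig":
        self.signal.validate()
        self.segmentation.validate()
        self.model.validate()
        self.stats.validate()
        return self


_SECTIONS = {
    "signal": SignalConfig,
    "segmentation": SegmentationConfig,
    "model": ModelConfig,
    "stats": StatsConfig,
}


def _section_from_dict(cls: type, name: str, data: Mapping[str, Any]) -> Any:
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    coerced: dict[str, Any] = {}
    for key, value in data.items():
        if key == "hfo_band":
            value = tuple(float(v) for v in value)
        coerced[key] = value
    return cls(**coerced)


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from nested mappings."""
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    sections = {
        name: _section_from_dict(cls, name, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(**sections).validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_dict(data)
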