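"""Nerve-signal reduction and quality control.

The raw electroneurogram (nominally 25 kHz) is reduced to a 25 Hz activity
envelope by rectifying and block-averaging (mean absolute value of each
1000-sample block), aligned with the simultaneously recorded bladder
pressure.  Quality control consists of a ten-highest/ten-lowest SNR
estimate with an inclusion threshold, a MAD-based screen for sharp pressure
artifacts, per-recording normalization, and first-order Savitzky-Golay
smoothing of relaxation-phase segments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .config import SignalConfig

__all__ = [
    "RawRecording",
    "AveragedRecording",
    "SNRResult",
    "ArtifactResult",
    "rectify_average",
    "compute_snr",
    "normalize_traces",
    "smooth_relaxation",
    "flag_artifacts",
    "reduce_recording",
    "SignalError",
]


class SignalError(ValueError):
    """Raised for degenerate or malformed signal inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Dual-rate cystometry + whole-nerve recording.

    Parameters
    ----------
    pressure
        Bladder pressure (cmH2O) sampled at ``pressure_rate_hz``.
    nerve
        Raw nerve voltage (V) sampled at ``nerve_rate_hz``.
    infusion_rate
        Intravesical infusion rate in ml/min.
    condition
        Infusate label, ``"saline"`` or ``"AA"`` (0.5 % acetic acid).
    """

    pressure: np.ndarray
    nerve: np.ndarray
    pressure_rate_hz: float = 25.0
    nerve_rate_hz: float = 25000.0
    infusion_rate: float = 0.05
    condition: str = "saline"
    t0_is_fill_start: bool = True
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.nerve = np.asarray(self.nerve, dtype=float)
        if self.pressure_rate_hz <= 0 or self.nerve_rate_hz <= 0:
            raise SignalError("sampling rates must be positive")
        ratio = self.nerve_rate_hz / self.pressure_rate_hz
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise SignalError(
                "nerve_rate_hz must be a positive integer multiple of "
                "pressure_rate_hz"
            )
        if not (np.isfinite(self.pressure).all() and np.isfinite(self.nerve).all()):
            raise SignalError("recording contains non-finite samples")
        if self.condition not in ("saline", "AA"):
            raise SignalError(f"unknown condition {self.condition!r}")

    @property
    def rate_ratio(self) -> int:
        return int(round(self.nerve_rate_hz / self.pressure_rate_hz))

    @property
    def duration_s(self) -> float:
        return len(self.pressure) / self.pressure_rate_hz

    def time_pressure(self) -> np.ndarray:
        """Time axis (s) of the pressure channel, t=0 at fill start."""
        return np.arange(len(self.pressure)) / self.pressure_rate_hz


@dataclass
class AveragedRecording:
    """Rectified-averaged envelope aligned with pressure at the low rate."""

    ra_nerve: np.ndarray
    pressure: np.ndarray
    rate_hz: float
    #: True where the pressure shows a sharp artifact
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.ra_nerve = np.asarray(self.ra_nerve, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.ra_nerve), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if not (len(self.ra_nerve) == len(self.pressure) == len(self.artifact_mask)):
            raise SignalError("envelope, pressure and mask lengths differ")
        if (self.ra_nerve < 0).any():
            raise SignalError("rectified-averaged envelope must be non-negative")

    def time(self) -> np.ndarray:
        return np.arange(len(self.ra_nerve)) / self.rate_hz

    def valid(self) -> np.ndarray:
        return ~self.artifact_mask


@dataclass(frozen=True)
class SNRResult:
    """Ten-highest/ten-lowest signal-to-noise estimate of an envelope."""

    snr: float
    mean_high10: float
    mean_low10: float
    #: inclusion decision: activity at least 50 % above baseline
    include: bool


@dataclass(frozen=True)
class ArtifactResult:
    mask: np.ndarray
    flagged_fraction: float
    #: measurement-level verdict: True means drop the whole measurement
    exclude: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rectify_average(nerve: np.ndarray, window: int = 1000) -> np.ndarray:
    """Rectify and block-average a raw nerve trace.

    Output sample ``k`` is the mean absolute value of the ``k``-th
    consecutive non-overlapping block of ``window`` raw samples; a trailing
    partial block is discarded.  With the nominal rates this reduces 1 s of
    25 kHz signal to 25 envelope samples.
    """
    nerve = np.asarray(nerve, dtype=float)
    if window < 1:
        raise SignalError("window must be a positive integer")
    n_blocks = len(nerve) // window
    if n_blocks < 1:
        raise SignalError(
            f"trace of length {len(nerve)} shorter than one window ({window})"
        )
    blocks = np.abs(nerve[: n_blocks * window]).reshape(n_blocks, window)
    return blocks.mean(axis=1)


def compute_snr(envelope: np.ndarray, mask: np.ndarray | None = None,
                snr_min: float = 0.5) -> SNRResult:
    """SNR = (mean of ten highest - mean of ten lowest) / mean of ten lowest.

    The ten lowest envelope values are taken to represent baseline activity
    and the ten highest compound action-potential activity.  ``mask`` marks
    artifact samples to ignore.  The inclusion flag is ``snr > snr_min``
    (default 0.5, i.e. activity at least 50 % above baseline).
    """
    envelope = np.asarray(envelope, dtype=float)
    if mask is not None:
        envelope = envelope[~np.asarray(mask, dtype=bool)]
    if len(envelope) < 20:
        raise SignalError("SNR needs at least 20 valid envelope samples")
    ordered = np.sort(envelope, kind="stable")
    low10 = float(ordered[:10].mean())
    high10 = float(ordered[-10:].mean())
    if low10 == 0.0:
        raise SignalError("mean of ten lowest values is zero (degenerate trace)")
    snr = (high10 - low10) / low10
    return SNRResult(snr=snr, mean_high10=high10, mean_low10=low10,
                     include=snr > snr_min)


def normalize_traces(avg: AveragedRecording) -> AveragedRecording:
    """Normalize an averaged recording for between-animal comparison.

    The envelope is divided by the maximum afferent activity, defined as the
    mean of its ten highest values; pressure is divided by its single
    maximum.  Artifact-masked samples do not contribute to either maximum.
    """
    env = avg.ra_nerve[avg.valid()]
    if len(env) < 10:
        raise SignalError("need at least 10 valid envelope samples to normalize")
    na_max = float(np.sort(env, kind="stable")[-10:].mean())
    p_max = float(avg.pressure[avg.valid()].max()) if avg.valid().any() else 0.0
    if na_max <= 0 or p_max <= 0:
        raise SignalError("degenerate zero maximum; cannot normalize")
    return AveragedRecording(
        ra_nerve=avg.ra_nerve / na_max,
        pressure=avg.pressure / p_max,
        rate_hz=avg.rate_hz,
        artifact_mask=avg.artifact_mask.copy(),
        normalized=True,
    )


def smooth_relaxation(segment: np.ndarray, frame: int = 25) -> np.ndarray:
    """First-order Savitzky-Golay smoothing of an envelope segment.

    A polynomial-order-1 local least-squares smoother; for a centred frame
    this equals the frame's moving average in the interior.  ``frame`` must
    be odd and no longer than the segment (default 25 samples = 1 s at the
    reduced rate).
    """
    segment = np.asarray(segment, dtype=float)
    if frame % 2 == 0 or frame < 3:
        raise SignalError("Savitzky-Golay frame must be odd and >= 3")
    if frame > len(segment):
        raise SignalError(
            f"frame ({frame}) exceeds segment length ({len(segment)})"
        )
    return savgol_filter(segment, window_length=frame, polyorder=1)


def flag_artifacts(pressure: np.ndarray, k: float = 8.0,
                   exclude_fraction: float = 0.01) -> ArtifactResult:
    """Screen the pressure trace for random sharp high-amplitude peaks.

    A sample is flagged when the first difference on either side exceeds
    ``k`` times the median absolute deviation (MAD) of all first
    differences.  When the MAD is exactly zero (essentially constant
    trace) any nonzero difference counts as a spike.  The measurement-level
    verdict is exclusion when more than ``exclude_fraction`` of samples are
    flagged, mirroring per-measurement rejection of movement artifacts.
    """
    pressure = np.asarray(pressure, dtype=float)
    if len(pressure) == 0:
        raise SignalError("empty pressure trace")
    mask = np.zeros(len(pressure), dtype=bool)
    if len(pressure) > 1:
        d = np.diff(pressure)
        mad = float(np.median(np.abs(d - np.median(d))))
        if mad > 0:
            big = np.abs(d) > k * mad
        else:
            big = np.abs(d) > 0
        # a large step between samples i and i+1 implicates both
        mask[:-1] |= big
        mask[1:] |= big
    frac = float(mask.mean())
    return ArtifactResult(mask=mask, flagged_fraction=frac,
                          exclude=frac > exclude_fraction)


def reduce_recording(rec: RawRecording,
                     cfg: SignalConfig | None = None) -> tuple[AveragedRecording, ArtifactResult]:
    """Reduce a raw recording to an aligned, artifact-screened envelope.

    The rectify-average window defaults to the rate ratio so that every
    envelope sample lines up with one pressure sample.
    """
    cfg = cfg or SignalConfig()
    window = rec.rate_ratio if cfg.ra_window == 1000 and rec.rate_ratio != 1000 \
        else cfg.ra_window
    ra = rectify_average(rec.nerve, window=window)
    n = min(len(ra), len(rec.pressure))
    pressure = rec.pressure[:n]
    ra = ra[:n]
    artifacts = flag_artifacts(pressure, k=cfg.artifact_k,
                               exclude_fraction=cfg.artifact_exclude_fraction)
    avg = AveragedRecording(ra_nerve=ra, pressure=pressure,
                            rate_hz=rec.pressure_rate_hz,
                            artifact_mask=artifacts.mask[:n])
    return avg, artifacts
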