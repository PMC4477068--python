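"""Cystometrogram phase segmentation.

Splits a recording into filling (t < t1), voiding (t1..t2) and relaxation
(t > t2) phases.  Voiding is delimited by the high-frequency oscillations
(HFO) that rapid urethral-sphincter contractions superimpose on the
pressure: t1 is the HFO onset (the pressure there is the threshold
pressure) and t2 the pressure maximum after HFO cessation.  The post-void
baseline is found by comparing consecutive 1-s window means until they
differ by less than 2 cmH2O.  The voiding interval itself is excluded from
all downstream fits because of movement artifacts in both channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .config import SegmentationConfig

__all__ = [
    "PhaseAnnotation",
    "detect_voiding",
    "detect_baseline",
    "detect_contraction_onset",
    "compute_volume",
    "annotate_recording",
    "NoVoidingDetected",
    "SegmentationError",
]

logger = logging.getLogger("neurocystometry")


class SegmentationError(ValueError):
    """Raised when a landmark cannot be computed."""


class NoVoidingDetected(SegmentationError):
    """The pressure trace contains no supra-threshold HFO interval."""


@dataclass(frozen=True)
class PhaseAnnotation:
    """Pressure landmarks of one voiding cycle (times in s from fill start)."""

    t_contraction_onset: float
    t1: float
    t2: float
    t_baseline: float
    p_thres: float      # cmH2O at t1
    p_baseline: float   # cmH2O, 1-s-window rule

    def __post_init__(self) -> None:
        if not (0 <= self.t_contraction_onset <= self.t1 < self.t2
                < self.t_baseline):
            raise SegmentationError(
                "phase ordering violated: need 0 <= onset <= t1 < t2 < t_baseline"
            )
        if self.p_thres < self.p_baseline:
            raise SegmentationError("p_thres must be >= p_baseline")


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_voiding(pressure: np.ndarray, fs: float = 25.0,
                   cfg: SegmentationConfig | None = None,
                   ) -> tuple[float, float, float]:
    """Locate the voiding phase; returns ``(t1, t2, p_thres)``.

    The pressure is band-passed in the HFO band, a centred sliding-RMS
    envelope is thresholded at ``k`` times its median (the trace is
    dominated by non-voiding samples, so the median measures the
    filling-phase floor), and the first sufficiently sustained
    supra-threshold run delimits the HFO.  ``t2`` is the time of maximum
    pressure within a short window after HFO cessation and ``p_thres`` the
    pressure at ``t1`` (taken on the HFO-band-removed trace, so that a
    detection landing a sample inside the oscillation still reads the
    underlying contraction pressure).
    """
    cfg = cfg or SegmentationConfig()
    pressure = np.asarray(pressure, dtype=float)
    if len(pressure) < int(2 * fs):
        raise SegmentationError("pressure trace too short for voiding detection")

    lo, hi = cfg.hfo_band
    hi = min(hi, 0.99 * fs / 2.0)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sosfiltfilt(sos, pressure)
    win = max(int(round(cfg.hfo_rms_window_s * fs)), 1)
    rms = np.sqrt(uniform_filter1d(band * band, size=win, mode="nearest"))

    threshold = cfg.hfo_threshold_k * max(float(np.median(rms)),
                                          cfg.hfo_threshold_floor)
    min_run = max(int(round(cfg.hfo_min_duration_s * fs)), 1)
    runs = [r for r in _contiguous_runs(rms > threshold)
            if r[1] - r[0] >= min_run]
    if not runs:
        raise NoVoidingDetected("no voiding detected")

    start, stop = runs[0]
    t1_idx = start
    cess_idx = stop - 1
    search_stop = min(cess_idx + int(round(cfg.t2_search_s * fs)) + 1,
                      len(pressure))
    t2_idx = cess_idx + int(np.argmax(pressure[cess_idx:search_stop]))
    if t2_idx <= t1_idx:
        t2_idx = t1_idx + 1
    p_thres = float(pressure[t1_idx] - band[t1_idx])
    return t1_idx / fs, t2_idx / fs, p_thres


def detect_baseline(pressure: np.ndarray, t2: float, fs: float = 25.0,
                    cfg: SegmentationConfig | None = None,
                    ) -> tuple[float, float]:
    """Post-void baseline by the consecutive-window rule.

    The pressure after ``t2`` is divided into successive non-overlapping
    windows (1 s by default); the first pair of consecutive windows whose
    means differ by less than 2 cmH2O (absolute difference) sets
    ``p_baseline`` to the first window's mean and ``t_baseline`` to the end
    of that window.  If no pair qualifies the final window is used, with a
    warning.
    """
    cfg = cfg or SegmentationConfig()
    pressure = np.asarray(pressure, dtype=float)
    win = max(int(round(cfg.baseline_window_s * fs)), 1)
    start = int(round(t2 * fs))
    tail = pressure[start:]
    n_win = len(tail) // win
    if n_win < 2:
        raise SegmentationError("insufficient post-void data for baseline rule")
    means = tail[: n_win * win].reshape(n_win, win).mean(axis=1)
    for i in range(n_win - 1):
        if abs(means[i] - means[i + 1]) < cfg.baseline_delta:
            t_baseline = (start + (i + 1) * win) / fs
            return t_baseline, float(means[i])
    logger.warning("baseline rule never satisfied; falling back to final window")
    return (start + n_win * win) / fs, float(means[-1])


def detect_contraction_onset(pressure: np.ndarray, t1: float, fs: float = 25.0,
                             cfg: SegmentationConfig | None = None) -> float:
    """Onset of the active contraction preceding voiding.

    Working on a 1-s-smoothed pressure, the onset is the latest upcrossing
    of (passive-phase median + margin) from which the smoothed pressure
    rises monotonically (within a small tolerance) until ``t1``.  When the
    criterion is never met the onset falls back to ``t1`` minus a fixed
    lead (15 s by default), floored at 0, with a warning.
    """
    cfg = cfg or SegmentationConfig()
    pressure = np.asarray(pressure, dtype=float)
    t1_idx = int(round(t1 * fs))
    fallback = max(t1 - cfg.onset_fallback_s, 0.0)
    if t1_idx < 2:
        return fallback

    win = max(int(round(cfg.onset_smooth_s * fs)), 1)
    smooth = uniform_filter1d(pressure[:t1_idx], size=win, mode="nearest")
    level = float(np.median(smooth)) + cfg.onset_margin

    # furthest index from which the rise to t1 is monotone (with tolerance)
    rise_start = t1_idx - 1
    running = smooth[t1_idx - 1]
    for i in range(t1_idx - 2, -1, -1):
        if smooth[i] > running + cfg.onset_tolerance:
            break
        running = min(running, smooth[i])
        rise_start = i

    seg = smooth[rise_start:t1_idx]
    above = seg > level
    if not above.any() or above.all():
        logger.warning("contraction-onset criterion not met; using t1 - %.0f s",
                       cfg.onset_fallback_s)
        return fallback
    crossing = rise_start + int(np.argmax(above))
    return crossing / fs


def compute_volume(t1: float, infusion_rate: float, pressure: np.ndarray,
                   fs: float = 25.0) -> tuple[np.ndarray, float]:
    """Infused-volume trace (ml) and bladder capacity.

    Filling runs at ``infusion_rate`` (ml/min) from t=0 and stops at the
    voiding onset, so ``volume(t) = rate * t`` for ``t <= t1`` and constant
    afterwards; capacity is the volume at ``t1``.
    """
    if infusion_rate <= 0:
        raise SegmentationError("infusion_rate must be > 0")
    t = np.arange(len(np.asarray(pressure))) / fs
    volume = infusion_rate / 60.0 * np.minimum(t, t1)
    capacity = infusion_rate / 60.0 * t1
    return volume, capacity


def annotate_recording(pressure: np.ndarray, fs: float = 25.0,
                       cfg: SegmentationConfig | None = None) -> PhaseAnnotation:
    """Run the full landmark detection on one pressure trace."""
    cfg = cfg or SegmentationConfig()
    t1, t2, p_thres = detect_voiding(pressure, fs=fs, cfg=cfg)
    t_baseline, p_baseline = detect_baseline(pressure, t2, fs=fs, cfg=cfg)
    t_onset = detect_contraction_onset(pressure, t1, fs=fs, cfg=cfg)
    return PhaseAnnotation(
        t_contraction_onset=t_onset,
        t1=t1,
        t2=t2,
        t_baseline=t_baseline,
        p_thres=p_thres,
        p_baseline=p_baseline,
    )
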