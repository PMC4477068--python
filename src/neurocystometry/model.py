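"""Afferent-activity modeling.

Three modeling steps on each segmented recording:

1. *Decay fit* — the isovolumetric relaxation pressure is fitted with a
   single exponential ``p(t) = A * exp(-t / tau)`` above baseline; the time
   constant tests the absence of efferent drive after voiding (a passive
   bladder relaxes with a condition-independent tau).
2. *Linear afferent model* — in the relaxation phase, where all recorded
   activity is afferent, the smoothed envelope is regressed on pressure:
   ``NA(t) = m * p(t) + NA0``.  The slope ``m`` measures the sensitivity of
   the afferent fibers to pressure, the offset ``NA0`` the baseline
   activity.  The fitted line is then extrapolated to the filling phase,
   where efferent activity contaminates the measured envelope, to estimate
   its afferent component.
3. *Volume model* — the filling-phase afferent estimate is regressed on
   infused volume, with Pearson's product-moment correlation quantifying
   the linear dependence.

All fits are ordinary least squares; the voiding interval (t1..t2) is never
included in any fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields
from typing import Any

import numpy as np

from .config import ModelConfig, SignalConfig
from .processing import (AveragedRecording, RawRecording, SNRResult,
                         compute_snr, normalize_traces, smooth_relaxation)
from .segmentation import PhaseAnnotation

__all__ = [
    "DecayFit",
    "LinearFit",
    "FillingEstimate",
    "MeasurementSummary",
    "fit_decay",
    "fit_na_pressure",
    "estimate_filling_afferent",
    "fit_na_volume",
    "summarize_measurement",
    "FitError",
]

logger = logging.getLogger("neurocystometry")


class FitError(ValueError):
    """Raised when a fit is undefined on the given data."""


@dataclass(frozen=True)
class DecayFit:
    """Exponential pressure-decay fit ``p = A * exp(-t/tau)`` above baseline."""

    A: float              # cmH2O
    tau: float            # s
    r_squared_log: float  # goodness of the log-domain fit
    n_points: int

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.A <= 0:
            raise FitError("decay fit requires A > 0 and tau > 0")


@dataclass(frozen=True)
class LinearFit:
    """Simple least-squares line with Pearson correlation.

    Units follow the inputs: volts per cmH2O and volts for fits on raw
    traces, dimensionless for fits on normalized traces.
    """

    m: float
    na0: float
    pearson_r: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FitError("linear fit needs at least 3 points")
        if not -1.0000001 <= self.pearson_r <= 1.0000001:
            raise FitError("Pearson r out of range")


@dataclass(frozen=True)
class FillingEstimate:
    """Model-extrapolated afferent envelope over the filling phase."""

    na_est: np.ndarray
    #: mean estimate over the passive sub-phase [0, contraction onset)
    fill_baseline_na: float
    #: mean estimate over the active contraction [onset, t1)
    fill_active_na: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_decay(time: np.ndarray, pressure: np.ndarray, p_baseline: float,
              epsilon: float = 0.5, min_samples: int = 10) -> DecayFit:
    """Fit the relaxation-phase exponential in the log domain.

    ``log(p - p_baseline)`` is regressed on time (measured from the start
    of the segment, i.e. from t2); ``tau = -1/slope`` and ``A`` is the
    intercept's exponential.  Samples within ``epsilon`` (cmH2O) of the
    baseline are excluded — their logarithm is dominated by noise.
    """
    time = np.asarray(time, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if len(time) != len(pressure):
        raise FitError("time and pressure lengths differ")
    above = pressure - p_baseline > epsilon
    if above.sum() < min_samples:
        raise FitError(
            f"fewer than {min_samples} samples above baseline + epsilon"
        )
    t = time[above] - time[0]
    y = np.log(pressure[above] - p_baseline)
    if np.ptp(y) == 0:
        raise FitError("no decay: constant pressure segment")
    slope, intercept = _ols_line(t, y)
    # a slope indistinguishable from zero at float precision is no decay
    if slope >= -1e-12 / (np.ptp(t) or 1.0):
        raise FitError("no decay: non-negative log-domain slope")
    r = float(np.corrcoef(t, y)[0, 1])
    return DecayFit(A=float(np.exp(intercept)), tau=-1.0 / slope,
                    r_squared_log=r * r, n_points=int(above.sum()))


def fit_na_pressure(na: np.ndarray, pressure: np.ndarray,
                    min_samples: int = 10) -> LinearFit:
    """Least-squares fit of envelope activity on pressure (Eq. ``NA = m p + NA0``).

    Expects relaxation-phase samples only (the voiding interval must
    already be masked out).  Slope and offset keep the units of the inputs;
    Pearson r and r^2 are computed on the same pairs.
    """
    na = np.asarray(na, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if len(na) != len(pressure):
        raise FitError("envelope and pressure lengths differ")
    if len(na) < min_samples:
        raise FitError(f"fewer than {min_samples} paired samples")
    if np.ptp(pressure) == 0:
        raise FitError("constant pressure segment: slope undefined")
    slope, intercept = _ols_line(pressure, na)
    if np.ptp(na) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pressure, na)[0, 1])
    return LinearFit(m=slope, na0=intercept, pearson_r=r, r_squared=r * r,
                     n_points=len(na))


def estimate_filling_afferent(fit: LinearFit, pressure_fill: np.ndarray,
                              fs: float, t_onset: float, t1: float,
                              ) -> FillingEstimate:
    """Extrapolate the relaxation-phase line to the filling phase.

    ``NA_est(t) = m * p(t) + NA0`` pointwise over ``t < t1``; also reports
    the mean estimate over the passive sub-phase and over the active
    contraction interval ``[t_onset, t1)``.
    """
    pressure_fill = np.asarray(pressure_fill, dtype=float)
    na_est = fit.m * pressure_fill + fit.na0
    onset_idx = int(round(t_onset * fs))
    onset_idx = min(max(onset_idx, 0), len(na_est))
    passive = na_est[:onset_idx]
    active = na_est[onset_idx:]
    fill_baseline = float(passive.mean()) if len(passive) else float("nan")
    fill_active = float(active.mean()) if len(active) else float("nan")
    return FillingEstimate(na_est=na_est, fill_baseline_na=fill_baseline,
                           fill_active_na=fill_active)


def fit_na_volume(na_est: np.ndarray, volume: np.ndarray,
                  min_samples: int = 10) -> LinearFit:
    """Least-squares fit of filling-phase afferent activity on infused volume."""
    na_est = np.asarray(na_est, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if len(na_est) != len(volume):
        raise FitError("estimate and volume lengths differ")
    if len(volume) < min_samples:
        raise FitError(f"fewer than {min_samples} paired samples")
    if np.ptp(volume) == 0:
        raise FitError("degenerate constant volume")
    slope, intercept = _ols_line(volume, na_est)
    if np.ptp(na_est) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(volume, na_est)[0, 1])
    return LinearFit(m=slope, na0=intercept, pearson_r=r, r_squared=r * r,
                     n_points=len(volume))


# ---------------------------------------------------------------------------
# per-measurement summary
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSummary:
    """Per-measurement parameter panel.

    Phase means and the ``*_norm`` fits are computed on normalized traces
    (envelope divided by the mean of its ten highest values, pressure by
    its maximum); ``slope_raw`` is in uV per cmH2O and ``offset_raw`` in V.
    """

    condition: str
    excluded: bool = False
    exclusion_reason: str = ""
    snr: float = float("nan")
    snr_ok: bool = False
    p_thres: float = float("nan")
    p_baseline: float = float("nan")
    capacity_ml: float = float("nan")
    tau_s: float = float("nan")
    fill_baseline_na: float = float("nan")
    fill_active_na: float = float("nan")
    relax_mean_na: float = float("nan")
    relax_max_na: float = float("nan")
    relax_mean_p: float = float("nan")
    slope_raw: float = float("nan")
    offset_raw: float = float("nan")
    slope_norm: float = float("nan")
    offset_norm: float = float("nan")
    pearson_r_p: float = float("nan")
    r_squared_p: float = float("nan")
    slope_vol: float = float("nan")
    offset_vol: float = float("nan")
    pearson_r_vol: float = float("nan")

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    @classmethod
    def parameter_names(cls) -> list[str]:
        """Numeric parameters compared between conditions, in fixed order."""
        skip = {"condition", "excluded", "exclusion_reason", "snr_ok"}
        return [f.name for f in dataclass_fields(cls) if f.name not in skip]


def _phase_indices(annotation: PhaseAnnotation, fs: float, n: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(filling, relaxation) index arrays; the voiding interval is dropped."""
    idx = np.arange(n)
    t = idx / fs
    filling = idx[t < annotation.t1]
    relax = idx[(t > annotation.t2) & (t <= annotation.t_baseline)]
    return filling, relax


def summarize_measurement(rec: RawRecording, avg: AveragedRecording,
                          annotation: PhaseAnnotation,
                          snr: SNRResult,
                          signal_cfg: SignalConfig | None = None,
                          model_cfg: ModelConfig | None = None,
                          ) -> MeasurementSummary:
    """Assemble the full parameter panel for one measurement.

    Runs the decay fit, the relaxation-phase linear model on raw and
    normalized traces, the filling-phase extrapolation and the volume
    model.  Fits that fail on this recording leave their fields NaN and are
    logged; the summary row itself is still produced.
    """
    signal_cfg = signal_cfg or SignalConfig()
    model_cfg = model_cfg or ModelConfig()
    fs = avg.rate_hz

    out = MeasurementSummary(condition=rec.condition)
    out.snr = snr.snr
    out.snr_ok = snr.include
    out.p_thres = annotation.p_thres
    out.p_baseline = annotation.p_baseline

    from .segmentation import compute_volume  # local to avoid cycle at import
    t_cap = (annotation.t_contraction_onset
             if getattr(model_cfg, "capacity_from_onset", False)
             else annotation.t1)
    volume, capacity = compute_volume(t_cap, rec.infusion_rate, avg.pressure,
                                      fs=fs)
    out.capacity_ml = capacity

    filling, relax = _phase_indices(annotation, fs, len(avg.ra_nerve))
    valid = avg.valid()
    relax = relax[valid[relax]]
    filling_v = filling[valid[filling]]

    norm = normalize_traces(avg)
    na_max = (float(np.sort(avg.ra_nerve[valid])[-10:].mean())
              if valid.sum() >= 10 else float("nan"))

    # decay fit: subtract an asymptote estimate (tail mean), which tracks
    # the true resting pressure better than the window-rule baseline
    tail = max(int(round(model_cfg.asymptote_tail_s * fs)), 1)
    p_asym = float(avg.pressure[valid][-tail:].mean()) if valid.sum() >= tail \
        else annotation.p_baseline
    try:
        decay = fit_decay(relax / fs, avg.pressure[relax], p_asym,
                          epsilon=model_cfg.decay_epsilon,
                          min_samples=model_cfg.min_fit_samples)
        out.tau_s = decay.tau
    except FitError as err:
        logger.info("decay fit failed: %s", err)

    if len(relax) >= max(model_cfg.min_fit_samples, signal_cfg.savgol_frame):
        na_relax = smooth_relaxation(avg.ra_nerve[relax],
                                     frame=signal_cfg.savgol_frame)
        na_relax_norm = smooth_relaxation(norm.ra_nerve[relax],
                                          frame=signal_cfg.savgol_frame)
        out.relax_mean_na = float(na_relax_norm.mean())
        out.relax_max_na = float(na_relax_norm.max())
        out.relax_mean_p = float(norm.pressure[relax].mean())
        try:
            fit_raw = fit_na_pressure(na_relax, avg.pressure[relax],
                                      min_samples=model_cfg.min_fit_samples)
            out.slope_raw = fit_raw.m * 1e6  # V/cmH2O -> uV/cmH2O
            out.offset_raw = fit_raw.na0
            out.pearson_r_p = fit_raw.pearson_r
            out.r_squared_p = fit_raw.r_squared

            fit_norm = fit_na_pressure(na_relax_norm, norm.pressure[relax],
                                       min_samples=model_cfg.min_fit_samples)
            out.slope_norm = fit_norm.m
            out.offset_norm = fit_norm.na0

            if len(filling_v) >= model_cfg.min_fit_samples:
                est = estimate_filling_afferent(
                    fit_raw, avg.pressure[filling_v], fs=fs,
                    t_onset=annotation.t_contraction_onset, t1=annotation.t1)
                if np.isfinite(na_max):
                    out.fill_baseline_na = est.fill_baseline_na / na_max
                    out.fill_active_na = est.fill_active_na / na_max
                source = (est.na_est if model_cfg.volume_uses_estimate
                          else avg.ra_nerve[filling_v])
                try:
                    fit_vol = fit_na_volume(source, volume[filling_v],
                                            min_samples=model_cfg.min_fit_samples)
                    out.slope_vol = fit_vol.m
                    out.offset_vol = fit_vol.na0
                    out.pearson_r_vol = fit_vol.pearson_r
                except FitError as err:
                    logger.info("volume fit failed: %s", err)
        except FitError as err:
            logger.info("pressure fit failed: %s", err)
    return out
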