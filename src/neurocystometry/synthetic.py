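"""Synthetic cystometry and whole-nerve signal generator.

Produces seeded dual-rate recordings with a known ground truth, emulating
the statistical structure the analysis assumes: passive filling with small
non-voiding contractions, an active contraction reaching the threshold
pressure, a voiding phase carrying high-frequency oscillations (HFO) of the
urethral sphincter, and isovolumetric exponential relaxation back to
baseline.  The nerve channel is zero-mean amplitude-modulated band-limited
Gaussian noise whose rectified-averaged envelope follows the linear
afferent model ``NA(t) = m * p(t) + NA0``, plus efferent bursts confined to
the filling and voiding phases (absent in "crushed-nerve" variants, where
the nerve is crushed central to the electrode and all recorded activity is
afferent).

Waveforms are phenomenological: there is no biomechanical bladder model,
no urethral resistance, and no per-fiber structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.signal import butter, sosfilt

from .processing import RawRecording

__all__ = [
    "ConditionParams",
    "CohortConfig",
    "GroundTruth",
    "saline_params",
    "aa_params",
    "simulate_pressure",
    "simulate_nerve",
    "generate_recording",
    "generate_cohort",
    "GeneratorError",
]

#: maximum permitted filling time (s); fillings longer than this are not run
MAX_FILL_S = 20.0 * 60.0


class GeneratorError(ValueError):
    """Raised for physically impossible generator parameters."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionParams:
    """Ground-truth parameters of one infusate condition.

    Defaults for the two conditions are provided by :func:`saline_params`
    and :func:`aa_params`.
    """

    label: str  # "saline" | "AA"
    #: infused volume at voiding onset (ml); t1 = capacity / infusion rate
    capacity_ml: float
    #: threshold pressure (cmH2O) at HFO onset, drawn per recording
    p_thres_mean: float
    p_thres_sd: float
    #: stable post-void baseline pressure (cmH2O)
    p_baseline: float
    #: time constant (s) of the isovolumetric exponential relaxation
    tau_s: float
    #: afferent sensitivity, envelope slope vs pressure (uV per cmH2O)
    slope_m: float
    #: baseline afferent envelope at zero pressure (V)
    offset_na0: float
    #: non-voiding contraction amplitude bounds (cmH2O)
    nvc_amp_range: tuple[float, float] = (0.5, 3.0)
    #: non-voiding contractions per minute of passive filling
    nvc_rate: float = 3.0
    #: voiding high-frequency oscillation frequency (Hz) and amplitude (cmH2O)
    hfo_freq_hz: float = 4.0
    hfo_amp: float = 2.5
    #: extra envelope (V) contributed by efferent bursts during filling and
    #: voiding; zero for crushed-nerve variants
    efferent_burst_amp: float = 1.0e-7
    #: unmodulated measurement-noise envelope on the nerve channel (V)
    noise_floor: float = 3.0e-8
    #: white measurement noise on the pressure channel (cmH2O, sd)
    pressure_noise_sd: float = 0.35
    #: pressure rise (cmH2O) across the passive filling phase
    passive_rise: float = 3.0
    #: interval (s) between active-contraction onset and t1
    onset_lead_s: float = 15.0
    #: voiding duration t2 - t1 (s)
    voiding_duration_s: float = 8.0
    #: pressure rise (cmH2O) from p_thres to the maximum at t2
    voiding_rise: float = 8.0
    #: HFO stop this long (s) before t2 ("after cessation of the HFO")
    hfo_gap_s: float = 1.5
    #: carrier band (Hz) of the nerve noise, mimicking the recording chain's
    #: band-pass
    carrier_band_hz: tuple[float, float] = (200.0, 2000.0)
    #: mean efferent bursts per minute and burst duration (s)
    efferent_rate: float = 4.0
    efferent_duration_s: float = 0.5

    def validate(self) -> None:
        if self.capacity_ml <= 0:
            raise GeneratorError("capacity_ml must be > 0")
        if self.tau_s <= 0:
            raise GeneratorError("tau_s must be > 0")
        if self.slope_m < 0:
            raise GeneratorError("slope_m must be >= 0")
        if self.offset_na0 <= 0:
            raise GeneratorError("offset_na0 must be > 0")
        lo, hi = self.nvc_amp_range
        if not 0 <= lo <= hi:
            raise GeneratorError("nvc_amp_range must be ordered and non-negative")
        if self.p_thres_mean <= self.p_baseline:
            raise GeneratorError("p_thres_mean must exceed p_baseline")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration shared by every recording of a cohort."""

    n_per_condition: int = 10
    seed: int = 0
    infusion_rate: float = 0.05  # ml/min
    pressure_rate_hz: float = 25.0
    nerve_rate_hz: float = 25000.0
    conditions: tuple[ConditionParams, ...] = ()

    def __post_init__(self) -> None:
        ratio = self.nerve_rate_hz / self.pressure_rate_hz
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise GeneratorError(
                "nerve_rate_hz must be an integer multiple of pressure_rate_hz"
            )
        if self.infusion_rate <= 0:
            raise GeneratorError("infusion_rate must be > 0")
        hi_hfo = max((c.hfo_freq_hz for c in self.conditions), default=0.0)
        if hi_hfo >= self.pressure_rate_hz / 2:
            raise GeneratorError("hfo_freq_hz must be below pressure Nyquist")

    @property
    def rate_ratio(self) -> int:
        return int(round(self.nerve_rate_hz / self.pressure_rate_hz))


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel attached to each synthetic recording."""

    true_m: float            # uV per cmH2O
    true_na0: float          # V
    true_tau: float          # s
    true_t1: float           # s, HFO / voiding onset
    true_t2: float           # s, pressure maximum after HFO cessation
    true_t_baseline: float   # s, where the 1-s-window rule settles
    true_capacity: float     # ml
    true_p_thres: float      # cmH2O
    true_p_baseline: float   # cmH2O
    true_t_onset: float      # s, active contraction onset

    def __post_init__(self) -> None:
        if not 0 < self.true_t1 < self.true_t2 < self.true_t_baseline:
            raise GeneratorError("ground-truth phase ordering violated")


def saline_params(crushed: bool = False, **overrides) -> ConditionParams:
    """Default saline condition.

    Threshold pressure 33.0 cmH2O and the raw afferent slope/offset follow
    the crushed-nerve saline estimates (0.003 uV/cmH2O, 2.3E-7 V).
    """
    p = ConditionParams(
        label="saline",
        capacity_ml=0.5,
        p_thres_mean=33.0,
        p_thres_sd=3.0,
        p_baseline=5.0,
        tau_s=3.0,
        slope_m=0.003,
        offset_na0=2.3e-7,
    )
    if crushed:
        p = replace(p, efferent_burst_amp=0.0)
    return replace(p, **overrides) if overrides else p


def aa_params(crushed: bool = False, **overrides) -> ConditionParams:
    """Default 0.5 % acetic-acid condition.

    Capacity is 69 % of the saline default (a 31 % reduction), the afferent
    slope is the crushed-nerve AA estimate 0.007 uV/cmH2O (about twice the
    saline slope), offset 2.1E-7 V, threshold pressure 31.0 cmH2O.
    """
    p = ConditionParams(
        label="AA",
        capacity_ml=0.5 * 0.69,
        p_thres_mean=31.0,
        p_thres_sd=3.0,
        p_baseline=5.0,
        tau_s=3.0,
        slope_m=0.007,
        offset_na0=2.1e-7,
    )
    if crushed:
        p = replace(p, efferent_burst_amp=0.0)
    return replace(p, **overrides) if overrides else p


# ---------------------------------------------------------------------------
# pressure channel
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _baseline_rule_settling(a: float, tau: float, window_s: float,
                            delta: float) -> float:
    """Time after t2 at which the 1-s-window baseline rule settles.

    For a pure exponential ``a * exp(-t/tau)`` above baseline, the mean over
    window k is ``a*tau*(1-exp(-w/tau))*exp(-k*w/tau)/w`` and the difference
    between consecutive window means decays geometrically; the rule accepts
    the first pair whose difference falls below ``delta``.
    """
    w = window_s
    decay = 1.0 - math.exp(-w / tau)
    k = 0
    while True:
        diff = a * tau * decay * decay * math.exp(-k * w / tau) / w
        if diff < delta:
            return (k + 1) * w
        k += 1
        if k > 10000:  # pragma: no cover - defensive
            return (k + 1) * w


def simulate_pressure(params: ConditionParams, cfg: CohortConfig,
                      seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Generate one cystometrogram and its ground truth.

    The trace is piecewise: a compliant passive filling with additive
    non-voiding transients, a smooth active rise reaching the (randomly
    drawn) threshold pressure at ``t1 = capacity / infusion_rate``, an HFO
    band on a rising plateau with the global maximum at ``t2``, and an
    exponential relaxation ``p_baseline + (p(t2)-p_baseline)*exp(-(t-t2)/tau)``
    afterwards.  The trace covers the baseline-settling time plus at least a
    10 s margin (and at least six time constants of relaxation).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fs = cfg.pressure_rate_hz

    t1 = params.capacity_ml / cfg.infusion_rate * 60.0
    if t1 > MAX_FILL_S:
        raise GeneratorError(
            f"capacity {params.capacity_ml} ml at {cfg.infusion_rate} ml/min "
            f"implies a filling time over 20 min"
        )
    t_onset = max(t1 - params.onset_lead_s, 0.0)
    t2 = t1 + params.voiding_duration_s

    p_thres = float(rng.normal(params.p_thres_mean, params.p_thres_sd))
    p_thres = max(p_thres, params.p_baseline + params.passive_rise + 5.0)
    p_max = p_thres + params.voiding_rise
    amp_relax = p_max - params.p_baseline

    settle = _baseline_rule_settling(amp_relax, params.tau_s, 1.0, 2.0)
    t_baseline = t2 + settle
    duration = max(t_baseline + 10.0, t2 + 6.0 * params.tau_s + 10.0)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    p = np.empty(n)

    # passive filling: slow compliant rise
    passive = params.p_baseline + params.passive_rise * np.minimum(
        t / max(t_onset, 1e-9), 1.0)
    p_on = params.p_baseline + params.passive_rise
    # active contraction: smooth monotone rise to p_thres at t1
    active = p_on + (p_thres - p_on) * _smoothstep(
        (t - t_onset) / max(t1 - t_onset, 1e-9))
    # voiding plateau rising to the global maximum at t2
    plateau = p_thres + (p_max - p_thres) * (
        (t - t1) / params.voiding_duration_s) ** 2
    relax = params.p_baseline + amp_relax * np.exp(-(t - t2) / params.tau_s)

    fill = np.where(t < t_onset, passive, active)
    void = plateau
    p = np.where(t < t1, fill, np.where(t <= t2, void, relax))

    # urethral-sphincter HFO, ceasing before the pressure maximum
    t_hfo_end = t2 - params.hfo_gap_s
    hfo_on = (t >= t1) & (t <= t_hfo_end)
    p += np.where(
        hfo_on,
        params.hfo_amp * np.sin(2.0 * np.pi * params.hfo_freq_hz * (t - t1)),
        0.0,
    )

    # non-voiding contractions during passive filling
    lo, hi = params.nvc_amp_range
    n_nvc = rng.poisson(params.nvc_rate * t_onset / 60.0)
    for _ in range(n_nvc):
        t0 = rng.uniform(0.0, max(t_onset - 3.0, 0.0))
        amp = rng.uniform(lo, hi)
        dur = rng.uniform(2.0, 4.0)
        span = (t >= t0) & (t < t0 + dur)
        p[span] += amp * np.sin(np.pi * (t[span] - t0) / dur)

    if params.pressure_noise_sd > 0:
        p += rng.normal(0.0, params.pressure_noise_sd, size=n)

    truth = GroundTruth(
        true_m=params.slope_m,
        true_na0=params.offset_na0,
        true_tau=params.tau_s,
        true_t1=t1,
        true_t2=t2,
        true_t_baseline=t_baseline,
        true_capacity=params.capacity_ml,
        true_p_thres=p_thres,
        true_p_baseline=params.p_baseline,
        true_t_onset=t_onset,
    )
    return p, truth


# ---------------------------------------------------------------------------
# nerve channel
# ---------------------------------------------------------------------------

def _bandlimited_carrier(n: int, fs: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-rectified-mean band-limited Gaussian carrier.

    White Gaussian noise is band-passed (4th-order Butterworth) and rescaled
    so that its mean absolute value is exactly 1; multiplying by an envelope
    then gives that envelope as the expected rectified mean.
    """
    x = rng.standard_normal(n)
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sosfilt(sos, x)
    scale = np.mean(np.abs(y))
    if scale == 0:  # pragma: no cover - defensive
        raise GeneratorError("degenerate carrier")
    return y / scale


def simulate_nerve(pressure: np.ndarray, params: ConditionParams,
                   cfg: CohortConfig, seed: int,
                   truth: GroundTruth | None = None) -> np.ndarray:
    """Generate the raw nerve channel for a given pressure trace.

    The expected rectified mean of each rate-ratio block equals
    ``slope_m * p(t) + offset_na0`` (slope converted from uV to V), with
    Poisson-timed efferent bursts adding envelope only before ``t2`` and an
    unmodulated Gaussian noise floor on top.
    """
    params.validate()
    pressure = np.asarray(pressure, dtype=float)
    rng = np.random.default_rng(seed)
    ratio = cfg.rate_ratio
    n_lo = len(pressure)
    n_hi = n_lo * ratio
    t_lo = np.arange(n_lo) / cfg.pressure_rate_hz

    envelope = params.slope_m * 1e-6 * pressure + params.offset_na0
    envelope = np.maximum(envelope, 0.1 * params.offset_na0)

    if params.efferent_burst_amp > 0:
        t2 = truth.true_t2 if truth is not None else t_lo[-1]
        window = min(t2, t_lo[-1])
        n_bursts = rng.poisson(params.efferent_rate * window / 60.0)
        for _ in range(n_bursts):
            t0 = rng.uniform(0.0, max(window - params.efferent_duration_s, 0.0))
            span = (t_lo >= t0) & (t_lo < t0 + params.efferent_duration_s)
            envelope = envelope + np.where(span, params.efferent_burst_amp, 0.0)

    carrier = _bandlimited_carrier(n_hi, cfg.nerve_rate_hz,
                                   params.carrier_band_hz, rng)
    nerve = carrier * np.repeat(envelope, ratio)
    if params.noise_floor > 0:
        sigma = params.noise_floor * math.sqrt(math.pi / 2.0)
        nerve = nerve + sigma * rng.standard_normal(n_hi)
    return nerve


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def generate_recording(params: ConditionParams, cfg: CohortConfig,
                       seed: int) -> tuple[RawRecording, GroundTruth]:
    """Generate one dual-rate recording with its ground truth."""
    pressure, truth = simulate_pressure(params, cfg, seed)
    nerve = simulate_nerve(pressure, params, cfg, seed + 1, truth=truth)
    rec = RawRecording(
        pressure=pressure,
        nerve=nerve,
        pressure_rate_hz=cfg.pressure_rate_hz,
        nerve_rate_hz=cfg.nerve_rate_hz,
        infusion_rate=cfg.infusion_rate,
        condition=params.label,
        meta={"seed": seed, "crushed": params.efferent_burst_amp == 0.0},
    )
    return rec, truth


def default_cohort_config(n_per_condition: int = 10, seed: int = 0,
                          crushed: bool = False, **kwargs) -> CohortConfig:
    """Two-arm study configuration with the default condition presets."""
    return CohortConfig(
        n_per_condition=n_per_condition,
        seed=seed,
        conditions=(saline_params(crushed=crushed), aa_params(crushed=crushed)),
        **kwargs,
    )


def generate_cohort(cfg: CohortConfig) -> list[tuple[RawRecording, GroundTruth]]:
    """Generate the full two-arm cohort.

    Per-recording seeds are ``cfg.seed * 2**16 + index`` with the index
    running across conditions, so cohorts are reproducible while recordings
    stay mutually independent.
    """
    if cfg.n_per_condition < 0:
        raise GeneratorError("n_per_condition must be >= 0")
    out: list[tuple[RawRecording, GroundTruth]] = []
    index = 0
    for params in cfg.conditions:
        for _ in range(cfg.n_per_condition):
            # keep the spread wide so nearby master seeds do not share
            # per-recording streams
            rec_seed = (cfg.seed * 65536 + index * 2) % (2**31)
            out.append(generate_recording(params, cfg, rec_seed))
            index += 1
    return out
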