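# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package.  It is the design record;
the README gives the user-facing overview.

## The measurement model

A whole-nerve recording from a postganglionic bladder nerve is treated as a
zero-mean, band-limited voltage whose short-time rectified mean (the
"activity envelope") carries the physiological information.  Two channels
are assumed: bladder pressure p(t) in cmH₂O at 25 Hz and nerve voltage in V
at 25 kHz (any integer rate ratio is supported; the rectify-average window
defaults to the ratio so envelope samples align with pressure samples).

The core physiological assumptions, encoded throughout:

1. **Relaxation is purely afferent.**  After the voiding contraction the
   bladder relaxes passively; no efferent drive means every recorded spike
   is afferent.  Two checks support this: the relaxation pressure follows a
   single exponential `p = p_base + A·e^(−t/τ)` with a time constant that
   does not differ between conditions, and crushed-nerve preparations
   (purely afferent by construction) show the same afferent–pressure slope
   as the intact-nerve estimate.
2. **Afferent activity is linear in pressure** over the recorded range:
   `NA(t) = m·p(t) + NA₀`.  The slope m is the pressure sensitivity of the
   afferent population; the offset NA₀ is the activity at zero pressure and
   is dominated by recording noise (the afferents are nearly silent in an
   empty bladder).
3. **The voiding interval (t₁, t₂) is unusable** (movement artifacts in
   both channels) and is excluded from every fit.

## Pipeline stages and parameters

| stage | parameter | default | why |
|---|---|---|---|
| rectify-average | window | 1000 samples | 25 kHz → 25 Hz, aligns 1:1 with pressure |
| SNR screen | threshold | 0.5 | activity ≥ 50 % above baseline; boundary excluded |
| artifact screen | k·MAD on first differences | k = 8 | flags isolated sharp peaks, robust to the slow CMG waveform |
| artifact verdict | flagged fraction | > 1 % excludes | per-measurement rejection |
| HFO detection | band | 3–12 Hz | rat urethral-sphincter oscillation range, below the 12.5 Hz Nyquist |
| | RMS window | 1 s | smooths individual oscillation cycles |
| | threshold | 4 × median envelope, floor 0.05 cmH₂O | median ≈ filling-phase floor; the absolute floor keeps noise-free traces from triggering on numerical residue |
| | min duration | 0.5 s | rejects isolated transients |
| baseline rule | window / delta | 1 s / 2 cmH₂O | consecutive-window mean comparison |
| contraction onset | margin | passive median + 2 cmH₂O, monotone rise to t₁ | no published algorithm; fallback t₁ − 15 s |
| Savitzky–Golay | order / frame | 1 / 25 samples (1 s) | first-order FIR smoothing; frame length is a free choice |
| decay fit | ε exclusion | 0.5 cmH₂O above baseline | log of near-baseline samples is noise-dominated |
| Mann–Whitney | exact branch | n ≤ 12, tie-free | full permutation distribution; otherwise tie-corrected normal + continuity correction |

All of these are exposed in `PipelineConfig` (YAML-loadable, unknown keys
rejected).

### The baseline paradox and the decay fit

The consecutive-window baseline rule stops at the *first* pair of 1-s
windows whose means differ by < 2 cmH₂O.  Applied to an exponential decay
this systematically stops while the pressure is still well above its
asymptote: with A ≈ 36 cmH₂O and τ = 3 s the rule settles ~6 s after t₂,
where the window mean still exceeds the true resting pressure by several
cmH₂O.  Subtracting that inflated value before the log-domain fit would
bias τ severely (the late samples' logarithms diverge).  The package
therefore separates the two roles: the rule's output is reported as the
baseline-pressure *parameter* (p_baseline), while the decay fit subtracts
an *asymptote estimate* — the mean pressure over the final seconds of the
recording, long after t_baseline.  With that choice τ recovery on noisy
synthetic recordings is within a few percent (the noise-free limit is
exact to < 0.1 %).

### Units

Raw slopes are reported in µV/cmH₂O and raw offsets in V, matching the
scales on which such recordings are usually quoted (slopes of a few
thousandths of a µV per cmH₂O; offsets of order 10⁻⁷ V).  Normalized
variants divide the envelope by the mean of its ten highest values and the
pressure by its maximum; both normalized fits are reported since either
normalization convention is defensible.

### Capacity

Capacity = infusion rate × t₁.  Whether filling is considered to stop at
the contraction onset or at t₁ is ambiguous in practice; t₁ is the default
and a config flag (`segmentation.capacity_from_onset`) switches to the
onset.

### Volume model

The volume regression consumes the *model-derived* afferent estimate
(`NA_est = m·p + NA₀` over the filling phase), not the raw mixed envelope,
because the quantity of interest is afferent activity and the raw filling
envelope contains efferent bursts.  `model.volume_uses_estimate = false`
switches to the raw envelope.

## The synthetic generator

`synthetic.py` generates recordings whose *statistical structure* matches
the assumptions above; it is phenomenological, not biomechanical (no muscle
model, no urethral resistance, no spike trains).

Pressure: compliant passive filling (baseline 5 cmH₂O rising by 3), small
non-voiding contractions (0.5–3 cmH₂O half-sine bumps, 3/min), a smoothstep
active rise over the last 15 s to a per-recording threshold pressure,
a voiding plateau rising 8 cmH₂O over 8 s carrying a 4 Hz, 2.5 cmH₂O HFO
that ceases 1.5 s before the maximum at t₂, then exponential relaxation
(τ = 3 s) plus white measurement noise (SD 0.35 cmH₂O).

Nerve: white Gaussian noise band-passed to 200–2000 Hz (the usual
amplifier band), normalized empirically to unit rectified mean, and
amplitude-modulated by the envelope `m·p(t) + NA₀` (the analytic Gaussian
calibration E|x| = σ·√(2/π) motivates the construction; the constant is
re-estimated on the filtered carrier because band-limiting changes it
slightly).  Efferent activity is rendered as Poisson-timed 0.5 s envelope
bursts (4/min, 10⁻⁷ V) present only before t₂; crushed-nerve variants set
the burst amplitude to zero.  An unmodulated noise floor (3×10⁻⁸ V
rectified-mean equivalent) adds in quadrature — at the default envelope
scale this perturbs the recovered offset by ~1 %.

Default condition values: saline — capacity 0.5 ml, p_thres 33.0 cmH₂O,
slope 0.003 µV/cmH₂O, offset 2.3×10⁻⁷ V; acetic acid — capacity 0.345 ml
(31 % reduction), p_thres 31.0 cmH₂O, slope 0.007 µV/cmH₂O (≈2× saline),
offset 2.1×10⁻⁷ V.  Filling at 0.05 ml/min implies t₁ = 600 s (saline) and
414 s (AA); fillings longer than 20 min are rejected.

The per-recording threshold-pressure spread is 3 cmH₂O.  Published spreads
for such measurements (±6 cmH₂O) pool between-animal and within-animal
variability; this generator has no animal hierarchy (every recording is
independent), so the smaller within-condition value is used.  Slope,
offset, capacity and τ are fixed per condition for the same reason —
between-recording variation in the estimates then reflects the measurement
process, which is what the recovery tests are about.

Seeding: one master seed; recording *i* of a cohort uses
`master·65536 + 2i` (each recording consumes two adjacent streams, pressure
and nerve).  Plain `master + i` would overlap the streams of neighbouring
recordings.

**What passing recovery tests do and do not show.**  The generator's
envelope is linear in pressure by construction, its relaxation is exactly
exponential, and there is exactly one void per recording.  Recovery of the
generator parameters therefore validates the *estimator chain* — reduction,
segmentation and fitting introduce no material bias — not the biological
adequacy of the linear model, which real recordings must judge.  Features
of real data the generator omits: afferent adaptation and hysteresis,
multi-void recordings, drifting baselines, non-stationary noise,
between-animal variability, and genuine movement artifacts (the artifact
screen is exercised with injected spikes instead).

## Problem sizes

Recovery studies in the test suite run 10 + 9 full-scale crushed-nerve
recordings at 25 kHz (the cohort sizes of the crushed-nerve comparison);
structural and property tests use scaled-down recordings (0.1 ml capacity,
2.5 kHz nerve rate, identical structure), and the null-cohort
type-I-error study runs 200 replicate 5-vs-5 cohorts at that reduced size.

## Known limitations

- Single-void parsing only; the first detected HFO run is *the* void.
- The HFO detector assumes oscillations within 3–12 Hz at ≥ ~1 cmH₂O over
  the pressure-noise floor; weaker or slower voiding signatures need
  config changes.
- The artifact screen flags isolated steps; slow drifts pass.
- No nonlinear (saturating) afferent model; no per-fiber decomposition —
  the recordings are explicitly multifiber.
- Measurements are treated as independent in the group comparison even
  when several come from one animal, matching how such panels are usually
  reported; a mixed-effects treatment is out of scope.
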