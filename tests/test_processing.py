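"""Envelope reduction, SNR, normalization, smoothing, artifact screening."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from neurocystometry import (AveragedRecording, RawRecording, SignalError,
                             compute_snr, flag_artifacts, normalize_traces,
                             rectify_average, smooth_relaxation)


def brute_force_ra(x, window):
    return np.array([np.mean(np.abs(x[k * window:(k + 1) * window]))
                     for k in range(len(x) // window)])


class TestRectifyAverage:
    def test_one_second_of_25khz_gives_25_samples(self, rng):
        out = rectify_average(rng.normal(size=25_000), window=1000)
        assert len(out) == 25

    def test_all_zero_input(self):
        assert np.array_equal(rectify_average(np.zeros(3000)), np.zeros(3))

    def test_sign_symmetry(self, rng):
        x = rng.normal(size=4000)
        assert np.array_equal(rectify_average(x, 500), rectify_average(-x, 500))

    def test_matches_loop_computation(self, rng):
        x = rng.normal(size=4000)
        assert rectify_average(x, 1000) == pytest.approx(
            brute_force_ra(x, 1000))

    @given(
        x=hnp.arrays(np.float64, st.integers(1, 400),
                     elements=st.floats(-1e6, 1e6)),
        window=st.integers(1, 50),
    )
    def test_equals_brute_force_for_all_windows(self, x, window):
        if len(x) < window:
            with pytest.raises(SignalError):
                rectify_average(x, window)
        else:
            assert rectify_average(x, window) == pytest.approx(
                brute_force_ra(x, window), nan_ok=True)

    def test_rejects_bad_window(self):
        with pytest.raises(SignalError):
            rectify_average(np.ones(100), 0)


class TestComputeSNR:
    def test_half_above_baseline_is_inclusion_boundary(self):
        trace = np.array([2.0] * 10 + [3.0] * 10)
        res = compute_snr(trace)
        assert res.snr == pytest.approx(0.5)
        assert not res.include  # inclusion requires SNR strictly above 0.5

    def test_constant_trace(self):
        res = compute_snr(np.full(30, 4.2))
        assert res.snr == 0.0

    def test_matches_sort_oracle(self, rng):
        x = rng.uniform(0.1, 1.0, size=100)
        s = np.sort(x)
        expected = (s[-10:].mean() - s[:10].mean()) / s[:10].mean()
        assert compute_snr(x).snr == pytest.approx(expected)

    @given(perm_seed=st.integers(0, 1000))
    def test_permutation_invariance(self, perm_seed):
        base = np.linspace(0.5, 2.0, 40)
        shuffled = np.random.default_rng(perm_seed).permutation(base)
        assert compute_snr(shuffled).snr == pytest.approx(compute_snr(base).snr)

    def test_too_few_samples(self):
        with pytest.raises(SignalError):
            compute_snr(np.ones(19))

    def test_zero_baseline_rejected(self):
        with pytest.raises(SignalError):
            compute_snr(np.concatenate([np.zeros(10), np.ones(10)]))


class TestNormalizeTraces:
    def _avg(self, ra, p):
        return AveragedRecording(ra_nerve=ra, pressure=p, rate_hz=25.0)

    def test_ten_highest_mean_is_one(self, rng):
        avg = self._avg(rng.uniform(0.5, 2.0, 100), rng.uniform(1, 30, 100))
        norm = normalize_traces(avg)
        assert np.sort(norm.ra_nerve)[-10:].mean() == pytest.approx(1.0)
        assert norm.pressure.max() == pytest.approx(1.0)

    def test_gain_invariance(self, rng):
        ra = rng.uniform(0.5, 2.0, 50)
        p = rng.uniform(1, 30, 50)
        n1 = normalize_traces(self._avg(ra, p))
        n2 = normalize_traces(self._avg(2.0 * ra, p))
        assert n1.ra_nerve == pytest.approx(n2.ra_nerve)

    def test_idempotent(self, rng):
        avg = self._avg(rng.uniform(0.5, 2.0, 60), rng.uniform(1, 30, 60))
        once = normalize_traces(avg)
        twice = normalize_traces(once)
        assert twice.ra_nerve == pytest.approx(once.ra_nerve)
        assert twice.pressure == pytest.approx(once.pressure)


class TestSmoothRelaxation:
    def test_interior_equals_moving_average(self, rng):
        x = rng.normal(size=200)
        frame = 25
        smoothed = smooth_relaxation(x, frame)
        half = frame // 2
        for i in (half, 60, 199 - half):
            window = x[i - half:i + half + 1]
            # first-order local least squares at the centre = window mean
            coeffs = np.polyfit(np.arange(frame), window, 1)
            centre = np.polyval(coeffs, half)
            assert smoothed[i] == pytest.approx(window.mean())
            assert smoothed[i] == pytest.approx(centre)

    def test_affine_input_unchanged(self):
        x = 3.0 + 0.5 * np.arange(100)
        assert smooth_relaxation(x, 25) == pytest.approx(x)

    def test_constant_input_unchanged(self):
        x = np.full(40, 7.0)
        assert smooth_relaxation(x, 25) == pytest.approx(x)

    def test_rejects_even_or_oversized_frame(self):
        with pytest.raises(SignalError):
            smooth_relaxation(np.ones(100), 24)
        with pytest.raises(SignalError):
            smooth_relaxation(np.ones(10), 25)


class TestFlagArtifacts:
    def test_clean_recording_included(self):
        rng = np.random.default_rng(0)
        p = 10.0 + 0.3 * rng.standard_normal(5000)
        res = flag_artifacts(p)
        assert not res.exclude
        assert not res.mask.any()

    def test_single_spike_flagged(self):
        rng = np.random.default_rng(1)
        p = 10.0 + 0.3 * rng.standard_normal(5000)
        p[2500] += 50.0
        res = flag_artifacts(p)
        assert res.mask[2500]
        # threshold arithmetic: the spike's steps dwarf k * MAD of the
        # surrounding noise differences
        d = np.diff(p)
        mad = np.median(np.abs(d - np.median(d)))
        assert 50.0 > 8 * mad
        assert not res.exclude

    def test_heavily_spiked_trace_excluded(self):
        rng = np.random.default_rng(2)
        p = 10.0 + 0.3 * rng.standard_normal(2000)
        spikes = rng.choice(2000, size=100, replace=False)
        p[spikes] += 40.0
        res = flag_artifacts(p)
        assert res.exclude

    def test_constant_trace_clean(self):
        res = flag_artifacts(np.full(100, 5.0))
        assert not res.mask.any()
        assert not res.exclude


class TestRawRecording:
    def test_rejects_non_integer_rate_ratio(self, rng):
        with pytest.raises(SignalError):
            RawRecording(pressure=np.ones(10), nerve=np.ones(100),
                         pressure_rate_hz=25.0, nerve_rate_hz=260.0)

    def test_rejects_non_finite(self):
        nerve = np.ones(100)
        nerve[3] = np.nan
        with pytest.raises(SignalError):
            RawRecording(pressure=np.ones(10), nerve=nerve,
                         pressure_rate_hz=25.0, nerve_rate_hz=250.0)
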