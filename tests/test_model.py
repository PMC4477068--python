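"""Decay fit, linear afferent model, extrapolation, volume model, summary."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurocystometry import (CohortConfig, FitError, analyze_recording,
                             estimate_filling_afferent, fit_decay,
                             fit_na_pressure, fit_na_volume,
                             generate_recording, saline_params,
                             simulate_pressure)

from conftest import small_cohort_config, small_params

FS = 25.0


class TestFitDecay:
    def test_exact_exponential_recovery(self):
        t = np.arange(0, 30, 1 / FS)
        p = 5.0 + 25.0 * np.exp(-t / 8.0)
        fit = fit_decay(t, p, p_baseline=5.0)
        assert fit.tau == pytest.approx(8.0, rel=1e-3)
        assert fit.A == pytest.approx(25.0, rel=1e-3)
        assert fit.r_squared_log == pytest.approx(1.0, abs=1e-9)

    def test_constant_segment_is_no_decay(self):
        t = np.arange(0, 5, 1 / FS)
        with pytest.raises(FitError):
            fit_decay(t, np.full_like(t, 20.0), p_baseline=5.0)

    def test_noisy_preset_recovery_over_seeds(self):
        """Mean fitted tau over 20 noisy recordings within 10 % of truth."""
        cfg = CohortConfig(n_per_condition=1, seed=0)
        params = saline_params(crushed=True)
        taus = []
        for seed in range(20):
            p, truth = simulate_pressure(params, cfg, seed=1000 + seed)
            from neurocystometry import annotate_recording
            ann = annotate_recording(p)
            t = np.arange(len(p)) / FS
            sel = (t > ann.t2) & (t <= ann.t_baseline)
            p_asym = p[-int(3 * FS):].mean()
            taus.append(fit_decay(t[sel], p[sel], p_asym).tau)
        assert np.mean(taus) == pytest.approx(params.tau_s, rel=0.10)


class TestFitNaPressure:
    def test_noise_free_exact_recovery(self):
        # printed crushed-nerve AA values: slope 0.007 uV/cmH2O, offset 2.1E-7 V
        p = np.linspace(10, 40, 200)
        na = 0.007e-6 * p + 2.1e-7
        fit = fit_na_pressure(na, p)
        assert fit.m == pytest.approx(0.007e-6, rel=1e-9)
        assert fit.na0 == pytest.approx(2.1e-7, rel=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_pressure_rejected(self):
        with pytest.raises(FitError):
            fit_na_pressure(np.ones(20), np.full(20, 8.0))

    @given(seed=st.integers(0, 200))
    def test_matches_normal_equations(self, seed):
        """OLS fit equals the closed-form normal-equations solution."""
        r = np.random.default_rng(seed)
        n = r.integers(10, 40)
        x = r.normal(size=n)
        if np.ptp(x) == 0:
            return
        y = r.normal(size=n)
        fit = fit_na_pressure(y, x, min_samples=3)
        X = np.column_stack([x, np.ones(n)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.m == pytest.approx(beta[0], rel=1e-8, abs=1e-12)
        assert fit.na0 == pytest.approx(beta[1], rel=1e-8, abs=1e-12)
        assert fit.r_squared == pytest.approx(fit.pearson_r ** 2, abs=1e-12)

    def test_noisy_cohort_slope_recovery(self):
        """Mean fitted raw slope within 25 % of the generator value."""
        cfg = small_cohort_config()
        params = small_params("AA")
        slopes = []
        for i in range(10):
            rec, truth = generate_recording(params, cfg, seed=40 + 2 * i)
            s = analyze_recording(rec)
            slopes.append(s.slope_raw)
        assert np.mean(slopes) == pytest.approx(params.slope_m, rel=0.25)


class TestEstimateFillingAfferent:
    def _fit(self, m, na0):
        return fit_na_pressure(m * np.linspace(0, 30, 50) + na0,
                               np.linspace(0, 30, 50), min_samples=3)

    def test_zero_slope_gives_constant_offset(self):
        fit = self._fit(0.0, 2.1e-7)
        est = estimate_filling_afferent(fit, np.linspace(3, 30, 100), FS,
                                        t_onset=2.0, t1=4.0)
        assert est.na_est == pytest.approx(np.full(100, 2.1e-7))

    def test_functional_identity_at_baseline_pressure(self):
        fit = self._fit(7e-9, 2.1e-7)
        p_base = 5.0
        est = estimate_filling_afferent(fit, np.full(50, p_base), FS,
                                        t_onset=1.0, t1=2.0)
        assert est.na_est == pytest.approx(
            np.full(50, fit.m * p_base + fit.na0))
        assert est.fill_baseline_na == pytest.approx(fit.m * p_base + fit.na0)

    def test_extrapolation_tracks_true_envelope(self, small_recording):
        """Filling-phase estimate correlates strongly with the true envelope."""
        rec, truth, cfg = small_recording
        from neurocystometry import annotate_recording, reduce_recording
        avg, _ = reduce_recording(rec)
        ann = annotate_recording(avg.pressure, fs=avg.rate_hz)
        t = avg.time()
        relax = (t > ann.t2) & (t <= ann.t_baseline)
        fit = fit_na_pressure(avg.ra_nerve[relax], avg.pressure[relax])
        fill = t < ann.t1
        est = estimate_filling_afferent(fit, avg.pressure[fill], avg.rate_hz,
                                        ann.t_contraction_onset, ann.t1)
        true_env = truth.true_m * 1e-6 * avg.pressure[fill] + truth.true_na0
        r = np.corrcoef(est.na_est, true_env)[0, 1]
        assert r > 0.95


class TestFitNaVolume:
    def test_constant_estimate_gives_zero_slope(self):
        vol = np.linspace(0, 0.5, 100)
        fit = fit_na_volume(np.full(100, 2.0e-7), vol)
        assert fit.m == pytest.approx(0.0, abs=1e-18)
        assert fit.pearson_r == 0.0

    def test_affine_in_time_perfect_correlation(self):
        vol = 0.05 / 60.0 * np.arange(500) / FS
        na = 1e-7 + 3e-7 * np.arange(500) / 499
        fit = fit_na_volume(na, vol)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_degenerate_volume_rejected(self):
        with pytest.raises(FitError):
            fit_na_volume(np.linspace(0, 1, 20), np.full(20, 0.3))

    def test_compliant_bladder_correlates_better_with_pressure(self):
        """Flat-then-late-rise filling: afferent activity tracks pressure
        more linearly than volume."""
        cfg = small_cohort_config()
        rec, _ = generate_recording(small_params(), cfg, seed=77)
        s = analyze_recording(rec)
        assert abs(s.pearson_r_vol) < s.pearson_r_p


class TestSummary:
    def test_clean_recording_roundtrips_truth(self, small_recording):
        rec, truth, cfg = small_recording
        s = analyze_recording(rec)
        assert not s.excluded
        assert s.capacity_ml == pytest.approx(truth.true_capacity, rel=0.02)
        assert s.p_thres == pytest.approx(truth.true_p_thres, abs=2.0)
        assert s.tau_s == pytest.approx(truth.true_tau, rel=0.10)
        assert s.slope_raw == pytest.approx(truth.true_m, rel=0.30)
        assert s.offset_raw == pytest.approx(truth.true_na0, rel=0.20)
        for field in ("fill_baseline_na", "fill_active_na", "relax_mean_na",
                      "relax_max_na"):
            value = getattr(s, field)
            assert 0.0 <= value <= 1.05

    def test_excluded_measurement_flagged(self):
        cfg = small_cohort_config()
        rec, _ = generate_recording(small_params(), cfg, seed=13)
        rec.pressure[::7] += 60.0  # massive artifact contamination
        s = analyze_recording(rec)
        assert s.excluded
        assert "artifact" in s.exclusion_reason

    def test_noise_free_slope_offset_recovery(self):
        """Noise-free envelope: slope and offset recovered to within 1 %."""
        cfg = small_cohort_config()
        errors = []
        for seed in range(0, 40, 2):
            params = small_params(pressure_noise_sd=0.0, nvc_rate=0.0,
                                  noise_floor=0.0)
            p, truth = simulate_pressure(params, cfg, seed)
            t = np.arange(len(p)) / FS
            sel = (t > truth.true_t2) & (t <= truth.true_t_baseline)
            na = params.slope_m * 1e-6 * p + params.offset_na0
            fit = fit_na_pressure(na[sel], p[sel])
            errors.append(max(abs(fit.m - truth.true_m * 1e-6)
                              / (truth.true_m * 1e-6),
                              abs(fit.na0 - truth.true_na0) / truth.true_na0))
        assert max(errors) <= 0.01

    def test_doubling_true_slope_doubles_fitted_slope(self):
        cfg = small_cohort_config()
        fitted = []
        for factor in (1.0, 2.0):
            params = small_params(pressure_noise_sd=0.0, nvc_rate=0.0,
                                  noise_floor=0.0,
                                  slope_m=0.003 * factor)
            p, truth = simulate_pressure(params, cfg, seed=2)
            t = np.arange(len(p)) / FS
            sel = (t > truth.true_t2) & (t <= truth.true_t_baseline)
            na = params.slope_m * 1e-6 * p + params.offset_na0
            fitted.append(fit_na_pressure(na[sel], p[sel]).m)
        assert fitted[1] / fitted[0] == pytest.approx(2.0, rel=0.01)
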