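"""Maps, background subtraction, windows, masking/smoothing, transient fits."""

import numpy as np
import pytest

from trpeimg.analysis import (
    build_maps,
    feature_beta,
    fit_damped_oscillation,
    fit_decay,
    integrate_window,
    mask_and_smooth,
    normalise,
    phase_difference,
    subtract_background,
    total_signal,
    _oscillation_model,
)
from trpeimg.spectra import PES, BetaMap, TRPESMap, WindowTrace


def _pes(eps, S, b2=None):
    b2 = np.zeros_like(eps) if b2 is None else b2
    return PES(eps, S, b2, np.zeros_like(eps))


EPS = np.linspace(0.1, 2.0, 96)


class TestBuildMaps:
    def test_identical_spectra_give_identical_rows(self):
        p = _pes(EPS, np.exp(-EPS))
        tmap, bmap = build_maps([-100.0, 0.0, 100.0], [p, p, p])
        assert np.all(tmap.signal[0] == tmap.signal[1])
        assert np.all(bmap.beta2[0] == bmap.beta2[2])

    def test_single_delay_map(self):
        tmap, _ = build_maps([0.0], [_pes(EPS, np.ones_like(EPS))])
        assert tmap.signal.shape == (1, EPS.size)

    def test_unsorted_delays_rejected(self):
        p = _pes(EPS, np.ones_like(EPS))
        with pytest.raises(ValueError, match="strictly increasing"):
            build_maps([100.0, 0.0], [p, p])

    def test_grid_mismatch_names_delay(self):
        pa = _pes(EPS, np.ones_like(EPS))
        pb = _pes(EPS + 0.01, np.ones_like(EPS))
        with pytest.raises(ValueError, match="t = 50"):
            build_maps([0.0, 50.0], [pa, pb])


class TestBackgroundAndNormalise:
    def _map(self, rows, delays):
        return TRPESMap(np.asarray(delays, float), EPS, np.asarray(rows, float))

    def test_map_equal_to_own_background_vanishes(self):
        row = np.exp(-EPS)
        tmap = self._map([row, row, row], [-200, -100, 100])
        out = subtract_background(tmap)
        assert np.allclose(out.signal, 0.0)
        assert out.background_subtracted

    def test_zero_background_is_identity(self):
        row = np.exp(-EPS)
        tmap = self._map([np.zeros_like(EPS), np.zeros_like(EPS), row], [-200, -100, 100])
        out = subtract_background(tmap)
        np.testing.assert_array_equal(out.signal[2], row)

    def test_missing_negative_delays_rejected(self):
        tmap = self._map([np.ones_like(EPS)], [100])
        with pytest.raises(ValueError, match="t < 0"):
            subtract_background(tmap)

    def test_normalise_scales_global_maximum_to_one(self):
        tmap = self._map([5.0 * np.ones_like(EPS)], [0])
        out = normalise(tmap)
        assert out.signal.max() == 1.0
        again = normalise(out)
        np.testing.assert_array_equal(again.signal, out.signal)

    def test_normalise_rejects_nonpositive_map(self):
        tmap = self._map([-np.ones_like(EPS)], [0])
        with pytest.raises(ValueError, match="not positive"):
            normalise(tmap)


class TestWindows:
    def test_unit_map_window_integral_is_window_width(self):
        tmap = TRPESMap([0.0], EPS, np.ones((1, EPS.size)))
        tr = integrate_window(tmap, 1.0, 1.5)
        assert tr.values[0] == pytest.approx(0.5, abs=1e-12)

    def test_full_window_equals_row_trapezoid(self):
        sig = np.random.default_rng(0).uniform(0, 1, (3, EPS.size))
        tmap = TRPESMap([-100.0, 0.0, 100.0], EPS, sig)
        tr = integrate_window(tmap, EPS[0], EPS[-1])
        np.testing.assert_allclose(tr.values, np.trapezoid(sig, EPS, axis=1), rtol=1e-12)

    def test_windows_additive_over_shared_boundary(self):
        sig = np.random.default_rng(1).uniform(0, 1, (2, EPS.size))
        tmap = TRPESMap([0.0, 50.0], EPS, sig)
        whole = integrate_window(tmap, 0.3, 1.7)
        left = integrate_window(tmap, 0.3, 0.95)
        right = integrate_window(tmap, 0.95, 1.7)
        np.testing.assert_allclose(left.values + right.values, whole.values, rtol=1e-12)

    def test_empty_overlap_rejected(self):
        tmap = TRPESMap([0.0], EPS, np.ones((1, EPS.size)))
        with pytest.raises(ValueError, match="does not overlap"):
            integrate_window(tmap, 5.0, 6.0)

    def test_total_signal_consistency(self):
        sig = np.random.default_rng(2).uniform(-0.2, 1.0, (4, EPS.size))
        tmap = TRPESMap([-150.0, -50.0, 0.0, 100.0], EPS, sig)
        bs = subtract_background(tmap)
        tot = total_signal(bs)
        win = integrate_window(bs, EPS[0], EPS[-1])
        np.testing.assert_allclose(tot.values, win.values)
        zero = TRPESMap([-1.0, 1.0], EPS, np.zeros((2, EPS.size)),
                        background_subtracted=True)
        assert np.all(total_signal(zero).values == 0.0)


class TestMaskAndSmooth:
    def _pair(self, signal, beta):
        delays = np.arange(signal.shape[0], dtype=float)
        tmap = TRPESMap(delays, EPS, signal, normalised=True)
        bmap = BetaMap(delays, EPS, beta)
        return tmap, bmap

    def test_low_signal_fully_masked(self):
        tmap, bmap = self._pair(np.full((2, EPS.size), 0.05), np.zeros((2, EPS.size)))
        out = mask_and_smooth(bmap, tmap, threshold=0.1)
        assert not out.valid.any()
        assert np.isnan(out.beta2).all()

    def test_constant_beta_unchanged_by_smoothing(self):
        tmap, bmap = self._pair(np.ones((1, EPS.size)), np.full((1, EPS.size), -0.3))
        out = mask_and_smooth(bmap, tmap)
        np.testing.assert_allclose(out.beta2, -0.3)

    def test_alternating_beta_centre_average(self):
        beta = np.tile(np.resize([1.0, -1.0], EPS.size), (1, 1))
        tmap, bmap = self._pair(np.ones((1, EPS.size)), beta)
        out = mask_and_smooth(bmap, tmap, window=5)
        # interior point: mean of 5 alternating values = +-0.2
        assert abs(out.beta2[0, 10]) == pytest.approx(0.2, abs=1e-12)

    def test_even_window_rejected(self):
        tmap, bmap = self._pair(np.ones((1, EPS.size)), np.zeros((1, EPS.size)))
        with pytest.raises(ValueError, match="odd"):
            mask_and_smooth(bmap, tmap, window=4)

    def test_smoothing_never_crosses_mask_boundary(self):
        sig = np.ones((1, EPS.size))
        sig[0, 40:50] = 0.0  # masked gap
        beta = np.zeros((1, EPS.size))
        beta[0, 50:] = 1.0  # step exactly at the gap edge
        tmap, bmap = self._pair(sig, beta)
        out = mask_and_smooth(bmap, tmap)
        # left run sees only zeros, right run only ones
        assert np.nanmax(np.abs(out.beta2[0, :40])) == 0.0
        assert np.nanmin(out.beta2[0, 50:]) == 1.0

    def test_raising_threshold_never_unmasks(self):
        rng = np.random.default_rng(3)
        sig = rng.uniform(0, 1, (3, EPS.size))
        tmap = TRPESMap(np.arange(3.0), EPS, sig, normalised=True)
        bmap = BetaMap(np.arange(3.0), EPS, rng.uniform(-1, 2, sig.shape))
        low = mask_and_smooth(bmap, tmap, threshold=0.1)
        high = mask_and_smooth(bmap, tmap, threshold=0.3)
        assert not np.any(high.valid & ~low.valid)


class TestFeatureBeta:
    def test_constant_beta_recovered(self):
        p = _pes(EPS, np.exp(-0.5 * ((EPS - 1.4) / 0.15) ** 2), np.full_like(EPS, -0.36))
        mean, unc = feature_beta(p, 1.15, 1.65)
        assert mean == pytest.approx(-0.36, abs=1e-12)

    def test_linear_beta_under_symmetric_peak_gives_centre_value(self):
        center = 1.0
        S = np.exp(-0.5 * ((EPS - center) / 0.1) ** 2)
        beta = -0.5 + 0.4 * (EPS - center)  # linear in energy
        # symmetric window around the peak centre on a uniform grid
        p = _pes(EPS, S, beta)
        lo, hi = center - 0.5, center + 0.5
        mean, _ = feature_beta(p, lo, hi)
        assert mean == pytest.approx(-0.5, abs=1e-3)

    def test_zero_signal_window_rejected(self):
        p = _pes(EPS, np.zeros_like(EPS))
        with pytest.raises(ValueError, match="no positive-signal"):
            feature_beta(p, 1.0, 1.5)


class TestFitDampedOscillation:
    def _trace(self, t, y):
        return WindowTrace("w", 0.0, 1.0, t, y)

    def test_noiseless_model_recovers_period(self):
        t = np.linspace(-300, 1200, 40)
        truth = dict(a=1.0, tau_d=350.0, T=400.0, phi=0.3, c1=2.0, tau=1.2e5, c0=0.1)
        y = _oscillation_model(t, truth["a"], truth["tau_d"], truth["T"], truth["phi"],
                               truth["c1"], truth["tau"], truth["c0"], sigma=42.47)
        fit = fit_damped_oscillation(self._trace(t, y), irf_fwhm_fs=100.0)
        assert fit.converged
        assert fit.params["period_fs"] == pytest.approx(400.0, abs=1.0)
        assert fit.params["phase_rad"] == pytest.approx(0.3, abs=0.05)

    def test_constant_trace_has_zero_amplitude(self):
        t = np.linspace(-300, 1200, 40)
        fit = fit_damped_oscillation(self._trace(t, np.full_like(t, 2.0)), 100.0)
        assert abs(fit.params["amplitude"]) <= max(3.0 * fit.stderr("amplitude"), 1e-6)

    def test_short_trace_rejected(self):
        t = np.linspace(-100, 400, 15)
        with pytest.raises(ValueError, match="1.5 periods"):
            fit_damped_oscillation(self._trace(t, np.zeros_like(t)), 100.0)

    def test_antiphase_traces_give_pi_difference(self):
        t = np.linspace(-300, 1200, 40)
        base = _oscillation_model(t, 1.0, 400.0, 400.0, 0.0, 1.0, 1e6, 0.0, 42.47)
        anti = _oscillation_model(t, 1.0, 400.0, 400.0, np.pi, 1.0, 1e6, 0.0, 42.47)
        f1 = fit_damped_oscillation(self._trace(t, base), 100.0)
        f2 = fit_damped_oscillation(self._trace(t, anti), 100.0)
        assert phase_difference(f1, f2) == pytest.approx(np.pi, abs=0.05)


class TestFitDecay:
    def test_exact_exponential_recovered(self):
        t = np.linspace(2e3, 4e5, 30)
        y = 3.0 * np.exp(-t / 1.2e5) + 0.2
        fit = fit_decay(WindowTrace("w", 0, 1, t, y), t_min_fs=2e3)
        assert fit.converged
        assert fit.params["tau_fs"] == pytest.approx(1.2e5, abs=2e3)

    def test_constant_trace_flagged_unbounded(self):
        t = np.linspace(2e3, 4e5, 30)
        fit = fit_decay(WindowTrace("w", 0, 1, t, np.full_like(t, 1.0)), t_min_fs=2e3)
        assert fit.flags.get("unbounded_lifetime")
        assert np.isnan(fit.params["tau_fs"])

    def test_pure_noise_not_converged(self):
        rng = np.random.default_rng(0)
        t = np.linspace(2e3, 4e5, 30)
        fit = fit_decay(WindowTrace("w", 0, 1, t, rng.normal(0, 1, t.size)), t_min_fs=2e3)
        assert (not fit.converged) or fit.flags.get("unbounded_lifetime")

    def test_too_few_points_rejected(self):
        t = np.array([1e3, 3e3, 5e3])
        with pytest.raises(ValueError, match="4 points"):
            fit_decay(WindowTrace("w", 0, 1, t, np.ones(3)), t_min_fs=2e3)
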