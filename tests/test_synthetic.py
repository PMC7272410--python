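"""Wavepacket trajectory, model spectra, forward projection, counting noise."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trpeimg.config import WavepacketConfig
from trpeimg.images import Image
from trpeimg.projection import forward_project, shell_chord_avg
from trpeimg.spectra import PES
from trpeimg.synthetic import (
    expectation_pes,
    generate_dataset,
    model_pes,
    sample_counts,
    trajectory,
)


def small_cfg(**over):
    """A fast, small-image variant of the study configuration."""
    base = dict(image_size=128, k_cal_eV_per_px2=5.5e-4, n_electrons=2e5,
                n_dense=16, dense_start_fs=-300.0, dense_stop_fs=1200.0)
    base.update(over)
    return WavepacketConfig(**base)


class TestTrajectory:
    def test_starts_at_planar_minimum(self):
        cfg = WavepacketConfig()
        assert trajectory(cfg, np.array([0.0]))[0] == 0.0

    def test_reaches_single_bond_minimum_at_half_period_undamped(self):
        cfg = WavepacketConfig(coherence_fs=1e15)
        assert trajectory(cfg, np.array([200.0]))[0] == pytest.approx(1.0, abs=1e-12)

    def test_returns_to_planar_minimum_at_full_period_undamped(self):
        cfg = WavepacketConfig(coherence_fs=1e15)
        assert trajectory(cfg, np.array([400.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_undamped_motion_is_periodic(self):
        cfg = WavepacketConfig(coherence_fs=1e18, lifetime_ps=1e12)
        t = np.linspace(0, 1200, 121)
        np.testing.assert_allclose(trajectory(cfg, t), trajectory(cfg, t + cfg.period_fs),
                                   atol=1e-9)

    def test_damped_packet_settles_at_twisted_minimum(self):
        cfg = WavepacketConfig()
        q = trajectory(cfg, np.array([50e3]))
        assert q[0] == pytest.approx(1.0, abs=1e-12)

    @given(t=st.floats(-1e4, 1e5), T=st.floats(100, 1000), td=st.floats(50, 5000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_zero_before_pump(self, t, T, td):
        cfg = WavepacketConfig(period_fs=T, coherence_fs=td)
        q = float(trajectory(cfg, np.array([t]))[0])
        assert 0.0 <= q <= 1.0
        if t < 0:
            assert q == 0.0


class TestModelPES:
    def test_peak_at_planar_centre_for_q0(self):
        cfg = WavepacketConfig()
        p = model_pes(0.0, 0.0, cfg)
        high = p.x > 0.6
        assert p.x[high][np.argmax(p.S[high])] == pytest.approx(1.4, abs=0.02)

    def test_peak_at_twisted_centre_for_q1(self):
        cfg = WavepacketConfig()
        p = model_pes(1.0, 0.0, cfg)
        high = p.x > 0.6
        assert p.x[high][np.argmax(p.S[high])] == pytest.approx(0.8, abs=0.02)

    def test_beta_interpolates_linearly_at_midpoint(self):
        cfg = WavepacketConfig(beta2_pm=-0.4, beta2_sb=-0.2)
        p = model_pes(0.5, 0.0, cfg)
        i = np.argmin(np.abs(p.x - 1.1))  # midpoint peak centre
        assert p.beta2[i] == pytest.approx(-0.3, abs=1e-3)

    def test_q_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            model_pes(1.2, 0.0, WavepacketConfig())


class TestForwardProject:
    def test_zero_spectrum_gives_zero_image(self):
        eps = np.linspace(0.01, 1.0, 50)
        p = PES(eps, np.zeros_like(eps), np.zeros_like(eps), np.zeros_like(eps))
        img = forward_project(p, 128, 1e-4)
        assert img.total == 0.0

    def test_thin_isotropic_shell_projection_profile(self):
        # a delta shell at radius R projects to ~ R/sqrt(R^2 - rho^2)
        radii = np.arange(63) + 0.5
        S = np.zeros_like(radii)
        R = 40.5
        S[40] = 1.0
        p = PES(radii, S, np.zeros_like(radii), np.zeros_like(radii), domain="radius")
        img = forward_project(p, 128)
        row = img.counts[64, :]  # horizontal line through the centre
        rho = np.abs(np.arange(128) - 63.5)
        inner = (rho > 5) & (rho < R - 3)  # away from the rim singularity
        closed_form = 2.0 * R / np.sqrt(R**2 - rho[inner] ** 2)  # delta-shell Abel projection
        ratio = row[inner] / closed_form
        np.testing.assert_allclose(ratio, ratio.mean(), rtol=2e-2)
        # pixel-averaged discretisation agrees with its own closed form too
        expect = shell_chord_avg(40.0, 41.0, rho[inner])
        np.testing.assert_allclose(row[inner] / row[inner].sum(),
                                   expect / expect.sum(), rtol=1e-2)

    def test_parallel_shell_vanishes_on_equator(self):
        radii = np.arange(63) + 0.5
        S = np.zeros_like(radii)
        S[40] = 1.0
        b2 = np.zeros_like(radii)
        b2[40] = 2.0
        p = PES(radii, S, b2, np.zeros_like(radii), domain="radius")
        img = forward_project(p, 128)
        # the equatorial row passes through the cos^2-node of the emission
        equator = 0.5 * (img.counts[63, :] + img.counts[64, :])
        pole = 0.5 * (img.counts[:, 63] + img.counts[:, 64])
        assert equator.max() < 2e-2 * pole.max()

    def test_counts_conserved_on_random_spectra(self, rng):
        eps = np.linspace(5e-4, 1.1, 200)
        k = 1.6e-4
        for _ in range(50):
            S = np.zeros_like(eps)
            for _ in range(rng.integers(1, 4)):
                S += rng.uniform(0.2, 1.0) * np.exp(
                    -0.5 * ((eps - rng.uniform(0.15, 0.9)) / rng.uniform(0.04, 0.2)) ** 2)
            b2 = np.full_like(eps, rng.uniform(-1, 2))
            p = PES(eps, S, b2, np.zeros_like(eps))
            img = forward_project(p, 180, k)
            radii = np.arange((180 - 1) // 2) + 0.5
            S_r = np.interp(k * radii**2, eps, S, left=0, right=0) * 2 * k * radii
            assert img.total == pytest.approx(S_r.sum(), rel=1e-3)

    def test_expectation_nonnegative_for_physical_beta2(self):
        eps = np.linspace(0.01, 1.0, 80)
        S = np.exp(-0.5 * ((eps - 0.5) / 0.1) ** 2)
        for b2 in (-1.0, -0.3, 0.0, 1.2, 2.0):
            p = PES(eps, S, np.full_like(eps, b2), np.zeros_like(eps))
            img = forward_project(p, 128, 2.8e-4)
            assert img.counts.min() >= -1e-12

    def test_image_too_small_raises_with_required_size(self):
        eps = np.linspace(0.01, 1.5, 50)
        S = np.ones_like(eps)
        p = PES(eps, S, np.zeros_like(eps), np.zeros_like(eps))
        with pytest.raises(ValueError, match="image_size >="):
            forward_project(p, 64, 1e-4)


class TestSampleCounts:
    def test_zero_electrons_gives_zero_image(self):
        img = Image(np.ones((16, 16)))
        assert sample_counts(img, 0, 1).total == 0.0

    def test_same_seed_reproduces_identical_frame(self):
        img = Image(np.random.default_rng(0).uniform(0, 5, (32, 32)))
        a = sample_counts(img, 1e4, 42)
        b = sample_counts(img, 1e4, 42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_replicate_mean_converges_to_expectation(self, rng):
        expect = rng.uniform(0.5, 2.0, (24, 24))
        img = Image(expect)
        n = 2e5  # mean counts/pixel ~ 350
        acc = np.zeros_like(expect)
        for i in range(200):
            acc += sample_counts(img, n, i).counts
        acc /= 200
        scaled = expect * (n / expect.sum())
        sel = scaled >= 100
        np.testing.assert_allclose(acc[sel], scaled[sel], rtol=2e-2)

    def test_negative_expectation_rejected(self):
        img = Image(np.zeros((4, 4)))
        img.counts[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            sample_counts(img, 10, 0)


class TestGenerateDataset:
    def test_noiseless_dataset_with_zero_electrons(self):
        cfg = small_cfg(n_electrons=0)
        ds = generate_dataset(cfg, delays_fs=np.array([-200.0, -100.0, 0.0, 200.0]))
        assert all(img.counts.min() >= 0 for _, img in ds.frames)
        assert ds.frames[2][1].metadata["n_electrons"] == 0.0

    def test_deterministic_given_config_and_seed(self):
        cfg = small_cfg()
        delays = np.array([-200.0, -100.0, 0.0, 150.0])
        a = generate_dataset(cfg, delays_fs=delays)
        b = generate_dataset(cfg, delays_fs=delays)
        for (_, ia), (_, ib) in zip(a.frames, b.frames):
            np.testing.assert_array_equal(ia.counts, ib.counts)

    def test_requires_two_negative_delays(self):
        cfg = small_cfg()
        with pytest.raises(ValueError, match="t < 0"):
            generate_dataset(cfg, delays_fs=np.array([-100.0, 0.0, 100.0]))

    def test_window_traces_oscillate_in_antiphase(self):
        # ground truth (spectrum level): the eps1/eps2 oscillating components
        # must be out of phase by pi, i.e. perfectly anticorrelated
        cfg = small_cfg(lifetime_ps=1e9, coherence_fs=1e9, irf_fwhm_fs=0.0)
        t = np.linspace(0, 1600, 81)
        s1, s2 = [], []
        for ti in t:
            p = expectation_pes(cfg, float(ti))
            in1 = (p.x >= 1.15) & (p.x <= 1.65)
            in2 = (p.x >= 0.55) & (p.x <= 1.05)
            s1.append(np.trapezoid(p.S[in1], p.x[in1]))
            s2.append(np.trapezoid(p.S[in2], p.x[in2]))
        s1 = np.asarray(s1) - np.mean(s1)
        s2 = np.asarray(s2) - np.mean(s2)
        corr = np.dot(s1, s2) / np.sqrt(np.dot(s1, s1) * np.dot(s2, s2))
        assert corr < -0.95

    def test_undamped_trace_periodic_with_period_T(self):
        cfg = small_cfg(lifetime_ps=1e9, coherence_fs=1e9, irf_fwhm_fs=0.0)
        t = np.linspace(0, 1200, 61)
        vals = []
        for ti in t:
            p = expectation_pes(cfg, float(ti))
            in1 = (p.x >= 1.15) & (p.x <= 1.65)
            vals.append(np.trapezoid(p.S[in1], p.x[in1]))
        vals = np.asarray(vals)
        shift = int(round(cfg.period_fs / (t[1] - t[0])))
        np.testing.assert_allclose(vals[shift:], vals[:-shift], rtol=1e-5)

    def test_irf_rise_width_matches_gaussian_step_response(self):
        cfg = small_cfg()
        t = np.linspace(-250, 250, 201)
        tot = []
        for ti in t:
            p = expectation_pes(cfg, float(ti))
            bg = expectation_pes(cfg, -1e4)
            tot.append(np.trapezoid(p.S - bg.S, p.x))
        tot = np.asarray(tot)
        tot /= tot[-1]
        t10 = np.interp(0.1, tot, t)
        t90 = np.interp(0.9, tot, t)
        sigma = cfg.irf_fwhm_fs / (2 * np.sqrt(2 * np.log(2)))
        expected = 2.563 * sigma  # 10-90% width of the Gaussian step response
        assert (t90 - t10) == pytest.approx(expected, rel=0.15)
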