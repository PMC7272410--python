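"""Synthetic time-resolved photoelectron image stacks from a 1-D wavepacket.

The model: photoexcitation launches a nuclear wavepacket on the excited
state.  A single reaction coordinate q ∈ [0, 1] interpolates between the
planar minimum (q = 0, photoelectron peak at ε_PM ≈ 1.4 eV) and the
single-bond-rotated minimum (q = 1, peak at ε_SB ≈ 0.8 eV).  The wavepacket
oscillates with period T, its coherent excursion damps with time constant
τ_d as it settles at the twisted minimum, and the excited-state population
decays with lifetime τ.  The photoelectron anisotropy follows the adiabatic
electronic structure: β₂(ε) interpolates linearly in q between the two
endpoint curves.  A static low-energy channel and a delay-independent
probe-only background complete the spectrum; all time-dependent amplitudes
are convolved with a Gaussian instrument response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WavepacketConfig
from .images import Image
from .projection import forward_project
from .spectra import PES, BetaMap, TRPESMap

__all__ = [
    "trajectory",
    "population",
    "model_pes",
    "sample_counts",
    "expectation_frames",
    "generate_dataset",
    "SyntheticDataset",
]


def trajectory(cfg: WavepacketConfig, t_grid: np.ndarray) -> np.ndarray:
    """Reaction coordinate q(t) ∈ [0, 1] of the isomerising wavepacket.

    q(t) = 1 − cos²(πt/T)·exp(−t/τ_d) for t ≥ 0 and q = 0 before the pump:
    the packet starts at the planar minimum, reaches the single-bond minimum
    at T/2, swings back, and the damped oscillation settles at the twisted
    minimum.  In the undamped limit this is sin²(πt/T), exactly periodic
    with period T.
    """
    t = np.asarray(t_grid, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time grid must be finite")
    q = 1.0 - np.cos(np.pi * t / cfg.period_fs) ** 2 * np.exp(-np.clip(t, 0.0, None) / cfg.coherence_fs)
    return np.where(t < 0.0, 0.0, q)


def population(cfg: WavepacketConfig, t_grid: np.ndarray) -> np.ndarray:
    """Excited-state population exp(−t/τ) for t ≥ 0 (no instrument response)."""
    t = np.asarray(t_grid, dtype=float)
    return np.where(t < 0.0, 0.0, np.exp(-np.clip(t, 0.0, None) / (cfg.lifetime_ps * 1e3)))


def default_energy_grid(cfg: WavepacketConfig) -> np.ndarray:
    """Energy grid matching the inversion's radial shells, ε = k·(r + ½)²."""
    n_r = (cfg.image_size - 1) // 2
    radii = np.arange(n_r) + 0.5
    return cfg.k_cal_eV_per_px2 * radii**2


def _gauss(eps: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((eps - center) / sigma) ** 2)


def model_pes(q: float, t_fs: float, cfg: WavepacketConfig,
              eps_grid: np.ndarray | None = None) -> PES:
    """Instantaneous model spectrum at coordinate q and delay t (pre-IRF).

    The moving peak sits at (1−q)·ε_PM + q·ε_SB with amplitude exp(−t/τ);
    its β₂(ε) is the q-linear blend of the endpoint curves.  The static
    low-ε channel (after excitation) and the probe-only background carry
    β₂ = 0, and β₄ ≡ 0 everywhere; the stored β₂(ε) is the
    intensity-weighted blend of the components.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"reaction coordinate q={q} outside [0, 1]")
    eps = default_energy_grid(cfg) if eps_grid is None else np.asarray(eps_grid, dtype=float)
    pop = float(population(cfg, np.array([t_fs]))[0])
    step = 1.0 if t_fs >= 0 else 0.0

    center = (1.0 - q) * cfg.eps_pm_center_eV + q * cfg.eps_sb_center_eV
    s_peak = pop * _gauss(eps, center, cfg.peak_width_eV)
    s_eps3 = step * cfg.eps3_amplitude * _gauss(eps, cfg.eps3_center_eV, cfg.eps3_width_eV)
    s_bg = cfg.background_amplitude * _gauss(eps, cfg.background_center_eV, cfg.background_width_eV)

    beta_peak = (1.0 - q) * cfg.beta2_pm(eps) + q * cfg.beta2_sb(eps)
    total = s_peak + s_eps3 + s_bg
    with np.errstate(invalid="ignore", divide="ignore"):
        beta2 = np.where(total > 0, s_peak * beta_peak / np.where(total > 0, total, 1.0), 0.0)
    return PES(x=eps, S=total, beta2=beta2, beta4=np.zeros_like(eps), domain="energy")


def _irf_nodes(cfg: WavepacketConfig, n: int = 81, span: float = 5.0):
    """Quadrature nodes/weights for the Gaussian IRF convolution."""
    if cfg.irf_fwhm_fs == 0.0:
        return np.array([0.0]), np.array([1.0])
    sigma = cfg.irf_fwhm_fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    u = np.linspace(-span, span, n)
    w = np.exp(-0.5 * u * u)
    return u * sigma, w / w.sum()


def expectation_pes(cfg: WavepacketConfig, t_fs: float,
                    eps_grid: np.ndarray | None = None) -> PES:
    """IRF-convolved expectation spectrum at one pump–probe delay.

    The convolution acts on the time axis of the instantaneous model (and so
    on the population rise/decay and the coherent peak motion); the
    delay-independent background is unaffected.
    """
    eps = default_energy_grid(cfg) if eps_grid is None else np.asarray(eps_grid, dtype=float)
    offsets, weights = _irf_nodes(cfg)
    S = np.zeros_like(eps)
    Sb = np.zeros_like(eps)
    for dt, w in zip(offsets, weights):
        tp = t_fs - dt
        qp = float(trajectory(cfg, np.array([tp]))[0])
        p = model_pes(qp, tp, cfg, eps)
        S += w * p.S
        Sb += w * p.S * p.beta2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta2 = np.where(S > 0, Sb / np.where(S > 0, S, 1.0), 0.0)
    return PES(x=eps, S=S, beta2=beta2, beta4=np.zeros_like(eps), domain="energy")


def sample_counts(image: Image, n_electrons: float, seed) -> Image:
    """Poisson-sample an expectation image scaled to ``n_electrons`` total.

    The same seed reproduces the identical frame bit-for-bit.
    """
    if np.any(image.counts < 0):
        raise ValueError("expectation image has negative pixels")
    if n_electrons < 0:
        raise ValueError("n_electrons must be non-negative")
    total = image.total
    if n_electrons == 0 or total == 0:
        counts = np.zeros_like(image.counts)
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(image.counts * (n_electrons / total)).astype(float)
    meta = dict(image.metadata, n_electrons=float(n_electrons))
    return Image(counts, center=image.center, metadata=meta)


@dataclass
class SyntheticDataset:
    """Per-delay images plus the generator's ground truth for assertions."""

    frames: list  # list of (delay_fs, Image)
    config: WavepacketConfig
    truth: dict = field(default_factory=dict)

    @property
    def delays_fs(self) -> np.ndarray:
        return np.array([d for d, _ in self.frames])


def expectation_frames(cfg: WavepacketConfig, delays_fs: np.ndarray) -> list[tuple[float, Image]]:
    """Noiseless expectation images for each delay (common arbitrary scale)."""
    frames = []
    for t in delays_fs:
        pes = expectation_pes(cfg, float(t))
        img = forward_project(pes, cfg.image_size, cfg.k_cal_eV_per_px2)
        img.metadata["delay_fs"] = float(t)
        frames.append((float(t), img))
    return frames


def generate_dataset(cfg: WavepacketConfig,
                     delays_fs: np.ndarray | None = None,
                     include_sparse: bool = False,
                     seed: int | None = None,
                     expectation: list[tuple[float, Image]] | None = None) -> SyntheticDataset:
    """Generate a full synthetic image stack with ground-truth tables.

    All frames share one intensity scale — the frame with the largest
    expectation total carries ``cfg.n_electrons`` electrons on average — so
    the population decay survives the counting statistics.  Passing a
    precomputed ``expectation`` (from :func:`expectation_frames`) avoids
    recomputing the noiseless stack when only the noise seed changes.

    With ``cfg.n_electrons == 0`` the expectation images are returned
    unsampled (noiseless dataset).
    """
    if delays_fs is None:
        delays_fs = cfg.delays_fs(include_sparse=include_sparse)
    delays_fs = np.asarray(delays_fs, dtype=float)
    if np.any(np.diff(delays_fs) <= 0):
        raise ValueError("delays must be strictly increasing")
    if np.count_nonzero(delays_fs < 0) < 2:
        raise ValueError("delay list must include at least 2 frames with t < 0")
    seed = cfg.seed if seed is None else int(seed)

    if expectation is None:
        expectation = expectation_frames(cfg, delays_fs)
    elif not np.allclose([d for d, _ in expectation], delays_fs):
        raise ValueError("precomputed expectation frames do not match the delay list")

    totals = np.array([img.total for _, img in expectation])
    scale = cfg.n_electrons / totals.max() if cfg.n_electrons > 0 and totals.max() > 0 else 0.0

    frames = []
    for i, (t, img) in enumerate(expectation):
        if scale == 0.0:
            out = Image(img.counts.copy(), center=img.center,
                        metadata=dict(img.metadata, seed=seed, n_electrons=0.0))
        else:
            rng = np.random.default_rng([seed, i])
            counts = rng.poisson(img.counts * scale).astype(float)
            out = Image(counts, center=img.center,
                        metadata=dict(img.metadata, seed=seed,
                                      n_electrons=float(counts.sum())))
        frames.append((t, out))

    truth = _ground_truth(cfg, delays_fs, expectation, scale)
    return SyntheticDataset(frames=frames, config=cfg, truth=truth)


def _ground_truth(cfg, delays_fs, expectation, scale) -> dict:
    eps = default_energy_grid(cfg)
    offsets, weights = _irf_nodes(cfg)
    q_inst = trajectory(cfg, delays_fs)
    q_irf = np.array([
        float(np.sum(weights * trajectory(cfg, t - offsets))) for t in delays_fs
    ])
    pop_irf = np.array([
        float(np.sum(weights * population(cfg, t - offsets))) for t in delays_fs
    ])
    spectra = [expectation_pes(cfg, float(t)) for t in delays_fs]
    sig = np.vstack([p.S for p in spectra])
    beta = np.vstack([p.beta2 for p in spectra])
    table = pd.DataFrame({
        "delay_fs": delays_fs,
        "q_instantaneous": q_inst,
        "q_irf": q_irf,
        "population_irf": pop_irf,
        "peak_center_eV": (1.0 - q_irf) * cfg.eps_pm_center_eV + q_irf * cfg.eps_sb_center_eV,
    })
    return {
        "table": table,
        "expectation_map": TRPESMap(delays_fs, eps, sig),
        "beta_map": BetaMap(delays_fs, eps, beta),
        "scale": scale,
    }
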