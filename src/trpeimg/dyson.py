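"""Plane-wave photodetachment cross-sections and anisotropies from Dyson orbitals.

The outgoing electron is treated as a plane wave (no interaction with the
neutral core), the dipole operator is taken in the length gauge, and the
molecular ensemble is isotropic.  Because the transition amplitude is linear
in the polarisation ê,

    M(k, ê) = ê · A(k),   A(k) = ∫ e^(−i k·r) · r · Ψ_D(r) d³r,

the laboratory-frame PAD after orientation averaging reduces exactly to

    I(θ) ∝ c_par·cos²θ + c_perp·sin²θ,
    c_par = ⟨|k̂·A|²⟩,   c_perp = (⟨|A|²⟩ − ⟨|k̂·A|²⟩)/2,

with ⟨·⟩ an average over emission directions k̂ in the molecular frame (the
azimuthal average of ê about k̂ is analytic).  Hence β₂ = 2(c_par − c_perp) /
(c_par + 2c_perp) and the expansion truncates exactly at P₂ for one-photon
detachment.  A(k) is evaluated in closed form from the Gaussian Fourier
transform; an explicit SO(3) numerical averaging route is provided as an
independent cross-check.

Atomic units throughout: ε = k²/2, and σ(ε) includes the density-of-states
factor k (β₂ is unaffected by it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EV_TO_HARTREE
from .orbitals import DysonOrbital, rotate_orbital

__all__ = [
    "PADResult",
    "matrix_element",
    "dipole_vector_amplitude",
    "beta_sigma_at",
    "beta_curve",
    "window_average_beta",
    "lab_frame_pad_so3",
]


# ---------------------------------------------------------------------------
# Gaussian Fourier integrals
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=256)
def _moment_poly(l: int, alpha: float) -> tuple[complex, ...]:
    """Coefficients of the polynomial p_l(k) with J_l = p_l(k)·J_0(k).

    Obtained from J_{l+1} = i·dJ_l/dk, which gives the recursion
    p_{l+1} = i·(p_l' − k·p_l/(2α)).
    """
    coeffs = np.array([1.0 + 0.0j])
    for _ in range(l):
        deriv = np.arange(1, coeffs.size, dtype=complex) * coeffs[1:]
        shifted = np.concatenate([[0.0j], coeffs]) / (2.0 * alpha)
        size = max(deriv.size, shifted.size)
        new = np.zeros(size, dtype=complex)
        new[:deriv.size] += deriv
        new[:shifted.size] -= shifted
        coeffs = 1j * new
    return tuple(coeffs)


def _J(l: int, k: np.ndarray, alpha: float) -> np.ndarray:
    """1-D moment integral ∫ u^l e^(−αu²) e^(−iku) du in closed form."""
    k = np.asarray(k, dtype=float)
    J0 = np.sqrt(np.pi / alpha) * np.exp(-k * k / (4.0 * alpha))
    poly = _moment_poly(l, float(alpha))
    val = np.zeros_like(k, dtype=complex)
    for m in range(len(poly) - 1, -1, -1):
        val = val * k + poly[m]
    return val * J0


def dipole_vector_amplitude(orbital: DysonOrbital, k_vectors: np.ndarray) -> np.ndarray:
    """Vector amplitude A(k) = ∫ e^(−ik·r) r Ψ_D(r) d³r for a batch of k.

    ``k_vectors`` has shape (n, 3) in atomic units; returns complex (n, 3).
    """
    kv = np.atleast_2d(np.asarray(k_vectors, dtype=float))
    A = np.zeros((kv.shape[0], 3), dtype=complex)
    for p in orbital.primitives:
        C = np.asarray(p.center)
        phase = np.exp(-1j * kv @ C)
        Jl = [_J(p.powers[ax], kv[:, ax], p.alpha) for ax in range(3)]
        Jl1 = [_J(p.powers[ax] + 1, kv[:, ax], p.alpha) for ax in range(3)]
        base = Jl[0] * Jl[1] * Jl[2]
        # component ax: replace the ax factor by the (l+1) moment
        comp = [
            Jl1[0] * Jl[1] * Jl[2],
            Jl[0] * Jl1[1] * Jl[2],
            Jl[0] * Jl[1] * Jl1[2],
        ]
        for ax in range(3):
            A[:, ax] += p.coeff * phase * (C[ax] * base + comp[ax])
    return A


def matrix_element(orbital: DysonOrbital, k_vector, polarisation) -> complex:
    """Plane-wave dipole amplitude M = ⟨e^(ik·r)| ê·r |Ψ_D⟩ (length gauge).

    ``k_vector`` and ``polarisation`` are given in the molecular frame; the
    polarisation must be a unit vector.
    """
    e = np.asarray(polarisation, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-8:
        raise ValueError("polarisation must be a unit vector")
    A = dipole_vector_amplitude(orbital, np.asarray(k_vector, dtype=float)[None, :])[0]
    return complex(e @ A)


# ---------------------------------------------------------------------------
# orientation averaging
# ---------------------------------------------------------------------------

def _khat_grid(n_polar: int, n_azim: int) -> tuple[np.ndarray, np.ndarray]:
    """Product quadrature over the sphere: Gauss–Legendre × uniform azimuth."""
    x, wx = np.polynomial.legendre.leggauss(n_polar)
    phi = (np.arange(n_azim) + 0.5) * (2.0 * np.pi / n_azim)
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    khat = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1).reshape(-1, 3)
    w = np.repeat(wx, n_azim) / (2.0 * n_azim)  # normalised to Σw = 1
    return khat, w


def _averaged_moments(orbital: DysonOrbital, k_mag: float,
                      n_polar: int, n_azim: int) -> tuple[float, float]:
    khat, w = _khat_grid(n_polar, n_azim)
    A = dipole_vector_amplitude(orbital, k_mag * khat)
    A_par = np.einsum("ni,ni->n", khat, A)
    m_par = float(np.sum(w * np.abs(A_par) ** 2))
    m_tot = float(np.sum(w * np.einsum("ni,ni->n", A.conj(), A).real))
    return m_par, m_tot


def beta_sigma_at(orbital: DysonOrbital, eps_eV: float,
                  tol: float = 1.0e-3) -> tuple[float, float]:
    """(σ, β₂) at one electron kinetic energy, orientation-averaged.

    The k̂ quadrature is refined until σ and β₂ change by less than ``tol``
    between successive orders; persistent non-convergence raises.
    """
    if eps_eV <= 0:
        raise ValueError("electron kinetic energy must be positive")
    k = np.sqrt(2.0 * eps_eV * EV_TO_HARTREE)
    prev = None
    for n_polar, n_azim in ((16, 16), (24, 32), (36, 48), (48, 64)):
        m_par, m_tot = _averaged_moments(orbital, k, n_polar, n_azim)
        c_par = m_par
        c_perp = 0.5 * (m_tot - m_par)
        denom = c_par + 2.0 * c_perp
        sigma = k * (4.0 * np.pi / 3.0) * denom
        beta2 = 2.0 * (c_par - c_perp) / denom if denom > 0 else np.nan
        if prev is not None:
            d_sigma = abs(sigma - prev[0]) / max(abs(prev[0]), 1e-300)
            d_beta = abs(beta2 - prev[1]) if np.isfinite(beta2) else 0.0
            if d_sigma <= tol and d_beta <= tol:
                return sigma, beta2
        prev = (sigma, beta2)
    raise RuntimeError(
        "orientation-average quadrature did not converge; the orbital needs a "
        "denser angular grid than the built-in refinement ladder")


@dataclass
class PADResult:
    """β₂(ε) and σ(ε) curves computed from one Dyson orbital."""

    eps_eV: np.ndarray
    sigma: np.ndarray
    beta2: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eps_eV = np.asarray(self.eps_eV, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if np.any(np.diff(self.eps_eV) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("cross-section must be non-negative")

    @property
    def k_au(self) -> np.ndarray:
        return np.sqrt(2.0 * self.eps_eV * EV_TO_HARTREE)


def beta_curve(orbital: DysonOrbital, eps_grid_eV) -> PADResult:
    """Map :func:`beta_sigma_at` over an energy grid (any input order)."""
    eps = np.sort(np.asarray(eps_grid_eV, dtype=float))
    if np.any(eps <= 0):
        raise ValueError("energy grid must be positive")
    out = [beta_sigma_at(orbital, float(e)) for e in eps]
    sigma = np.array([o[0] for o in out])
    beta2 = np.array([o[1] for o in out])
    return PADResult(eps, sigma, beta2,
                     metadata={"orbital": orbital.label, "model": "plane-wave dipole"})


def window_average_beta(pad: PADResult, eps_lo: float, eps_hi: float,
                        weighting: str = "uniform") -> float:
    """Windowed mean of the computed β₂(ε), comparable to `feature_beta`."""
    sel = (pad.eps_eV >= eps_lo) & (pad.eps_eV <= eps_hi)
    if not np.any(sel):
        raise ValueError(f"window [{eps_lo}, {eps_hi}] eV contains no grid points")
    if weighting == "uniform":
        return float(pad.beta2[sel].mean())
    if weighting == "sigma-weighted":
        w = pad.sigma[sel]
        if w.sum() <= 0:
            raise ValueError("zero total cross-section weight in window")
        return float(np.sum(w * pad.beta2[sel]) / w.sum())
    raise ValueError("weighting must be 'uniform' or 'sigma-weighted'")


# ---------------------------------------------------------------------------
# independent SO(3) averaging route (cross-check)
# ---------------------------------------------------------------------------

def lab_frame_pad_so3(orbital: DysonOrbital, eps_eV: float, thetas: np.ndarray,
                      n_alpha: int = 12, n_beta: int = 12, n_gamma: int = 12) -> np.ndarray:
    """Lab-frame I(θ) by explicit numerical averaging over molecular orientations.

    For each Euler rotation the molecular-frame matrix element is evaluated
    at the rotated lab emission direction and polarisation; this route never
    uses the analytic azimuthal contraction and serves as its oracle.
    """
    k = np.sqrt(2.0 * eps_eV * EV_TO_HARTREE)
    alphas = (np.arange(n_alpha) + 0.5) * 2 * np.pi / n_alpha
    xb, wb = np.polynomial.legendre.leggauss(n_beta)
    betas = np.arccos(xb)
    gammas = (np.arange(n_gamma) + 0.5) * 2 * np.pi / n_gamma
    e_lab = np.array([0.0, 0.0, 1.0])
    k_lab = np.stack([np.sin(thetas), np.zeros_like(thetas), np.cos(thetas)], axis=-1)

    intensity = np.zeros_like(thetas, dtype=float)
    wtot = 0.0
    for a in alphas:
        Ra = _rot_z(a)
        for b, wb_i in zip(betas, wb):
            Rb = _rot_y(b)
            for g in gammas:
                R = Ra @ Rb @ _rot_z(g)
                kv = k * (k_lab @ R.T)          # lab directions in molecular frame
                e_mol = R @ e_lab
                A = dipole_vector_amplitude(orbital, kv)
                M = A @ e_mol
                intensity += wb_i * np.abs(M) ** 2
                wtot += wb_i
    return intensity / wtot


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(b: float) -> np.ndarray:
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
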