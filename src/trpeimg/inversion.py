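"""Polar onion peeling: recover spectrum and anisotropies from a VMI image.

The velocity-map image is resampled onto a polar grid (exploiting the
four-fold reflection symmetry of one-colour-polarised distributions by
quadrant averaging), then shells are peeled from the outermost radius
inward: the residual intensity on each ring is fitted to the Legendre
decomposition I(θ) = σ/4π [1 + β₂P₂(cosθ) + β₄P₄(cosθ)] of that ring's own
shell, and the fitted shell's forward projection is subtracted from all
interior radii.  The shell-projection basis is shared with
:mod:`trpeimg.projection`, which makes the peel the exact inverse of the
forward model up to discretisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Image
from .projection import legendre_p2, legendre_p4, shell_chord_avg, shell_volume
from .spectra import PES

__all__ = ["LegendreFit", "legendre_fit", "to_polar", "pop_invert", "CalibrationModel", "calibrate"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Legendre decomposition of an angular distribution
# ---------------------------------------------------------------------------

@dataclass
class LegendreFit:
    """Weighted least-squares coefficients of the PAD Legendre expansion."""

    sigma: float          # 4π × monopole coefficient
    beta2: float
    beta4: float
    coeffs: np.ndarray    # raw (c0, c2[, c4]) coefficients
    covariance: np.ndarray
    flagged: bool = False  # True when the input carried no intensity


def _legendre_design(cos_theta: np.ndarray, orders) -> np.ndarray:
    cols = []
    for n in orders:
        if n == 0:
            cols.append(np.ones_like(cos_theta))
        elif n == 2:
            cols.append(legendre_p2(cos_theta))
        elif n == 4:
            cols.append(legendre_p4(cos_theta))
        else:
            raise ValueError(f"unsupported Legendre order {n}")
    return np.column_stack(cols)


def legendre_fit(theta: np.ndarray, intensity: np.ndarray,
                 weights: np.ndarray | None = None,
                 orders=(0, 2, 4)) -> LegendreFit:
    """Fit I(θ) = c₀ + c₂P₂(cosθ) + c₄P₄(cosθ) by weighted least squares.

    Returns σ = 4π·c₀ and the anisotropy ratios β₂ = c₂/c₀, β₄ = c₄/c₀.  An
    all-zero input yields σ = 0 with undefined (NaN) β, flagged rather than
    raised.
    """
    theta = np.asarray(theta, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if theta.size < 5 or np.unique(theta).size < 5:
        raise ValueError("need at least 5 distinct theta samples")
    if weights is None:
        weights = np.ones_like(theta)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
    X = _legendre_design(np.cos(theta), orders)
    w = np.sqrt(weights)
    coeffs, res, rank, _ = np.linalg.lstsq(X * w[:, None], intensity * w, rcond=None)
    dof = max(theta.size - len(coeffs), 1)
    rss = float(res[0]) if res.size else float(np.sum((intensity - X @ coeffs) ** 2 * weights))
    xtx = (X * weights[:, None]).T @ X
    cov = np.linalg.pinv(xtx) * rss / dof
    c = dict(zip(orders, coeffs))
    c0 = c.get(0, 0.0)
    if c0 == 0.0 and np.allclose(intensity, 0.0):
        return LegendreFit(0.0, np.nan, np.nan, coeffs, cov, flagged=True)
    beta2 = c.get(2, 0.0) / c0 if c0 != 0 else np.nan
    beta4 = c.get(4, 0.0) / c0 if c0 != 0 else np.nan
    return LegendreFit(4.0 * np.pi * c0, beta2, beta4, coeffs, cov, flagged=False)


# ---------------------------------------------------------------------------
# polar resampling
# ---------------------------------------------------------------------------

def to_polar(image: Image, n_r: int | None = None, n_theta: int = 128) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample an image onto a quadrant-averaged polar grid.

    θ is measured from the polarisation (vertical) axis and spans (0, π/2)
    after averaging the four reflection-equivalent quadrants; bilinear
    interpolation is used.  Returns ``(polar, radii, thetas)`` where
    ``polar[i, j]`` is the per-pixel intensity at radius ``radii[i]`` and
    angle ``thetas[j]``.
    """
    if n_theta < 8:
        raise ValueError("n_theta must be at least 8")
    ny, nx = image.shape
    cx, cy = image.center
    r_max = min(cx, nx - 1 - cx, cy, ny - 1 - cy)
    n_r_max = int(np.floor(r_max - 0.5))
    if n_r is None:
        n_r = n_r_max
    elif n_r > n_r_max:
        logger.warning("requested %d radial bins but only %d fit inside the image; clipping", n_r, n_r_max)
        n_r = n_r_max
    if n_r < 8:
        raise ValueError("radial range too small (need at least 8 bins)")
    radii = np.arange(n_r) + 0.5
    thetas = (np.arange(n_theta) + 0.5) * (np.pi / 2.0) / n_theta
    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    dz = rr * np.cos(tt)  # along polarisation axis (vertical)
    dx = rr * np.sin(tt)
    polar = np.zeros((n_r, n_theta))
    for sz in (+1.0, -1.0):
        for sx in (+1.0, -1.0):
            coords = np.stack([cy - sz * dz, cx + sx * dx])  # (row, col)
            polar += ndimage.map_coordinates(image.counts, coords, order=1, mode="nearest")
    return polar / 4.0, radii, thetas


# ---------------------------------------------------------------------------
# onion peeling
# ---------------------------------------------------------------------------

def pop_invert(image: Image, n_theta: int = 128, freeze_beta4: bool = False,
               n_r: int | None = None) -> PES:
    """Invert a velocity-map image by polar onion peeling.

    Returns a radius-domain PES: S(r) is the total electron count in the
    1-pixel shell at radius r, with β₂(r), β₄(r) and per-ring fit
    diagnostics.  Negative fitted shell amplitudes are clipped to zero (the
    clip fraction is recorded in ``diagnostics``).
    """
    if not np.all(np.isfinite(image.counts)):
        raise ValueError("image contains non-finite pixels")
    polar, radii, thetas = to_polar(image, n_r=n_r, n_theta=n_theta)
    n_r = radii.size
    cos_t = np.cos(thetas)
    orders = (0, 2) if freeze_beta4 else (0, 2, 4)

    S = np.zeros(n_r)
    b2 = np.full(n_r, np.nan)
    b4 = np.full(n_r, np.nan)
    S_err = np.zeros(n_r)
    b2_err = np.full(n_r, np.nan)
    n_clipped = 0
    n_neg_warn = 0
    noise_floor = max(np.abs(polar).max() * 1e-12, 1e-300)

    residual = polar.copy()
    for s in range(n_r - 1, -1, -1):
        R = radii[s]
        s_lo, s_hi = R - 0.5, R + 0.5
        V = shell_volume(s_lo, s_hi)
        a_self = shell_chord_avg(s_lo, s_hi, np.array([R]))[0] / V
        # design matrix for this ring: own-shell projection at ρ = R
        X = _legendre_design(cos_t, orders) * a_self
        y = residual[s]
        coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coeffs) ** 2))
        dof = max(y.size - len(coeffs), 1)
        cov = np.linalg.pinv(X.T @ X) * rss / dof

        c0 = coeffs[0]
        if c0 <= 0.0:
            if c0 < -10.0 * np.sqrt(max(cov[0, 0], 0.0)) and abs(c0) > noise_floor:
                n_neg_warn += 1
            n_clipped += 1
            continue
        c2 = coeffs[1]
        c4 = coeffs[2] if not freeze_beta4 else 0.0
        S[s] = c0
        b2[s] = c2 / c0
        b4[s] = c4 / c0
        S_err[s] = np.sqrt(max(cov[0, 0], 0.0))
        # delta method for the ratio beta2 = c2/c0
        v0, v2, c02 = cov[0, 0], cov[1, 1], cov[0, 1]
        b2_err[s] = np.sqrt(max(v2 + b2[s] ** 2 * v0 - 2.0 * b2[s] * c02, 0.0)) / c0

        if s > 0:
            rho_in = radii[:s]
            chord = shell_chord_avg(s_lo, s_hi, rho_in) / V
            u = np.clip(rho_in[:, None] * cos_t[None, :] / R, -1.0, 1.0)
            shell_proj = chord[:, None] * (
                c0 + c2 * legendre_p2(u) + c4 * legendre_p4(u))
            residual[:s] -= shell_proj

    return PES(
        x=radii, S=S, beta2=b2, beta4=b4, domain="radius",
        S_err=S_err, beta2_err=b2_err,
        diagnostics={
            "clip_fraction": n_clipped / n_r,
            "negative_residual_warnings": n_neg_warn,
            "n_theta": n_theta,
        },
    )


# ---------------------------------------------------------------------------
# energy calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Quadratic radius→energy calibration ε = k_cal·r² (eV, pixels)."""

    k_cal_eV_per_px2: float

    def __post_init__(self) -> None:
        if self.k_cal_eV_per_px2 <= 0:
            raise ValueError("k_cal must be positive")

    @classmethod
    def from_reference(cls, eps_ref_eV: float, r_ref_px: float) -> "CalibrationModel":
        """Calibrate from a reference peak of known energy observed at r_ref."""
        return cls(eps_ref_eV / r_ref_px**2)


def calibrate(pes: PES, cal: CalibrationModel) -> PES:
    """Convert a radius-domain PES to the energy domain.

    Applies ε = k·r² and the Jacobian S(ε) = S(r)/(2kr); β curves are
    re-indexed unchanged.  An r = 0 bin (if present) is dropped.
    """
    if pes.domain != "radius":
        raise ValueError("calibrate expects a radius-domain PES")
    k = cal.k_cal_eV_per_px2
    keep = pes.x > 0
    r = pes.x[keep]
    jac = 1.0 / (2.0 * k * r)
    return PES(
        x=k * r**2,
        S=pes.S[keep] * jac,
        beta2=pes.beta2[keep],
        beta4=pes.beta4[keep],
        domain="energy",
        S_err=None if pes.S_err is None else pes.S_err[keep] * jac,
        beta2_err=None if pes.beta2_err is None else pes.beta2_err[keep],
        diagnostics=dict(pes.diagnostics, k_cal_eV_per_px2=k),
    )
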