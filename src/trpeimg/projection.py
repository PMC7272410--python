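"""Forward Abel projection of cylindrically symmetric electron distributions.

The 3-D velocity distribution is modelled as a stack of 1-pixel-wide radial
shells.  A shell spanning radii [s_lo, s_hi] with uniform radial density and
angular distribution 1 + β₂P₂(cosθ) + β₄P₄(cosθ) (θ from the polarisation
axis, the vertical image axis) projects along the line of sight onto the
detector plane as

    chord(ρ) · [1 + β₂P₂(z/R) + β₄P₄(z/R)] / V,

where ρ is the in-plane radius, z the in-plane coordinate along the
polarisation axis, chord(ρ) the line-of-sight path length through the shell,
and V = 4π/3 (s_hi³ − s_lo³) the shell volume.  Both the projector here and
the polar onion-peeling inversion use the same discretised shell basis, so
the two operations are mutually consistent by construction.

Pixels are assigned the radial average of the chord over the pixel width
(analytic antiderivative), which integrates the rim singularity exactly, and
each shell is renormalised so that its summed pixel counts equal its spectral
weight: the projection conserves total counts by construction.
"""

from __future__ import annotations

import numpy as np

from .images import Image
from .spectra import PES

__all__ = ["forward_project", "shell_chord_avg", "shell_volume", "legendre_p2", "legendre_p4"]


def legendre_p2(u: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * u * u - 1.0)


def legendre_p4(u: np.ndarray) -> np.ndarray:
    u2 = u * u
    return 0.125 * (35.0 * u2 * u2 - 30.0 * u2 + 3.0)


def _chord_antiderivative(rho: np.ndarray, s: float) -> np.ndarray:
    """Antiderivative in ρ of chord 2√(s²−ρ²), continued constant for ρ ≥ s."""
    r = np.minimum(np.asarray(rho, dtype=float), s)
    if s <= 0.0:
        return np.zeros_like(r)
    return r * np.sqrt(np.maximum(s * s - r * r, 0.0)) + s * s * np.arcsin(np.clip(r / s, -1.0, 1.0))


def shell_chord_avg(s_lo: float, s_hi: float, rho: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Pixel-averaged line-of-sight chord through the shell [s_lo, s_hi].

    Averages the chord over a radial interval of ``width`` centred on ρ, which
    regularises the inverse-square-root rim of the projection.
    """
    rho = np.asarray(rho, dtype=float)
    lo = np.maximum(rho - width / 2.0, 0.0)
    hi = rho + width / 2.0
    out = (
        _chord_antiderivative(hi, s_hi)
        - _chord_antiderivative(lo, s_hi)
        - _chord_antiderivative(hi, s_lo)
        + _chord_antiderivative(lo, s_lo)
    )
    return out / width


def shell_volume(s_lo: float, s_hi: float) -> float:
    return 4.0 * np.pi / 3.0 * (s_hi**3 - s_lo**3)


def _pes_on_shells(pes: PES, radii: np.ndarray, k_cal: float):
    """Resample a PES onto 1-px radial shells; returns (S_per_shell, β₂, β₄).

    For an energy-domain PES the Jacobian ε = k·r² ⇒ dε = 2kr·dr converts
    spectral density to counts per unit radius.
    """
    if pes.domain == "energy":
        eps = k_cal * radii**2
        S = np.interp(eps, pes.x, pes.S, left=0.0, right=0.0) * 2.0 * k_cal * radii
        b2 = np.interp(eps, pes.x, pes.beta2)
        b4 = np.interp(eps, pes.x, pes.beta4)
    else:
        S = np.interp(radii, pes.x, pes.S, left=0.0, right=0.0)
        b2 = np.interp(radii, pes.x, pes.beta2)
        b4 = np.interp(radii, pes.x, pes.beta4)
    b2 = np.where(S > 0, np.nan_to_num(b2), 0.0)
    b4 = np.where(S > 0, np.nan_to_num(b4), 0.0)
    return S, b2, b4


def forward_project(pes: PES, image_size: int, k_cal: float | None = None) -> Image:
    """Project a spectrum + anisotropy onto a 2-D expectation image.

    The image is centred on the pixel grid; the polarisation axis is
    vertical.  Total counts equal the shell-resampled spectral weight
    Σ S(r)Δr by construction.

    Raises
    ------
    ValueError
        If the image is too small to contain the largest populated radius.
    """
    if pes.domain == "energy" and k_cal is None:
        raise ValueError("k_cal is required to project an energy-domain PES")
    n = int(image_size)
    n_r = (n - 1) // 2  # largest whole shell that fits inside the grid
    radii = np.arange(n_r) + 0.5
    S, b2, b4 = _pes_on_shells(pes, radii, k_cal if k_cal is not None else 1.0)

    # does the populated part of the spectrum fit?
    populated = np.nonzero(pes.S > 1e-9 * max(pes.S.max(), 1e-300))[0]
    if populated.size:
        x_max = pes.x[populated[-1]]
        r_needed = np.sqrt(x_max / k_cal) if pes.domain == "energy" else x_max
        if r_needed > n_r:
            raise ValueError(
                f"image of size {n} holds radii up to {n_r} px but the spectrum "
                f"extends to {r_needed:.1f} px; need image_size >= {2 * int(np.ceil(r_needed)) + 2}"
            )

    half = n // 2
    if n % 2 == 0:
        # quadrant offsets 0.5 … n/2-0.5; full image is the mirrored quadrant
        off = np.arange(half) + 0.5
        z = off[:, None]            # vertical (polarisation) offset
        x = off[None, :]
        quad = _accumulate(z, x, radii, S, b2, b4, fraction=0.25)
        top = np.hstack([quad[:, ::-1], quad])
        img = np.vstack([top[::-1, :], top])
    else:
        off = np.arange(n) - (n - 1) / 2.0
        z = off[:, None]
        x = off[None, :]
        img = _accumulate(z, x, radii, S, b2, b4, fraction=1.0)
    return Image(img, metadata={"k_cal_eV_per_px2": k_cal} if k_cal is not None else {})


def _accumulate(z, x, radii, S, b2, b4, fraction: float) -> np.ndarray:
    """Sum shell projections on the given grid; ``fraction`` is the share of
    each shell's counts the grid covers (0.25 for one quadrant)."""
    rho = np.sqrt(z * z + x * x)
    out = np.zeros(np.broadcast_shapes(z.shape, x.shape), dtype=float)
    zb = np.broadcast_to(z, out.shape)
    for i, R in enumerate(radii):
        if S[i] <= 0.0:
            continue
        s_lo, s_hi = R - 0.5, R + 0.5
        mask = rho < s_hi + 0.5
        chord = shell_chord_avg(s_lo, s_hi, rho[mask])
        u = np.clip(zb[mask] / R, -1.0, 1.0)
        vals = chord * (1.0 + b2[i] * legendre_p2(u) + b4[i] * legendre_p4(u))
        tot = vals.sum()
        if tot > 0.0:
            vals *= (S[i] * fraction) / tot
        out[mask] += vals
    return out
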