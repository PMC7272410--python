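"""Time/energy/angle-resolved analysis of per-delay photoelectron spectra.

Builds delay × energy signal and β₂ maps, subtracts the pre-time-zero
background, integrates spectral windows, masks and smooths the anisotropy
map, and fits the transient dynamics: an IRF-convolved damped cosine for the
coherent wavepacket oscillation and a single exponential for the
excited-state population decay.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

from .spectra import PES, BetaMap, FitResult, TRPESMap, WindowTrace

__all__ = [
    "build_maps",
    "subtract_background",
    "normalise",
    "integrate_window",
    "mask_and_smooth",
    "feature_beta",
    "total_signal",
    "fit_damped_oscillation",
    "fit_decay",
    "phase_difference",
]


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

def build_maps(delays_fs, pes_list: list[PES]) -> tuple[TRPESMap, BetaMap]:
    """Stack energy-domain spectra into (TRPESMap, BetaMap); no mask yet."""
    delays_fs = np.asarray(delays_fs, dtype=float)
    if len(pes_list) != delays_fs.size:
        raise ValueError("one PES required per delay")
    bad = np.nonzero(np.diff(delays_fs) <= 0)[0]
    if bad.size:
        raise ValueError(f"delays not strictly increasing at t = {delays_fs[bad[0] + 1]} fs")
    ref = pes_list[0]
    for t, p in zip(delays_fs, pes_list):
        if p.domain != "energy":
            raise ValueError(f"PES at t = {t} fs is not energy-calibrated")
        if p.x.shape != ref.x.shape or not np.allclose(p.x, ref.x):
            raise ValueError(f"energy grid mismatch at delay t = {t} fs")
    sig = np.vstack([p.S for p in pes_list])
    beta = np.vstack([p.beta2 for p in pes_list])
    err = None
    if all(p.S_err is not None for p in pes_list):
        err = np.vstack([p.S_err for p in pes_list])
    return (
        TRPESMap(delays_fs, ref.x.copy(), sig, signal_err=err),
        BetaMap(delays_fs, ref.x.copy(), beta, valid=np.ones_like(beta, dtype=bool)),
    )


def subtract_background(tmap: TRPESMap) -> TRPESMap:
    """Subtract the mean of all t < 0 rows, leaving only time-evolving signal.

    Negative values are retained (rendered white in the usual false-colour
    display).
    """
    neg = tmap.delays_fs < 0
    if not np.any(neg):
        raise ValueError("no t < 0 frame available for background subtraction")
    background = tmap.signal[neg].mean(axis=0)
    out = tmap.copy()
    out.signal = tmap.signal - background[None, :]
    out.background_subtracted = True
    return out


def normalise(tmap: TRPESMap) -> TRPESMap:
    """Divide by the global maximum (which must be positive)."""
    peak = tmap.signal.max()
    if peak <= 0:
        raise ValueError("map maximum is not positive; cannot normalise")
    out = tmap.copy()
    out.signal = tmap.signal / peak
    if out.signal_err is not None:
        out.signal_err = out.signal_err / peak
    out.normalised = True
    return out


# ---------------------------------------------------------------------------
# spectral windows
# ---------------------------------------------------------------------------

def _window_grid(eps: np.ndarray, lo: float, hi: float):
    """Augment the grid with interpolated points at the window edges."""
    if not lo < hi:
        raise ValueError("window bounds must satisfy lo < hi")
    lo_eff = max(lo, eps[0])
    hi_eff = min(hi, eps[-1])
    if lo_eff >= hi_eff:
        raise ValueError(f"window [{lo}, {hi}] eV does not overlap the energy grid")
    inner = eps[(eps > lo_eff) & (eps < hi_eff)]
    return np.concatenate([[lo_eff], inner, [hi_eff]])


def integrate_window(tmap: TRPESMap, eps_lo: float, eps_hi: float,
                     label: str = "") -> WindowTrace:
    """Trapezoidal integral of the signal over [eps_lo, eps_hi] per delay.

    Window edges falling between grid points are handled by linear
    interpolation, which makes the integral exactly additive over windows
    that share a boundary.
    """
    grid = _window_grid(tmap.energies_eV, eps_lo, eps_hi)
    rows = np.vstack([
        np.interp(grid, tmap.energies_eV, row) for row in tmap.signal
    ])
    vals = np.trapezoid(rows, grid, axis=1)
    errors = None
    if tmap.signal_err is not None:
        # trapezoid weights on the augmented grid
        w = np.zeros_like(grid)
        d = np.diff(grid)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        err_rows = np.vstack([
            np.interp(grid, tmap.energies_eV, row) for row in tmap.signal_err
        ])
        errors = np.sqrt(np.sum((w[None, :] * err_rows) ** 2, axis=1))
    return WindowTrace(label or f"[{eps_lo}, {eps_hi}] eV", eps_lo, eps_hi,
                       tmap.delays_fs.copy(), vals, errors)


def total_signal(tmap: TRPESMap) -> WindowTrace:
    """Full-grid integral per delay (requires a background-subtracted map)."""
    if not tmap.background_subtracted:
        raise ValueError("total_signal expects a background-subtracted map")
    eps = tmap.energies_eV
    trace = integrate_window(tmap, eps[0], eps[-1], label="total")
    return trace


def mask_and_smooth(bmap: BetaMap, tmap: TRPESMap, threshold: float = 0.1,
                    window: int = 5) -> BetaMap:
    """Mask β₂ where the normalised signal is below ``threshold`` and apply a
    centred moving average along ε inside each unmasked run.

    The averaging window shrinks at run edges and never crosses a mask
    boundary.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd (centred average)")
    if not tmap.normalised:
        raise ValueError("mask_and_smooth expects a normalised signal map")
    if bmap.beta2.shape != tmap.signal.shape:
        raise ValueError("beta map and signal map shapes differ")
    half = window // 2
    valid = (tmap.signal >= threshold) & np.isfinite(bmap.beta2)
    beta = np.full_like(bmap.beta2, np.nan)
    n_rows, n_cols = valid.shape
    for i in range(n_rows):
        j = 0
        while j < n_cols:
            if not valid[i, j]:
                j += 1
                continue
            k = j
            while k < n_cols and valid[i, k]:
                k += 1
            run = bmap.beta2[i, j:k]
            sm = np.empty_like(run)
            for m in range(run.size):
                a = max(0, m - half)
                b = min(run.size, m + half + 1)
                sm[m] = run[a:b].mean()
            beta[i, j:k] = sm
            j = k
    return BetaMap(bmap.delays_fs.copy(), bmap.energies_eV.copy(), beta, valid=valid)


def feature_beta(pes: PES, eps_lo: float, eps_hi: float) -> tuple[float, float]:
    """Signal-weighted mean β₂ over a spectral feature, with uncertainty.

    The uncertainty combines (in quadrature) the propagated per-point fit
    errors and the weighted dispersion of β₂ across the window.
    """
    sel = (pes.x >= eps_lo) & (pes.x <= eps_hi) & (pes.S > 0) & np.isfinite(pes.beta2)
    if not np.any(sel):
        raise ValueError(f"no positive-signal points in window [{eps_lo}, {eps_hi}] eV")
    w = pes.S[sel]
    b = pes.beta2[sel]
    wsum = w.sum()
    mean = float(np.sum(w * b) / wsum)
    disp = float(np.sqrt(np.sum(w**2 * (b - mean) ** 2)) / wsum)
    fit = 0.0
    if pes.beta2_err is not None:
        s = pes.beta2_err[sel]
        s = np.where(np.isfinite(s), s, 0.0)
        fit = float(np.sqrt(np.sum((w * s) ** 2)) / wsum)
    return mean, float(np.hypot(disp, fit))


# ---------------------------------------------------------------------------
# transient fitting
# ---------------------------------------------------------------------------

def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _conv_exp_step(t: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    """Analytic Θ(t)·e^(−t/τ) ⊗ Gaussian(σ)."""
    if sigma == 0.0:
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    arg = (sigma / tau - t / sigma) / np.sqrt(2.0)
    # guard the exponent against overflow for t << 0
    expo = np.clip(sigma**2 / (2 * tau**2) - t / tau, -700.0, 700.0)
    return 0.5 * np.exp(expo) * special.erfc(arg)


def _conv_step(t: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return (t >= 0).astype(float)
    return 0.5 * special.erfc(-t / (np.sqrt(2.0) * sigma))


_COS_NODES = 81


def _conv_damped_cos(t: np.ndarray, a: float, tau_d: float, T: float, phi: float,
                     sigma: float) -> np.ndarray:
    """Numerical Θ(t)·a·e^(−t/τ_d)·cos(2πt/T − φ) ⊗ Gaussian(σ)."""
    if sigma == 0.0:
        tp = np.clip(t, 0, None)
        return np.where(t >= 0, a * np.exp(-tp / tau_d) * np.cos(2 * np.pi * tp / T - phi), 0.0)
    u = np.linspace(-5.0, 5.0, _COS_NODES)
    w = np.exp(-0.5 * u * u)
    w /= w.sum()
    tp = t[:, None] - sigma * u[None, :]
    f = np.where(tp >= 0,
                 a * np.exp(-np.clip(tp, 0, None) / tau_d) * np.cos(2 * np.pi * tp / T - phi),
                 0.0)
    return f @ w


def _oscillation_model(t, a, tau_d, T, phi, c1, tau, c0, sigma):
    return (
        _conv_damped_cos(t, a, tau_d, T, phi, sigma)
        + c1 * _conv_exp_step(t, tau, sigma)
        + c0 * _conv_step(t, sigma)
    )


def fit_damped_oscillation(trace: WindowTrace, irf_fwhm_fs: float,
                           period_guess_fs: float = 400.0) -> FitResult:
    """Fit an IRF-convolved damped cosine plus population decay to a trace.

    Model: s(t) = [a·e^(−t/τ_d)·cos(2πt/T − φ) + c₁·e^(−t/τ) + c₀]·Θ(t)
    convolved with a Gaussian of the given FWHM.  Eight period starts are
    tried and the best residual wins; the returned amplitude is normalised
    to a ≥ 0 with the phase wrapped into (−π, π].
    """
    t = trace.delays_fs
    y = trace.values
    if t.size < 12:
        raise ValueError("need at least 12 points to fit the oscillation")
    span = t.max() - max(t.min(), 0.0)
    if span < 1.5 * period_guess_fs:
        raise ValueError("trace must span at least 1.5 periods of the initial guess")
    sigma = _fwhm_to_sigma(irf_fwhm_fs)
    w = None
    if trace.errors is not None and np.all(trace.errors > 0):
        w = 1.0 / trace.errors

    scale = max(np.ptp(y), abs(y).max(), 1e-12)
    off0 = float(np.median(y[t > 0.7 * t.max()])) if np.any(t > 0.7 * t.max()) else float(y[-1])
    amp0 = float(y[t >= 0][0] - off0) if np.any(t >= 0) else scale

    def residuals(p):
        a, tau_d, T, phi, c1, tau, c0 = p
        r = _oscillation_model(t, a, tau_d, T, phi, c1, tau, c0, sigma) - y
        return r * w if w is not None else r

    lower = [-np.inf, 10.0, period_guess_fs / 8.0, -2 * np.pi, -np.inf, 100.0, -np.inf]
    upper = [np.inf, 1e7, period_guess_fs * 8.0, 2 * np.pi, np.inf, 1e9, np.inf]
    best = None
    for T0 in period_guess_fs * np.geomspace(0.5, 2.0, 8):
        p0 = [0.5 * scale, T0, T0, 0.0, amp0, max(10 * t.max(), 1e5), off0]
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lower, upper))
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return FitResult("damped_oscillation", {}, {}, np.nan, converged=False,
                         flags={"no_start_converged": True})

    p = best.x.copy()
    if p[0] < 0:  # canonical form: positive amplitude
        p[0] = -p[0]
        p[3] += np.pi
    p[3] = np.arctan2(np.sin(p[3]), np.cos(p[3]))  # wrap phase to (-pi, pi]

    names = ["amplitude", "tau_d_fs", "period_fs", "phase_rad", "c1", "tau_fs", "offset"]
    errs = _lsq_uncertainties(best, t.size)
    return FitResult(
        "damped_oscillation",
        dict(zip(names, map(float, p))),
        dict(zip(names, errs)),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=True,
        flags={"irf_fwhm_fs": irf_fwhm_fs},
    )


def _lsq_uncertainties(sol, n_points: int) -> list[float]:
    J = sol.jac
    dof = max(n_points - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        return [float(np.sqrt(max(v, 0.0))) for v in np.diag(cov)]
    except np.linalg.LinAlgError:
        return [float("nan")] * J.shape[1]


def fit_decay(trace: WindowTrace, t_min_fs: float) -> FitResult:
    """Single-exponential-plus-offset fit of the long-delay population decay.

    Points before ``t_min_fs`` (chosen after the coherence has damped) are
    excluded.  A trace with no resolvable decay is flagged
    ``unbounded_lifetime`` instead of reporting a meaningless number.
    """
    sel = trace.delays_fs >= t_min_fs
    if np.count_nonzero(sel) < 4:
        raise ValueError("need at least 4 points after t_min for the decay fit")
    t = trace.delays_fs[sel]
    y = trace.values[sel]
    w = None
    if trace.errors is not None and np.all(trace.errors[sel] > 0):
        w = 1.0 / trace.errors[sel]

    scale = max(abs(y).max(), 1e-300)
    span = t.max() - t.min()

    def residuals(p):
        a, tau, c = p
        r = a * np.exp(-(t - t[0]) / tau) + c - y
        return r * w if w is not None else r

    p0 = [y[0] - y[-1], span / 2.0, y[-1]]
    sol = optimize.least_squares(
        residuals, p0, bounds=([-np.inf, span * 1e-4, -np.inf], [np.inf, span * 1e4, np.inf]))
    a, tau, c = sol.x
    errs = _lsq_uncertainties(sol, t.size)
    a_err, tau_err, c_err = errs
    flags = {}
    converged = bool(sol.success)

    if abs(a) <= 2.0 * a_err or tau >= span * 1e3:
        # no decaying component resolvable: lifetime unbounded, not a number
        flags["unbounded_lifetime"] = True
        params = {"amplitude": float(a), "tau_fs": float("nan"), "offset": float(c)}
        uncs = {"amplitude": a_err, "tau_fs": float("nan"), "offset": c_err}
        return FitResult("exp_decay", params, uncs,
                         float(np.sqrt(2 * sol.cost)), converged, flags)
    if not np.isfinite(tau_err) or tau_err >= tau:
        converged = False
    # amplitude is referenced to the first fitted point (t = t_min)
    params = {"amplitude": float(a), "tau_fs": float(tau), "offset": float(c)}
    uncs = {"amplitude": a_err, "tau_fs": tau_err, "offset": c_err}
    return FitResult("exp_decay", params, uncs, float(np.sqrt(2 * sol.cost)), converged, flags)


def phase_difference(fit_a: FitResult, fit_b: FitResult) -> float:
    """Absolute oscillation phase difference mapped into [0, π]."""
    d = fit_b.params["phase_rad"] - fit_a.params["phase_rad"]
    d = np.mod(d, 2.0 * np.pi)
    return float(min(d, 2.0 * np.pi - d))
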