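"""In-memory containers for spectra, maps, traces and fit results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PES", "TRPESMap", "BetaMap", "WindowTrace", "FitResult"]


def _strictly_increasing(x: np.ndarray) -> bool:
    return bool(np.all(np.diff(x) > 0))


@dataclass
class PES:
    """A photoelectron spectrum with angular anisotropy curves.

    The abscissa is either pixel radius (``domain='radius'``) or electron
    kinetic energy in eV (``domain='energy'``).  The angular distribution at
    each abscissa point is I(θ) ∝ 1 + β₂P₂(cosθ) + β₄P₄(cosθ), θ measured
    from the laser polarisation axis.
    """

    x: np.ndarray
    S: np.ndarray
    beta2: np.ndarray
    beta4: np.ndarray
    domain: str = "energy"  # "radius" (pixels) or "energy" (eV)
    S_err: np.ndarray | None = None
    beta2_err: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.beta4 = np.asarray(self.beta4, dtype=float)
        if self.domain not in ("radius", "energy"):
            raise ValueError(f"unknown PES domain {self.domain!r}")
        n = self.x.size
        for name in ("S", "beta2", "beta4"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"PES field {name} does not match abscissa length {n}")
        if not _strictly_increasing(self.x):
            raise ValueError("PES abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("PES intensities must be finite")

    def to_frame(self) -> pd.DataFrame:
        col = "eps_eV" if self.domain == "energy" else "r_px"
        data = {col: self.x, "S": self.S, "beta2": self.beta2, "beta4": self.beta4}
        if self.S_err is not None:
            data["S_err"] = self.S_err
        if self.beta2_err is not None:
            data["beta2_err"] = self.beta2_err
        return pd.DataFrame(data)


@dataclass
class TRPESMap:
    """Signal on a (delay × energy) grid."""

    delays_fs: np.ndarray
    energies_eV: np.ndarray
    signal: np.ndarray  # shape (n_delays, n_energies)
    background_subtracted: bool = False
    normalised: bool = False
    signal_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays_fs = np.asarray(self.delays_fs, dtype=float)
        self.energies_eV = np.asarray(self.energies_eV, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.delays_fs.size, self.energies_eV.size):
            raise ValueError("signal matrix shape must be (n_delays, n_energies)")
        if not _strictly_increasing(self.delays_fs):
            raise ValueError("delays must be strictly increasing")
        if not _strictly_increasing(self.energies_eV):
            raise ValueError("energy grid must be strictly increasing")

    def copy(self) -> "TRPESMap":
        return TRPESMap(
            self.delays_fs.copy(),
            self.energies_eV.copy(),
            self.signal.copy(),
            self.background_subtracted,
            self.normalised,
            None if self.signal_err is None else self.signal_err.copy(),
        )


@dataclass
class BetaMap:
    """β₂ on a (delay × energy) grid with a validity mask.

    ``valid`` is True where the (normalised) signal is large enough for the
    anisotropy to be meaningful; masked entries are NaN in ``beta2``.
    """

    delays_fs: np.ndarray
    energies_eV: np.ndarray
    beta2: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays_fs = np.asarray(self.delays_fs, dtype=float)
        self.energies_eV = np.asarray(self.energies_eV, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        shape = (self.delays_fs.size, self.energies_eV.size)
        if self.beta2.shape != shape:
            raise ValueError("beta2 matrix shape must be (n_delays, n_energies)")
        if self.valid is None:
            self.valid = np.isfinite(self.beta2)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != shape:
                raise ValueError("validity mask shape must match beta2")


@dataclass
class WindowTrace:
    """Spectrally integrated signal versus pump–probe delay."""

    label: str
    eps_lo: float
    eps_hi: float
    delays_fs: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays_fs = np.asarray(self.delays_fs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.delays_fs.shape:
            raise ValueError("trace length must equal delay count")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {"delay_fs": self.delays_fs, "signal": self.values}
        if self.errors is not None:
            data["signal_err"] = self.errors
        return pd.DataFrame(data)


@dataclass
class FitResult:
    """Parameters of a transient fit with 1-σ uncertainties."""

    model: str
    params: dict[str, float]
    uncertainties: dict[str, float]
    residual_norm: float
    converged: bool
    flags: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def stderr(self, key: str) -> float:
        return self.uncertainties.get(key, float("nan"))
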