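"""Energetic limits and feature assignment for pump–probe photodetachment.

Given pump/probe photon energies, the vertical detachment energy and
per-geometry S₁–D₀ gaps, these routines predict the maximum electron
kinetic energy available when the probe detaches the excited anion at each
critical geometry, the expected signal range once the vibrational energy
budget is accounted for, and score measured spectral features against
candidate geometries on energetic compatibility plus anisotropy agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import EnergeticsConfig

__all__ = [
    "EnergeticsModel",
    "EpsilonLimit",
    "GeometryWindow",
    "MeasuredFeature",
    "CandidateGeometry",
    "AssignmentReport",
    "epsilon_max_fc",
    "epsilon_range_geom",
    "assign",
]

# the energetics table doubles as the model object
EnergeticsModel = EnergeticsConfig


class EpsilonLimit(NamedTuple):
    """A maximum electron kinetic energy with a channel-open flag."""

    eps_eV: float
    channel_open: bool


def epsilon_max_fc(model: EnergeticsModel) -> EpsilonLimit:
    """Two-photon detachment limit at the Franck–Condon geometry.

    ε_FC = hv_pump + hv_probe − VDE.  A non-positive result is flagged as
    "no two-photon detachment window" rather than raised.
    """
    eps = model.hv_pump_eV + model.hv_probe_eV - model.vde_eV
    return EpsilonLimit(float(eps), eps > 0.0)


@dataclass(frozen=True)
class GeometryWindow:
    """Predicted photoelectron signal range for one candidate geometry."""

    label: str
    eps_lo_eV: float
    eps_hi_eV: float
    channel_open: bool


def epsilon_range_geom(model: EnergeticsModel, label: str) -> GeometryWindow:
    """Expected signal range for probe detachment at a given geometry.

    The upper limit is ε_hi = hv_probe − gap(label), with gap the vertical
    D₀−S₁ energy there.  The maximum shifts down by the vibrational energy
    available above the local S₁ minimum, E_vib = hv_pump − [E_S1(label) −
    E_S0(FC)], giving ε_lo = max(ε_hi − E_vib, 0).  gap ≥ hv_probe means
    the probe cannot reach D₀ (channel closed).
    """
    try:
        entry = model.geometries[label]
    except KeyError as exc:
        raise KeyError(f"no energetics entry for geometry {label!r}") from exc
    gap = float(entry["gap_eV"])
    e_s1 = float(entry["e_s1_eV"])
    eps_hi = model.hv_probe_eV - gap
    if eps_hi <= 0.0:
        return GeometryWindow(label, 0.0, float(eps_hi), channel_open=False)
    e_vib = max(model.hv_pump_eV - e_s1, 0.0)
    eps_lo = max(eps_hi - e_vib, 0.0)
    return GeometryWindow(label, float(eps_lo), float(eps_hi), channel_open=True)


@dataclass(frozen=True)
class MeasuredFeature:
    """A measured photoelectron feature: centre ± width plus its anisotropy."""

    label: str
    center_eV: float
    width_eV: float
    beta2: float
    beta2_err: float = 0.0


@dataclass(frozen=True)
class CandidateGeometry:
    """A candidate geometry with its predicted range and model anisotropy."""

    label: str
    window: GeometryWindow
    model_beta2: float
    model_beta2_err: float = 0.0


@dataclass
class AssignmentReport:
    """All feature–candidate scores plus the deterministic ranking."""

    pairs: pd.DataFrame
    ranking: dict[str, list[str]]
    notes: list[str] = field(default_factory=list)

    def best(self, feature_label: str) -> str | None:
        ranked = self.ranking.get(feature_label, [])
        return ranked[0] if ranked else None


def assign(features: list[MeasuredFeature], candidates: list[CandidateGeometry],
           model: EnergeticsModel) -> AssignmentReport:
    """Score every feature against every candidate geometry.

    A feature is energetically compatible with a candidate iff its centre
    lies within the candidate's predicted range widened by the
    electronic-structure uncertainty margin δ (``model.compat_margin_eV``)
    and the detachment channel is open.  Ranking per feature is
    lexicographic: compatibility first, then anisotropy deviation
    |β₂_meas − β₂_model| / combined uncertainty; ties keep the candidate
    input order.
    """
    if not features or not candidates:
        raise ValueError("assign needs at least one feature and one candidate")
    delta = model.compat_margin_eV
    rows = []
    notes = []
    for feat in features:
        for order, cand in enumerate(candidates):
            win = cand.window
            compatible = bool(
                win.channel_open
                and (win.eps_lo_eV - delta) <= feat.center_eV <= (win.eps_hi_eV + delta)
            )
            unc = float(np.hypot(feat.beta2_err, cand.model_beta2_err))
            dev = abs(feat.beta2 - cand.model_beta2)
            beta_dev = dev / unc if unc > 0 else dev
            rows.append({
                "feature": feat.label,
                "candidate": cand.label,
                "feature_center_eV": feat.center_eV,
                "eps_lo_eV": win.eps_lo_eV,
                "eps_hi_eV": win.eps_hi_eV,
                "channel_open": win.channel_open,
                "compatible": compatible,
                "beta2_measured": feat.beta2,
                "beta2_model": cand.model_beta2,
                "beta2_deviation": beta_dev,
                "candidate_order": order,
            })
    pairs = pd.DataFrame(rows)
    ranking: dict[str, list[str]] = {}
    for feat in features:
        sub = pairs[pairs["feature"] == feat.label].copy()
        sub = sub.sort_values(
            by=["compatible", "beta2_deviation", "candidate_order"],
            ascending=[False, True, True],
            kind="stable",
        )
        ranking[feat.label] = sub["candidate"].tolist()
        tied = sub[sub.duplicated(subset=["compatible", "beta2_deviation"], keep=False)]
        if not tied.empty:
            notes.append(
                f"feature {feat.label!r}: tie between {sorted(set(tied['candidate']))} "
                "broken by candidate order")
    return AssignmentReport(pairs=pairs, ranking=ranking, notes=notes)
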