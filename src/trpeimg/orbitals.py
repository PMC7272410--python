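"""Dyson orbitals as Cartesian-Gaussian expansions.

The one-electron wavefunction of the detached electron is represented as a sum
of primitives ``c · (x−Cx)^lx (y−Cy)^ly (z−Cz)^lz · exp(−α |r−C|²)`` with
centres and exponents in atomic units (bohr, bohr⁻²).  Two on-disk dialects
are supported: a restricted Molden subset (Cartesian s/p/d shells, one MO
selected by index) and a plain JSON list of primitives.

Overlaps are evaluated with the standard Gaussian-product/binomial closed
form, so orbital norms are analytic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR

__all__ = [
    "GaussianPrimitive",
    "DysonOrbital",
    "OrbitalFormatError",
    "read_orbital",
    "write_orbital_json",
    "overlap",
    "rotate_orbital",
]


class OrbitalFormatError(ValueError):
    """Raised for malformed or unsupported orbital files."""


@dataclass(frozen=True)
class GaussianPrimitive:
    """One Cartesian Gaussian primitive, all quantities in atomic units."""

    center: tuple[float, float, float]  # bohr
    powers: tuple[int, int, int]        # (lx, ly, lz), each >= 0
    alpha: float                        # bohr^-2, > 0
    coeff: float                        # real expansion coefficient

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise OrbitalFormatError(f"Gaussian exponent must be positive, got {self.alpha}")
        if any((p < 0 or int(p) != p) for p in self.powers):
            raise OrbitalFormatError(f"angular exponents must be non-negative integers: {self.powers}")


def _double_factorial(n: int) -> int:
    # (-1)!! == 1 by convention
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _overlap_1d(l1: int, l2: int, pa: float, pb: float, gamma: float) -> float:
    """1-D overlap factor of x^l1 (about A) and x^l2 (about B) Gaussians."""
    s = 0.0
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if (i + j) % 2:
                continue
            s += (
                math.comb(l1, i)
                * math.comb(l2, j)
                * pa ** (l1 - i)
                * pb ** (l2 - j)
                * _double_factorial(i + j - 1)
                / (2.0 * gamma) ** ((i + j) // 2)
            )
    return s * math.sqrt(math.pi / gamma)


def overlap(p: GaussianPrimitive, q: GaussianPrimitive) -> float:
    """Analytic overlap integral ⟨p|q⟩ including both coefficients."""
    a, b = p.alpha, q.alpha
    gamma = a + b
    A = np.asarray(p.center)
    B = np.asarray(q.center)
    P = (a * A + b * B) / gamma
    ab2 = float(np.dot(A - B, A - B))
    pref = math.exp(-a * b / gamma * ab2)
    val = pref
    for ax in range(3):
        val *= _overlap_1d(p.powers[ax], q.powers[ax], P[ax] - A[ax], P[ax] - B[ax], gamma)
    return p.coeff * q.coeff * val


@dataclass
class DysonOrbital:
    """A Dyson orbital Ψ_D as a list of Cartesian Gaussian primitives."""

    primitives: list[GaussianPrimitive]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.primitives:
            raise OrbitalFormatError("orbital must contain at least one primitive")

    @property
    def norm(self) -> float:
        """‖Ψ_D‖ from the analytic primitive overlap matrix."""
        n2 = 0.0
        for p in self.primitives:
            for q in self.primitives:
                n2 += overlap(p, q)
        if not math.isfinite(n2) or n2 <= 0:
            raise OrbitalFormatError("orbital norm is not finite and positive")
        return math.sqrt(n2)

    def scaled(self, factor: float) -> "DysonOrbital":
        return DysonOrbital(
            [GaussianPrimitive(p.center, p.powers, p.alpha, p.coeff * factor) for p in self.primitives],
            label=self.label,
        )


def _expand_linear_power(vectors: list[np.ndarray]) -> dict[tuple[int, int, int], float]:
    """Expand Π_i (v_i · u) into monomials u_x^a u_y^b u_z^c."""
    poly = {(0, 0, 0): 1.0}
    for v in vectors:
        new: dict[tuple[int, int, int], float] = {}
        for (a, b, c), coef in poly.items():
            for ax, inc in enumerate(((1, 0, 0), (0, 1, 0), (0, 0, 1))):
                if v[ax] == 0.0:
                    continue
                key = (a + inc[0], b + inc[1], c + inc[2])
                new[key] = new.get(key, 0.0) + coef * v[ax]
        poly = new
    return poly


def rotate_orbital(orbital: DysonOrbital, rotation: np.ndarray) -> DysonOrbital:
    """Rigidly rotate an orbital: ψ'(r) = ψ(Rᵀ r) with R a proper rotation.

    Centres move to R·C and each Cartesian monomial is re-expanded in the
    rotated frame; the expansion is exact for any angular momentum.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ValueError("rotation must be a proper 3x3 rotation matrix")
    prims: list[GaussianPrimitive] = []
    for p in orbital.primitives:
        newc = tuple(R @ np.asarray(p.center))
        vectors = []
        for ax in range(3):
            vectors.extend([R[:, ax]] * p.powers[ax])
        poly = _expand_linear_power(vectors) if vectors else {(0, 0, 0): 1.0}
        for powers, coef in poly.items():
            if coef == 0.0:
                continue
            prims.append(GaussianPrimitive(newc, powers, p.alpha, p.coeff * coef))
    return DysonOrbital(prims, label=orbital.label)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_orbital(path, dialect: str = "json", mo_index: int = 0) -> DysonOrbital:
    """Read a Dyson orbital.

    Parameters
    ----------
    dialect : {"json", "molden_subset"}
        ``json`` is a documented plain list of primitives in atomic units.
        ``molden_subset`` accepts Cartesian s/p/d GTOs only and selects one MO
        from the ``[MO]`` section by ``mo_index`` (0-based).
    """
    if dialect == "json":
        return _read_orbital_json(path)
    if dialect == "molden_subset":
        return _read_orbital_molden(path, mo_index)
    raise OrbitalFormatError(f"unknown orbital dialect {dialect!r}; use 'json' or 'molden_subset'")


def _read_orbital_json(path) -> DysonOrbital:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    prims_doc = doc.get("primitives", [])
    if not prims_doc:
        raise OrbitalFormatError(f"{path}: orbital file contains zero primitives")
    prims = [
        GaussianPrimitive(
            center=tuple(float(v) for v in entry["center"]),
            powers=tuple(int(v) for v in entry["powers"]),
            alpha=float(entry["alpha"]),
            coeff=float(entry["coeff"]),
        )
        for entry in prims_doc
    ]
    return DysonOrbital(prims, label=str(doc.get("label", "")))


def write_orbital_json(orbital: DysonOrbital, path) -> None:
    doc = {
        "label": orbital.label,
        "units": "atomic (bohr, bohr^-2)",
        "primitives": [
            {
                "center": list(p.center),
                "powers": list(p.powers),
                "alpha": p.alpha,
                "coeff": p.coeff,
            }
            for p in orbital.primitives
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_CART_COMPONENTS = {
    "s": [(0, 0, 0)],
    "p": [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    # Molden Cartesian d ordering
    "d": [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}


def _primitive_norm(alpha: float, powers: tuple[int, int, int]) -> float:
    l, m, n = powers
    L = l + m + n
    num = (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = math.sqrt(
        _double_factorial(2 * l - 1) * _double_factorial(2 * m - 1) * _double_factorial(2 * n - 1)
    )
    return num / den


def _read_orbital_molden(path, mo_index: int) -> DysonOrbital:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip() for ln in fh]

    def find_section(name: str) -> int:
        for i, ln in enumerate(lines):
            s = ln.strip().lower()
            if s.startswith("[") and "]" in s and s[1:s.index("]")].strip() == name.lower():
                return i
        raise OrbitalFormatError(f"{path}: missing [{name}] section")

    i_atoms = find_section("atoms")
    i_gto = find_section("gto")
    i_mo = find_section("mo")

    header = lines[i_atoms].strip().lower()
    if "au" in header.split("]")[-1]:
        to_bohr = 1.0
    else:
        to_bohr = ANGSTROM_TO_BOHR

    centers: dict[int, np.ndarray] = {}
    for ln in lines[i_atoms + 1:]:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("["):
            break
        parts = s.split()
        # element, index, atomic number, x, y, z
        centers[int(parts[1])] = np.array([float(v) for v in parts[3:6]]) * to_bohr

    # [GTO]: blocks "atom_index 0" then shells "type nprim 1.00" + prim lines
    shells: list[tuple[int, str, list[tuple[float, float]]]] = []
    i = i_gto + 1
    while i < len(lines):
        s = lines[i].strip()
        if s.startswith("["):
            break
        if not s:
            i += 1
            continue
        atom_idx = int(s.split()[0])
        i += 1
        while i < len(lines) and lines[i].strip() and not lines[i].strip().startswith("["):
            parts = lines[i].split()
            shell_type = parts[0].lower()
            if shell_type not in _CART_COMPONENTS:
                raise OrbitalFormatError(
                    f"{path}: unsupported shell type {shell_type!r} (subset allows s, p, d)"
                )
            nprim = int(parts[1])
            prims = []
            for k in range(nprim):
                i += 1
                a, c = (float(v.replace("D", "E").replace("d", "e")) for v in lines[i].split()[:2])
                prims.append((a, c))
            shells.append((atom_idx, shell_type, prims))
            i += 1
    basis: list[tuple[int, str, list[tuple[float, float]], tuple[int, int, int]]] = []
    for atom_idx, shell_type, prims in shells:
        for powers in _CART_COMPONENTS[shell_type]:
            basis.append((atom_idx, shell_type, prims, powers))

    # [MO]: select the mo_index-th MO block
    mo_blocks: list[dict[int, float]] = []
    current: dict[int, float] | None = None
    for ln in lines[i_mo + 1:]:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("["):
            break
        low = s.lower()
        if low.startswith(("sym", "ene", "spin", "occup")):
            if low.startswith("sym"):
                current = {}
                mo_blocks.append(current)
            continue
        parts = s.split()
        if current is None:  # file without Sym= headers: single implicit MO
            current = {}
            mo_blocks.append(current)
        current[int(parts[0])] = float(parts[1])
    if not mo_blocks:
        raise OrbitalFormatError(f"{path}: [MO] section contains no orbitals")
    if mo_index >= len(mo_blocks):
        raise OrbitalFormatError(
            f"{path}: MO index {mo_index} out of range ({len(mo_blocks)} orbitals present)"
        )
    coeffs = mo_blocks[mo_index]

    primitives: list[GaussianPrimitive] = []
    for ibf, (atom_idx, _shell, prims, powers) in enumerate(basis, start=1):
        mo_c = coeffs.get(ibf, 0.0)
        if mo_c == 0.0:
            continue
        center = tuple(centers[atom_idx])
        for alpha, c in prims:
            primitives.append(
                GaussianPrimitive(center, powers, alpha, mo_c * c * _primitive_norm(alpha, powers))
            )
    if not primitives:
        raise OrbitalFormatError(f"{path}: selected MO has all-zero coefficients")
    return DysonOrbital(primitives, label=f"molden:{path}#mo{mo_index}")
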