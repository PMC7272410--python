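"""Linear interpolation in internal coordinates (LIIC) between geometries.

Geometries are converted to Z-matrix internal coordinates (bonds, angles,
dihedrals over a user-supplied connectivity), each coordinate is
interpolated affinely in the path parameter λ, and Cartesian frames are
rebuilt.  No reoptimisation is performed along the path: an LIIC pathway is
the straight line between two critical points in internal-coordinate space,
not a minimum-energy path.

Dihedrals interpolate along the shorter angular arc with ±180° wrapping; an
explicit rotation direction can be forced for arcs near the 180° ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import Geometry, GeometryError, dihedral

__all__ = ["ZMatrix", "to_internals", "from_internals", "liic_path", "LIICPath"]


Connectivity = list[tuple[int, ...]]
"""Per-atom reference tuples: atom 0 → (), atom 1 → (j,), atom 2 → (j, k),
atom i ≥ 3 → (j, k, l): bond to j, angle i–j–k, dihedral i–j–k–l.  Each
reference must point to an earlier atom."""


@dataclass
class ZMatrix:
    """Internal-coordinate set over a Z-matrix style connectivity.

    ``bonds`` are Å, ``angles`` and ``dihedrals`` degrees; entry i describes
    atom i (entries for atoms without that coordinate type are NaN).
    """

    elements: list[str]
    connectivity: Connectivity
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if len(self.connectivity) != n:
            raise GeometryError("connectivity must list one reference tuple per atom")
        for i, refs in enumerate(self.connectivity):
            if len(refs) != min(i, 3):
                raise GeometryError(f"atom {i} needs {min(i, 3)} references, got {len(refs)}")
            if any(r >= i or r < 0 for r in refs):
                raise GeometryError(f"atom {i} references a later atom: {refs}")
        for i in range(1, n):
            if self.bonds[i] <= 0:
                raise GeometryError(f"bond length for atom {i} must be positive")
        for i in range(2, n):
            if not 0.0 < self.angles[i] < 180.0:
                raise GeometryError(f"angle for atom {i} must lie in (0, 180) degrees")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def to_internals(geometry: Geometry, connectivity: Connectivity) -> ZMatrix:
    """Measure Z-matrix internal coordinates over the given connectivity."""
    n = geometry.n_atoms
    if len(connectivity) != n:
        raise GeometryError("connectivity must cover all atoms")
    p = geometry.coords
    bonds = np.full(n, np.nan)
    angles = np.full(n, np.nan)
    dihedrals = np.full(n, np.nan)
    for i in range(1, n):
        refs = connectivity[i]
        j = refs[0]
        bonds[i] = float(np.linalg.norm(p[i] - p[j]))
        if i >= 2:
            k = refs[1]
            ang = _angle_deg(p[i], p[j], p[k])
            if ang < 1e-6 * 180 or ang > 180 - 1e-6 * 180:
                raise GeometryError(f"collinear angle reference for atoms ({i}, {j}, {k})")
            angles[i] = ang
        if i >= 3:
            l = refs[2]
            ref_ang = _angle_deg(p[j], p[k], p[l])
            if ref_ang < 1e-4 or ref_ang > 180 - 1e-4:
                raise GeometryError(
                    f"collinear dihedral reference atoms ({j}, {k}, {l}) for atom {i}")
            dihedrals[i] = dihedral(geometry, i, j, k, l)
    return ZMatrix(list(geometry.elements), list(connectivity), bonds, angles, dihedrals,
                   label=geometry.label)


def from_internals(zmat: ZMatrix) -> Geometry:
    """Rebuild Cartesian coordinates (natural-extension reference frame).

    The absolute orientation is arbitrary; a round trip through
    :func:`to_internals` reproduces the original geometry up to a rigid
    rotation/translation.
    """
    n = len(zmat.elements)
    p = np.zeros((n, 3))
    for i in range(1, n):
        refs = zmat.connectivity[i]
        r = zmat.bonds[i]
        if i == 1:
            p[i] = p[refs[0]] + np.array([r, 0.0, 0.0])
            continue
        j, k = refs[0], refs[1]
        theta = np.radians(zmat.angles[i])
        if i == 2:
            u = p[k] - p[j]
            u /= np.linalg.norm(u)
            # in-plane perpendicular: any vector normal to u in the xy-plane
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            p[i] = p[j] + r * (np.cos(theta) * u + np.sin(theta) * perp)
            continue
        l = refs[2]
        phi = np.radians(zmat.dihedrals[i])
        b1 = p[j] - p[k]
        b1 /= np.linalg.norm(b1)
        b0 = p[k] - p[l]
        nvec = np.cross(b0, b1)
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            raise GeometryError(f"collinear dihedral reference atoms ({j}, {k}, {l})")
        nvec /= nn
        mvec = np.cross(nvec, b1)
        # natural extension: the new bond makes angle theta with j->k and
        # dihedral phi about the j-k axis
        d = r * (-np.cos(theta) * b1 + np.sin(theta) * (np.cos(phi) * mvec - np.sin(phi) * nvec))
        p[i] = p[j] + d
    geom = Geometry(list(zmat.elements), p, label=zmat.label)
    return geom


def _wrap_arc(delta: float) -> float:
    """Map a dihedral difference onto the shorter arc in (−180, 180]."""
    d = (delta + 180.0) % 360.0 - 180.0
    if d == -180.0:
        d = 180.0
    return d


@dataclass
class LIICPath:
    """An ordered geometry series with interpolation fractions λ ∈ [0, 1]."""

    geometries: list[Geometry]
    lambdas: np.ndarray
    connectivity: Connectivity
    energies: pd.DataFrame | None = None  # optional per-state energies (eV)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.geometries) != self.lambdas.size:
            raise GeometryError("one geometry required per lambda")
        if np.any(np.diff(self.lambdas) <= 0):
            raise GeometryError("lambda values must be strictly increasing")

    def dihedral_profile(self, i: int, j: int, k: int, l: int) -> np.ndarray:
        return np.array([dihedral(g, i, j, k, l) for g in self.geometries])


def _align_onto(mobile: Geometry, reference: Geometry) -> Geometry:
    """Rigidly align (rotation + translation, Kabsch) mobile onto reference."""
    x = mobile.coords - mobile.coords.mean(axis=0)
    y = reference.coords - reference.coords.mean(axis=0)
    rot, _ = Rotation.align_vectors(y, x)
    return Geometry(list(mobile.elements), rot.apply(x) + reference.coords.mean(axis=0),
                    label=mobile.label)


def liic_path(geom_a: Geometry, geom_b: Geometry, n_points: int,
              connectivity: Connectivity,
              dihedral_direction: dict[int, int] | None = None) -> LIICPath:
    """Linearly interpolate internal coordinates between two geometries.

    ``dihedral_direction`` optionally forces the rotation sense (+1/−1) of
    the dihedral placing a given atom, overriding the shorter-arc rule for
    arcs near the ±180° ambiguity.  Endpoint frames are the inputs exactly.
    """
    if n_points < 2:
        raise GeometryError("an LIIC path needs at least 2 points")
    if geom_a.elements != geom_b.elements:
        raise GeometryError("endpoint geometries have different atoms or ordering")
    za = to_internals(geom_a, connectivity)
    zb = to_internals(geom_b, connectivity)
    n = geom_a.n_atoms
    d_dih = np.zeros(n)
    for i in range(3, n):
        delta = _wrap_arc(zb.dihedrals[i] - za.dihedrals[i])
        if dihedral_direction and i in dihedral_direction:
            want = dihedral_direction[i]
            if want not in (+1, -1):
                raise GeometryError("dihedral_direction values must be +1 or -1")
            if delta != 0.0 and np.sign(delta) != want:
                delta -= np.sign(delta) * 360.0
        d_dih[i] = delta

    lambdas = np.linspace(0.0, 1.0, n_points)
    geoms: list[Geometry] = [geom_a]
    for lam in lambdas[1:-1]:
        z = ZMatrix(
            list(za.elements), list(connectivity),
            bonds=za.bonds + lam * (zb.bonds - za.bonds),
            angles=za.angles + lam * (zb.angles - za.angles),
            dihedrals=za.dihedrals + lam * d_dih,
            label=f"liic lambda={lam:.4f}",
        )
        geoms.append(_align_onto(from_internals(z), geoms[-1]))
    geoms.append(geom_b)
    return LIICPath(geoms, lambdas, list(connectivity))
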