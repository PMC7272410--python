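"""Molecular geometries and XYZ file handling.

A :class:`Geometry` is an ordered list of element symbols with Cartesian
coordinates in Å.  The comment line of an XYZ file is kept as the geometry
label, which downstream code uses to tag critical points on the excited-state
surface (e.g. ``FC``, ``PM``, ``SB``, ``DB``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "GeometryError", "read_xyz", "write_xyz", "read_xyz_frames", "dihedral"]


class GeometryError(ValueError):
    """Raised for malformed geometry files or invalid geometric requests."""


@dataclass
class Geometry:
    """Element symbols plus Cartesian coordinates (Å)."""

    elements: list[str]
    coords: np.ndarray  # shape (n_atoms, 3), Å
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != self.coords.shape[0]:
            raise GeometryError(
                f"{len(self.elements)} element symbols but {self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        """Interatomic distance in Å."""
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


def read_xyz(path) -> Geometry:
    """Read a single-frame standard XYZ file.

    The declared atom count must match the body; the comment line becomes the
    geometry label.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    return _parse_xyz_block(lines, path=str(path), offset=0)[0]


def read_xyz_frames(path) -> list[Geometry]:
    """Read a multi-frame XYZ file (concatenated frames), e.g. an LIIC path."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        geom, pos = _parse_xyz_block(lines, path=str(path), offset=pos)
        frames.append(geom)
    if not frames:
        raise GeometryError(f"{path}: no XYZ frames found")
    return frames


def _parse_xyz_block(lines: list[str], path: str, offset: int) -> tuple[Geometry, int]:
    try:
        n_atoms = int(lines[offset].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path}, line {offset + 1}: malformed atom-count line") from exc
    if len(lines) < offset + 2 + n_atoms:
        raise GeometryError(
            f"{path}: declares {n_atoms} atoms but file ends after line {len(lines)}"
        )
    label = lines[offset + 1].strip()
    elements: list[str] = []
    coords = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        lineno = offset + 2 + i
        parts = lines[lineno].split()
        if len(parts) < 4:
            raise GeometryError(f"{path}, line {lineno + 1}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise GeometryError(f"{path}, line {lineno + 1}: non-numeric coordinate") from exc
    return Geometry(elements, coords, label=label), offset + 2 + n_atoms


def write_xyz(geometry: Geometry, path, mode: str = "w") -> None:
    """Write a Geometry in standard XYZ format (6-decimal coordinates)."""
    with open(path, mode, encoding="utf-8") as fh:
        fh.write(f"{geometry.n_atoms}\n{geometry.label}\n")
        for el, (x, y, z) in zip(geometry.elements, geometry.coords):
            fh.write(f"{el} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def dihedral(geometry: Geometry, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle i-j-k-l in degrees, in (−180, 180].

    Positive sign follows the IUPAC convention: looking down j→k, a clockwise
    rotation of l relative to i is positive.  Mirror images flip the sign.
    """
    if len({i, j, k, l}) != 4:
        raise GeometryError("dihedral needs four distinct atoms")
    p = geometry.coords
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError(f"collinear atoms in dihedral ({i}, {j}, {k}, {l})")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)
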