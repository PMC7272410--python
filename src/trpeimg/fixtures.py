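"""Loaders for the packaged synthetic fixtures.

The fixtures are stand-ins constructed by this package, not quantum-
chemistry output: two model Dyson orbitals (a planar π-like orbital and a
twisted, delocalised two-fragment orbital) and a pair of surrogate
chromophore-tail geometries for the planar-minimum → single-bond-rotated
path.  They reproduce the qualitative character of the real systems — the
sign and size of β₂ and which dihedral carries the motion — not their
ab-initio values.
"""

from __future__ import annotations

from importlib import resources

from .geometry import Geometry, read_xyz
from .liic import Connectivity
from .orbitals import DysonOrbital, read_orbital

__all__ = [
    "planar_pi_orbital",
    "twisted_orbital",
    "fixture_geometries",
    "fixture_connectivity",
    "SB_DIHEDRAL_ATOMS",
    "DB_DIHEDRAL_ATOMS",
]


def _data_path(name: str):
    return resources.files("trpeimg.data").joinpath(name)


def planar_pi_orbital() -> DysonOrbital:
    """Synthetic planar π-like orbital: parallel p primitives on collinear
    centres, the character expected to give β₂ < 0."""
    with resources.as_file(_data_path("psi_planar_pi_synthetic.json")) as p:
        return read_orbital(p, dialect="json")


def twisted_orbital() -> DysonOrbital:
    """Synthetic twisted, delocalised two-fragment orbital with perpendicular
    p orientations, the character expected to give β₂ ≈ 0."""
    with resources.as_file(_data_path("psi_twisted_synthetic.json")) as p:
        return read_orbital(p, dialect="json")


# Surrogate tail: O=C1-C2=C3 backbone with hydrogens (a 2-propenal-like
# chain).  Atom order: O, C1, C2, C3, H(C1), H(C2), H(C3), H(C3).
SB_DIHEDRAL_ATOMS = (0, 1, 2, 3)   # O=C1-C2=C3: rotation about the C1-C2 single bond
DB_DIHEDRAL_ATOMS = (1, 2, 3, 6)   # C1-C2=C3-H: rotation about the C2=C3 double bond


def fixture_connectivity() -> Connectivity:
    """Z-matrix references matching the packaged surrogate geometries."""
    return [
        (),            # O
        (0,),          # C1 bonded to O
        (1, 0),        # C2: bond C1, angle C2-C1-O
        (2, 1, 0),     # C3: bond C2, angle C3-C2-C1, dihedral C3-C2-C1-O
        (1, 2, 3),     # H on C1
        (2, 1, 0),     # H on C2
        (3, 2, 1),     # H on C3
        (3, 2, 1),     # H' on C3
    ]


def fixture_geometries() -> tuple[Geometry, Geometry]:
    """(planar-minimum, single-bond-rotated) surrogate geometries (XYZ, Å)."""
    with resources.as_file(_data_path("pm_synthetic.xyz")) as p:
        pm = read_xyz(p)
    with resources.as_file(_data_path("sb_synthetic.xyz")) as p:
        sb = read_xyz(p)
    return pm, sb
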