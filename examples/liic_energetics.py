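"""Interpolate between critical geometries and assign spectral features.

Builds the LIIC path from the planar minimum to the single-bond-rotated
minimum of the packaged surrogate chromophore tail, tracks both
isomerisation dihedrals along it, and scores the two measured photoelectron
features against all candidate geometries using the energetics table plus
model anisotropies.
"""

import numpy as np

from trpeimg.config import pck_fixture
from trpeimg.energetics import (
    CandidateGeometry,
    MeasuredFeature,
    assign,
    epsilon_max_fc,
    epsilon_range_geom,
)
from trpeimg.fixtures import (
    DB_DIHEDRAL_ATOMS,
    SB_DIHEDRAL_ATOMS,
    fixture_connectivity,
    fixture_geometries,
)
from trpeimg.liic import liic_path

pm, sb = fixture_geometries()
path = liic_path(pm, sb, 9, fixture_connectivity())
phi_sb = path.dihedral_profile(*SB_DIHEDRAL_ATOMS)
phi_db = path.dihedral_profile(*DB_DIHEDRAL_ATOMS)
print("LIIC path PM -> SB (9 frames):")
print("  phi_SB:", np.array2string(np.round(np.abs(phi_sb), 1)))
print("  phi_DB:", np.array2string(np.round(np.abs(phi_db), 1)))
print("  only the single-bond dihedral moves; the double bond stays planar\n")

model = pck_fixture().energetics
print(f"two-photon detachment limit eps_FC = {epsilon_max_fc(model).eps_eV:.2f} eV")
for label in ("FC", "PM", "SB", "DB"):
    w = epsilon_range_geom(model, label)
    print(f"  {label}: predicted signal range {w.eps_lo_eV:.2f} - {w.eps_hi_eV:.2f} eV")

features = [
    MeasuredFeature("eps1 (t=0)", 1.4, 0.3, -0.36, 0.09),
    MeasuredFeature("eps2 (t=1ps)", 0.8, 0.3, -0.11, 0.12),
]
model_beta = {"FC": -0.48, "PM": -0.40, "SB": -0.19, "DB": 0.04}
candidates = [CandidateGeometry(lbl, epsilon_range_geom(model, lbl), model_beta[lbl])
              for lbl in ("FC", "PM", "SB", "DB")]
report = assign(features, candidates, model)
print()
for feat in features:
    print(f"feature {feat.label}: ranked candidates -> {report.ranking[feat.label]}")
print("\nThe late-time peak is energetically incompatible with double-bond")
print("rotation (its maximum lies below 0.21 eV) and its anisotropy matches the")
print("single-bond-rotated geometry: the dynamics follow the single bond.")
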