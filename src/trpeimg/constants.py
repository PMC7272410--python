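"""Unit conventions used across the package.

Lengths are Å in geometry files and bohr in orbital math; energies are eV at
the interfaces and hartree inside quantum-mechanical formulas.
"""

BOHR_TO_ANGSTROM = 0.52917721067
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_EV = 27.211386
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
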