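"""Unit system and conversion constants.

The internal unit system follows the molecular-mechanics "real" convention:
length Å, time fs, mass amu (g/mol), energy kcal/mol, force kcal/mol/Å.
All conversions between this system and pressure/stress units are centralized
here; no module defines its own conversion factors.
"""

from __future__ import annotations

#: Avogadro constant, 1/mol (CODATA 2018).
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL = 0.001987204259

#: 1 amu·Å²/fs² expressed in kcal/mol (kinetic-energy conversion).
AMU_A2_FS2_TO_KCAL_MOL = 1.66053906892e-27 * 1e10 * N_AVOGADRO / 4184.0

#: 1 kcal/mol/Å³ expressed in GPa (energy density → pressure).
KCAL_MOL_A3_TO_GPA = 4184.0 / N_AVOGADRO / 1e-30 / 1e9

#: 1 kcal/mol/Å³ expressed in atm.
KCAL_MOL_A3_TO_ATM = 4184.0 / N_AVOGADRO / 1e-30 / 101325.0

#: 1 GPa in atm.
GPA_TO_ATM = 1e9 / 101325.0

#: Hydroxyapatite Ca10(PO4)6(OH)2 formula mass, g/mol (44 atoms per unit).
HA_MOLAR_MASS = 1004.62

#: Water molar mass, g/mol.
WATER_MOLAR_MASS = 18.015
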