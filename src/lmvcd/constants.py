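"""Physical constants and unit conversions.

Internal unit system: wavenumbers in cm^-1, lengths in angstrom, masses in
unified atomic mass units (u), charges in units of the elementary charge e,
momentum-containing matrix elements in units of hbar/angstrom.  All cgs
(electrostatic) conversion factors are isolated here; nothing else in the
package hard-codes a physical constant.
"""

from __future__ import annotations

import math

# CODATA 2018, cgs-Gaussian
HBAR = 1.054571817e-27  # erg s
PLANCK_H = 2.0 * math.pi * HBAR  # erg s
C_LIGHT = 2.99792458e10  # cm/s
AMU = 1.66053906660e-24  # g
E_ESU = 4.80320425e-10  # statC (esu)
AVOGADRO = 6.02214076e23  # 1/mol

CM_PER_ANGSTROM = 1.0e-8
ANGSTROM_PER_CM = 1.0e8

#: electric transition moment conversion: (e * angstrom) -> esu cm
EA_TO_ESU_CM = E_ESU * CM_PER_ANGSTROM

#: dipole strength conversion: (e*angstrom)^2 -> 10^-40 esu^2 cm^2
EA2_TO_1E40_ESU2CM2 = EA_TO_ESU_CM**2 / 1.0e-40

#: rotational strength conversion: (e*angstrom)^2 -> 10^-44 esu^2 cm^2
EA2_TO_1E44_ESU2CM2 = EA_TO_ESU_CM**2 / 1.0e-44

# Integrated-absorption conversion, cgs derivation:
#   integral( eps(nu)/nu dnu ) = [8 pi^3 N_A / (3000 h c ln10)] * D
# with D the dipole strength in esu^2 cm^2 and eps the decadic molar
# absorptivity in L mol^-1 cm^-1.  The same constant with 4R in place of D
# gives the circular-dichroism integral of delta_eps/nu.
EPS_INTEGRAL_PER_D = (
    8.0 * math.pi**3 * AVOGADRO / (3000.0 * PLANCK_H * C_LIGHT * math.log(10.0))
)  # ~1.087e38 per esu^2 cm^2


def angular_frequency(wavenumber_cm1: float) -> float:
    """Angular frequency (rad/s) of a transition at ``wavenumber_cm1``."""
    return 2.0 * math.pi * C_LIGHT * wavenumber_cm1


def reduced_mass_u(m1_u: float, m2_u: float) -> float:
    """Reduced mass of a diatomic pair, in u."""
    return m1_u * m2_u / (m1_u + m2_u)


# Isotopic masses (u) of the atoms occurring in CH/XH local modes.
ATOMIC_MASS_U = {
    "H": 1.00782503207,
    "C": 12.0,
    "O": 15.99491461956,
    "S": 31.97207100,
    "N": 14.0030740048,
}

#: the idealised 12C-1H reduced mass used throughout the CH local-mode
#: literature (integer masses 12 and 1)
CH_REDUCED_MASS_U = 12.0 / 13.0
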