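"""Physical constants (CODATA 2018) and the unit conversions used across the package.

Internal unit chain: energies in kJ/mol, lengths in Å, masses in amu, time in fs,
temperatures in K.  Frequencies are reported in cm^-1, pressures at the interface
in GPa.  Everything below is derived from the CODATA 2018 defining constants so
that a single source of truth exists for unit conversions.
"""

import math

# --- CODATA 2018 (SI) ---
AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN_SI = 1.380649e-23  # J/K
PLANCK_SI = 6.62607015e-34  # J s
HBAR_SI = PLANCK_SI / (2.0 * math.pi)  # J s
SPEED_OF_LIGHT_SI = 2.99792458e8  # m/s
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
AMU_KG = 1.66053906660e-27  # kg

# --- derived, in the internal unit chain ---
#: Boltzmann constant, kJ/(mol K)
KB = BOLTZMANN_SI * AVOGADRO / 1000.0

#: Coulomb prefactor e^2/(4 pi eps0) expressed in kJ Å / (mol e^2);
#: energy of two unit charges 1 Å apart is this many kJ/mol.
COULOMB_KJ_A = (
    ELEMENTARY_CHARGE**2
    / (4.0 * math.pi * VACUUM_PERMITTIVITY)
    * 1e10
    * AVOGADRO
    / 1000.0
)

#: sqrt(kJ/mol/Å^2/amu) -> angular frequency in rad/s
_OMEGA_SI_PER_INTERNAL = math.sqrt(1000.0 / AVOGADRO / AMU_KG / 1e-20)

#: sqrt of a dynamical-matrix eigenvalue (kJ/mol/Å^2/amu) -> wavenumber in cm^-1
SQRT_EV_TO_CM1 = _OMEGA_SI_PER_INTERNAL / (2.0 * math.pi * SPEED_OF_LIGHT_SI * 100.0)

#: photon energy of 1 cm^-1 in kJ/mol (h c nu-tilde)
CM1_TO_KJMOL = PLANCK_SI * SPEED_OF_LIGHT_SI * 100.0 * AVOGADRO / 1000.0

#: 1 GPa expressed in kJ/(mol Å^3)
GPA_TO_KJMOL_A3 = 1e9 * 1e-30 * AVOGADRO / 1000.0

#: 1 atm expressed in kJ/(mol Å^3)
ATM_TO_KJMOL_A3 = 101325.0 * 1e-30 * AVOGADRO / 1000.0

#: multiply force[kJ/mol/Å] / mass[amu] by this to get acceleration in Å/fs^2
FORCE_OVER_MASS_TO_ACC = 1000.0 / AVOGADRO / 1e-10 / AMU_KG * 1e-20


def thermal_speed(temperature, mass):
    """RMS thermal speed sqrt(3 kB T / m) in Å/fs for ``mass`` in amu."""
    v_si = math.sqrt(3.0 * BOLTZMANN_SI * temperature / (mass * AMU_KG))
    return v_si * 1e-5  # m/s -> Å/fs
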