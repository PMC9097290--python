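"""Physical constants and unit conversions.

The package works internally in "real" molecular-mechanics units:
Angstrom, kcal/mol, femtosecond, g/mol, charges in units of the elementary
charge.  The analysis layer reports nm, pN, pN nm and pN nm^2, which are the
units of single-molecule experiments.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used by the electrostatics and thermostat.

    Attributes
    ----------
    kB_J : Boltzmann constant in J/K.
    NA : Avogadro constant in 1/mol.
    e0 : elementary charge in C.
    eps0 : vacuum permittivity in F/m.
    epsr : relative permittivity of water (dimensionless).
    """

    kB_J: float = 1.38e-23
    NA: float = 6.022e23
    e0: float = 1.6e-19
    eps0: float = 8.859e-12
    epsr: float = 78.3

    @property
    def kB_kcal_mol(self) -> float:
        """Boltzmann constant in kcal/mol/K."""
        return self.kB_J * self.NA / CAL_PER_J_MOL

    @property
    def kB_pN_nm(self) -> float:
        """Boltzmann constant in pN nm / K (kB*300 K ~ 4.14 pN nm)."""
        return self.kB_J * 1e21

    def kBT(self, T: float) -> float:
        """Thermal energy at temperature ``T`` (K) in kcal/mol."""
        return self.kB_kcal_mol * T

    @property
    def coulomb_kcal_A(self) -> float:
        """e0^2 NA / (4 pi eps0), in kcal Angstrom / mol.

        Multiply by q_i q_j / (epsr * r[A]) for the Coulomb energy in vacuo
        water; evaluates to ~331 kcal A/mol with the constants above.
        """
        import math

        return self.e0**2 * self.NA / (4.0 * math.pi * self.eps0) / CAL_PER_J_MOL * 1e10


CONSTANTS = PhysicalConstants()

# 1 kcal = 4184 J
CAL_PER_J_MOL = 4184.0

# force: kcal/mol/A -> pN
KCAL_MOL_A_TO_PN = CAL_PER_J_MOL / CONSTANTS.NA / 1e-10 * 1e12
# energy: pN nm -> kcal/mol
PN_NM_TO_KCAL_MOL = 1e-21 * CONSTANTS.NA / CAL_PER_J_MOL
# kinetic energy: (g/mol) (A/fs)^2 -> kcal/mol
MVSQ2E = 1e7 / CAL_PER_J_MOL
# acceleration: (kcal/mol/A) / (g/mol) -> A/fs^2
FTM2A = 1.0 / MVSQ2E

# Bead masses in g/mol.  The nucleotide mass is split between the phosphate
# group, the deoxyribose sugar and the base; masses only affect kinetics, not
# the configurational ensemble sampled by the Langevin thermostat.
BEAD_MASSES = {
    "P": 95.0,
    "S": 115.0,
    "A": 134.0,
    "C": 110.0,
    "G": 150.0,
    "T": 125.0,
}
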