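"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in Angstrom, charges in elementary charge
units (e), energies in kcal/mol, potentials in kcal/(mol*e).
"""

import math

#: Coulomb constant so that phi(r) = COULOMB * q / (eps * r) is in kcal/(mol*e)
#: for q in e and r in Angstrom.
COULOMB = 332.0637

#: kcal/mol corresponding to 1 eV (equivalently, 1 V per unit charge).
KCAL_PER_VOLT = 23.0605

#: Boltzmann constant in kcal/(mol*K).
BOLTZMANN = 1.9872041e-3

#: Avogadro-derived factor converting mol/L to particles per A^3.
MOLAR_TO_PER_A3 = 6.02214076e-4

FOUR_PI = 4.0 * math.pi


def kappa_bar_squared(ionic_strength: float, temperature: float) -> float:
    """Modified Debye screening factor ``kappa_bar^2`` in 1/A^2.

    This is the coefficient of ``-phi`` in the linearized PB equation
    written as ``div(eps grad phi) - kappa_bar^2 phi = -4 pi k rho``;
    it already contains the solvent dielectric implicitly through its
    definition and is applied only at solvent grid nodes.

    Parameters
    ----------
    ionic_strength : float
        Ionic strength in mol/L.
    temperature : float
        Temperature in K.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    return (2.0 * FOUR_PI * COULOMB * MOLAR_TO_PER_A3 * ionic_strength
            / (BOLTZMANN * temperature))
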