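"""Physical constants in the unit system of the package.

Lengths in angstrom, energies in kcal/mol, time in ns, charge in units
of the elementary charge, temperature in kelvin.
"""

KB_KCAL = 0.0019872041
"""Boltzmann constant, kcal/(mol K)."""

COULOMB_KCAL = 332.0636
"""Coulomb constant k_e = 1/(4 pi eps0), kcal A/(mol e^2)."""

ELEMENTARY_CHARGE_C = 1.60217662e-19
"""Elementary charge in coulombs (used for ionic-current conversion)."""

DEBYE_CONST = 3.04
"""Debye length prefactor for water near room temperature:
lambda_D = 3.04 / sqrt(I) angstrom with I in molar."""
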