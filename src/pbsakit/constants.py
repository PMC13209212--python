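"""Physical constants in the package's internal unit system.

Internal units are Angstrom, elementary charge, kcal/mol and Kelvin
throughout; SI constants appear only inside the Debye-length formula,
which is evaluated in SI and converted to Angstrom at the end.
"""

#: Coulomb's constant e^2/(4 pi eps_0), kcal mol^-1 A e^-2.
COULOMB_KCAL = 332.0637

#: Boltzmann constant, kcal mol^-1 K^-1 (per particle, molar scale).
BOLTZMANN_KCAL = 0.0019872

#: Ideal gas constant, kcal mol^-1 K^-1 (numerically identical to k_B on
#: the molar scale used here).
GAS_CONSTANT_KCAL = 0.0019872

# SI constants, used only by debye_length.
VACUUM_PERMITTIVITY_SI = 8.8541878128e-12  # F m^-1
BOLTZMANN_SI = 1.380649e-23                # J K^-1
ELEMENTARY_CHARGE_SI = 1.602176634e-19     # C
AVOGADRO = 6.02214076e23                   # mol^-1
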