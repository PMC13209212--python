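"""Debye length and screened Coulomb energies in salty media.

Mobile ions damp long-range electrostatics; the Debye length lambda_D is
the distance over which the damping factor exp(-r/lambda_D) falls to 1/e.
"""

import pbsakit as pk

saline = [(0.15, 1), (0.15, -1)]  # mol/L Na+ / Cl-
lam = pk.debye_length(saline, epsilon_solvent=80.0, temperature=298.15)
print(f"Debye length of normal saline at 298.15 K: {lam:.2f} A")

# A +1/-1 ion pair exactly one Debye length apart: the screened energy is
# the plain Coulomb energy attenuated by 1/e.
top, frame = pk.two_ion_dimer(separation=lam)
plain = pk.elec_energy(frame, top).total
screened = pk.elec_energy(
    frame, top, pk.ScreeningParams(enabled=True, ion_species=saline)
).total
print(f"unscreened pair energy : {plain:8.3f} kcal/mol")
print(f"screened pair energy   : {screened:8.3f} kcal/mol "
      f"(ratio {screened / plain:.4f}, 1/e = 0.3679)")
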