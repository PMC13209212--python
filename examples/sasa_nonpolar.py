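"""Solvent-accessible surface area and the non-polar binding term.

Non-polar solvation follows the linear SASA model G = gamma * A + b.
Binding buries interface area (dA < 0), so the non-polar term usually
favours complex formation.
"""

import numpy as np

import pbsakit as pk

# isolated sphere: area is exactly 4 pi (r + probe)^2
frame_one = pk.Frame(0, 0.0, np.zeros((1, 3)))
area = pk.shrake_rupley(frame_one, np.array([1.0]))[0]
print(f"isolated r=1.0 A atom with 1.4 A probe: {area:.2f} A^2 "
      f"(exact {4 * np.pi * 2.4**2:.2f})")

top, frames = pk.generate_toy_system(
    pk.ToySpec(n_receptor_atoms=10, n_ligand_atoms=3, n_frames=1, seed=3)
)
frame = frames[0]
a_complex = pk.shrake_rupley(frame, top.radii).sum()
a_parts = sum(
    pk.shrake_rupley(
        pk.extract_group(frame, top, w), top.radii[top.group_indices(w)]
    ).sum()
    for w in ("receptor", "ligand")
)
print(f"complex SASA {a_complex:.1f} A^2 vs unbound parts {a_parts:.1f} A^2 "
      f"(buried {a_parts - a_complex:.1f} A^2)")

delta, _ = pk.binding_nonpolar(frame, top)
print(f"ddG_nonpolar = {delta:.3f} kcal/mol "
      f"(gamma = 0.00542 kcal/mol/A^2, b = 0.92 kcal/mol per species)")
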