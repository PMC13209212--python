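"""In silico alanine scanning of a receptor residue.

Each target residue is truncated to alanine (side chain removed beyond
C-beta, retained atoms frozen in place, charges reset from an alanine
template) and the binding energy is recomputed.  The mutant - wild-type
difference measures that side chain's contribution to binding.
"""

import numpy as np

import pbsakit as pk

# tiny peptide-like receptor: one LEU-style residue + backbone-only GLY,
# with a charged one-atom ligand nearby
names = [
    ("N", -0.4), ("H", 0.3), ("CA", 0.0), ("HA", 0.1),
    ("CB", -0.1), ("HB1", 0.05), ("HB2", 0.05),
    ("CG", -0.6), ("HG", 0.1), ("CD1", 0.2), ("CD2", 0.2),
    ("C", 0.6), ("O", -0.55),
]
rng = np.random.default_rng(4)
atoms, coords = [], []
for i, (name, q) in enumerate(names, start=1):
    atoms.append(pk.AtomRecord(i, name, 1, "LEU", q, 20.0, 2000.0, 1.6))
    coords.append(rng.uniform(0, 6, 3))
atoms.append(pk.AtomRecord(len(names) + 1, "LIG", 2, "MOL", 1.0, 20.0, 2000.0, 1.8))
coords.append(np.array([9.0, 3.0, 3.0]))
top = pk.Topology(atoms=atoms, receptor_group=tuple(range(1, len(names) + 1)),
                  ligand_group=(len(names) + 1,))
frame = pk.Frame(0, 0.0, np.array(coords))

wt, mutants = pk.alanine_scan(
    [frame], top, [1],
    pb_params=pk.PBParams(grid_spacing=0.8, grid_margin=6.0),
)
mut = mutants[1]
print(f"wild type dH : {wt.mean['dh']:8.3f} kcal/mol")
print(f"L1A mutant dH: {mut.mean['dh']:8.3f} kcal/mol")
print(f"ddH (mut-wt) : {mut.mean['dh'] - wt.mean['dh']:8.3f} kcal/mol")
print("a positive ddH means the truncated side chain was helping binding")
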