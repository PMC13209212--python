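"""Per-residue aggregation of per-atom energies and B-factor export.

The binding energy of a residue is the sum of the per-atom contributions
of its atoms, so residue sums conserve the molecular total by
construction.  For visualization, the per-residue (or per-atom) energy is
written into the B-factor column of a single-MODEL PDB, ready for
"B-factor putty" rendering.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .topology import Topology
from .trajectory import Frame, write_pdb


def residue_decompose(
    per_atom: Mapping[int, float], topology: Topology
) -> dict[tuple[int, str], float]:
    """Accumulate per-atom energies onto (residue_id, residue_name) keys.

    Residues with no contributing atoms get 0; an atom id absent from the
    topology is an error.
    """
    known = {a.atom_id: a for a in topology.atoms}
    stray = set(per_atom) - set(known)
    if stray:
        raise ValidationError(f"unknown atom_id(s) in per-atom map: {sorted(stray)}")
    out: dict[tuple[int, str], float] = {}
    for a in topology.atoms:
        out.setdefault((a.residue_id, a.residue_name), 0.0)
    for atom_id, value in per_atom.items():
        a = known[atom_id]
        out[(a.residue_id, a.residue_name)] += float(value)
    return out


def write_bfactor_pdb(
    frame: Frame,
    topology: Topology,
    per_residue: Mapping[tuple[int, str], float] | Mapping[int, float],
    path: str | Path,
    per_atom: bool = False,
) -> None:
    """Write a single-MODEL PDB with energies in the B-factor column.

    By default every atom carries its residue's energy; with
    ``per_atom=True`` the map is interpreted as atom_id -> energy instead.
    Values are formatted to 2 decimals and clamped to the PDB column
    range [-999.99, 999.99].
    """
    n = topology.n_atoms
    b = np.zeros(n)
    if per_atom:
        for i, a in enumerate(topology.atoms):
            b[i] = float(per_residue.get(a.atom_id, 0.0))
    else:
        lookup = {}
        for key, value in per_residue.items():
            rid = key[0] if isinstance(key, tuple) else key
            lookup[rid] = float(value)
        for i, a in enumerate(topology.atoms):
            b[i] = lookup.get(a.residue_id, 0.0)
    write_pdb(path, frame, topology, bfactors=b)


def residue_table(
    per_atom_terms: Mapping[str, Mapping[int, float]], topology: Topology
) -> pd.DataFrame:
    """Residue x term table (elec, vdw, polar, nonpolar, total) in kcal/mol."""
    rows: dict[tuple[int, str], dict[str, float]] = {}
    for term, per_atom in per_atom_terms.items():
        for key, value in residue_decompose(per_atom, topology).items():
            rows.setdefault(key, {})[term] = value
    records = []
    for (rid, rname), terms in sorted(rows.items()):
        rec = {"residue_id": rid, "residue_name": rname}
        rec.update(terms)
        rec["total"] = sum(terms.values())
        records.append(rec)
    return pd.DataFrame.from_records(records)
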