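"""In silico alanine scanning by side-chain truncation.

A receptor residue is mutated to alanine by deleting every side-chain
atom beyond the C-beta and keeping all retained atoms (backbone, CB and
the hydrogens already bonded to CB) at their original coordinates — no
geometry is rebuilt.  Partial charges of the retained atoms are
reassigned from a bundled alanine charge template (Amber ff14SB-style) so
the truncated residue is a chemically sensible, net-neutral alanine.
The binding energy terms are then recomputed frame by frame and reported
as mutant - wild-type differences.

GLY (no C-beta), PRO (backbone ring) and residues already ALA are
rejected; ligand residues are out of scope by construction.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Sequence

from .errors import ScopeError, UnsupportedResidueError, ValidationError
from .topology import AtomRecord, Topology
from .trajectory import Frame

logger = logging.getLogger(__name__)

#: Backbone atom names always retained (plus OXT on a C-terminal residue).
BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN", "HA", "HA1", "HA2"}
)

#: Alanine partial-charge template (Amber ff14SB alanine), e units.
ALANINE_CHARGES = {
    "N": -0.4157,
    "H": 0.2719,
    "HN": 0.2719,
    "CA": 0.0337,
    "HA": 0.0823,
    "CB": -0.1825,
    "HB1": 0.0603,
    "HB2": 0.0603,
    "HB3": 0.0603,
    "C": 0.5973,
    "O": -0.5679,
}


def _is_cb_hydrogen(name: str) -> bool:
    # covers HB1/HB2/HB3, 1HB/2HB/3HB and bare HB naming conventions
    n = name.upper()
    return n.startswith("HB") or (n and n[0] in "123" and n[1:].startswith("HB"))


def _template_charge(name: str, fallback: float) -> float:
    n = name.upper()
    if n in ALANINE_CHARGES:
        return ALANINE_CHARGES[n]
    if _is_cb_hydrogen(n):
        return ALANINE_CHARGES["HB1"]
    return fallback


def mutate_to_alanine(
    frame: Frame, topology: Topology, residue_id: int
) -> tuple[Frame, Topology]:
    """Truncate one receptor residue to alanine; returns new frame+topology.

    Retained atoms keep their original coordinates bit-exactly; deleted
    atoms are removed from both the frame and the (renumbered) topology.
    """
    topology.require_groups()
    res_atoms = [a for a in topology.atoms if a.residue_id == residue_id]
    if not res_atoms:
        raise ValidationError(f"residue {residue_id} not found")
    res_name = res_atoms[0].residue_name.upper()
    receptor = set(topology.receptor_group)
    if any(a.atom_id not in receptor for a in res_atoms):
        raise ScopeError(
            f"residue {residue_id} ({res_name}) is not (fully) in the receptor group; "
            "alanine scanning targets receptor residues only"
        )
    if res_name == "ALA":
        raise UnsupportedResidueError(f"residue {residue_id} is already alanine")
    if res_name == "GLY":
        raise UnsupportedResidueError(f"residue {residue_id} is glycine (no C-beta)")
    if res_name == "PRO":
        raise UnsupportedResidueError(
            f"residue {residue_id} is proline (backbone ring cannot be truncated)"
        )
    names = {a.atom_name.upper() for a in res_atoms}
    if "CB" not in names:
        raise UnsupportedResidueError(
            f"residue {residue_id} ({res_name}) has no CB atom"
        )

    def _retained(a: AtomRecord) -> bool:
        n = a.atom_name.upper()
        return n in BACKBONE_NAMES or n == "CB" or _is_cb_hydrogen(n)

    keep_ids = []
    mutated: dict[int, AtomRecord] = {}
    n_cb_h = 0
    for a in topology.atoms:
        if a.residue_id != residue_id:
            keep_ids.append(a.atom_id)
            continue
        if not _retained(a):
            continue
        keep_ids.append(a.atom_id)
        if _is_cb_hydrogen(a.atom_name):
            n_cb_h += 1
        mutated[a.atom_id] = replace(
            a,
            residue_name="ALA",
            charge=_template_charge(a.atom_name, a.charge),
        )
    if 0 < n_cb_h < 3:
        logger.info(
            "residue %d: CB carries %d hydrogen(s) after truncation "
            "(united-atom-like); positions left as-is",
            residue_id,
            n_cb_h,
        )

    atoms = [mutated.get(i, topology.atoms[i - 1]) for i in keep_ids]
    # reuse Topology.subset's renumbering by building an id-keeping copy first
    base = Topology(
        atoms=[replace(a, atom_id=j + 1) for j, a in enumerate(atoms)],
        receptor_group=None,
        ligand_group=None,
        temperature=topology.temperature,
    )
    remap = {old: new for new, old in enumerate(keep_ids, start=1)}
    new_top = Topology(
        atoms=base.atoms,
        receptor_group=tuple(remap[i] for i in topology.receptor_group if i in remap),
        ligand_group=tuple(remap[i] for i in topology.ligand_group if i in remap),
        temperature=topology.temperature,
        original_ids=tuple(keep_ids),
    )
    keep_idx = [i - 1 for i in keep_ids]
    new_frame = Frame(
        index=frame.index,
        time=frame.time,
        coords=frame.coords[keep_idx],
        box=frame.box,
    )
    return new_frame, new_top


def alanine_scan(
    frames: Sequence[Frame],
    topology: Topology,
    residue_ids: Iterable[int],
    screening=None,
    pb_params=None,
    sasa_params=None,
    combining: str = "geometric",
):
    """Scan residues: per-mutant Summary plus the shared wild-type Summary.

    Returns ``(wt_summary, {residue_id: summary-or-None})``; a residue
    that cannot be mutated is logged and marked ``None`` without aborting
    the rest of the scan.  The wild-type run is computed once and is
    identical to a standalone pipeline run with the same parameters.
    """
    from .pipeline import compute_series

    wt_series = compute_series(frames, topology, screening, pb_params, sasa_params, combining)
    from .thermo import summarize

    wt_summary = summarize(wt_series, topology.temperature)
    results: dict[int, object] = {}
    for rid in residue_ids:
        try:
            mutated = [mutate_to_alanine(f, topology, rid) for f in frames]
        except (UnsupportedResidueError, ScopeError, ValidationError) as exc:
            logger.warning("alanine scan: residue %s skipped: %s", rid, exc)
            results[rid] = None
            continue
        mut_top = mutated[0][1]
        mut_frames = [f for f, _t in mutated]
        series = compute_series(
            mut_frames, mut_top, screening, pb_params, sasa_params, combining
        )
        results[rid] = summarize(series, topology.temperature)
    return wt_summary, results
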