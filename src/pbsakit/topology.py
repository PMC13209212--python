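"""Domain types and the plain-text topology sidecar.

The sidecar replaces force-field extraction from binary run files: it is a
whitespace- or comma-separated table with one row per solute atom,

    atom_id atom_name residue_id residue_name charge c6 c12 radius

(``sigma epsilon`` columns may replace ``c6 c12`` and are converted with
C6 = 4*eps*sigma^6, C12 = 4*eps*sigma^12, kcal/mol and Angstrom units).
Lines starting with ``#`` are comments; ``#@ key value`` lines carry
metadata (currently ``temperature`` in K).  Receptor/ligand index groups
may follow the table inline in GROMACS ``.ndx`` syntax::

    [ receptor ]
    1 2 3 ...
    [ ligand ]
    ...

or live in a separate ``.ndx`` file passed to :func:`resolve_groups`.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GroupLookupError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Residue names treated as explicit solvent/ions and dropped on read.
SOLVENT_RESIDUES = frozenset({"SOL", "WAT", "HOH", "NA", "CL", "NA+", "CL-"})

_TABLE_COLUMNS = ("atom_id", "atom_name", "residue_id", "residue_name", "charge")
_DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class AtomRecord:
    """One solute atom: identity, partial charge and non-bonded parameters.

    ``charge`` is in elementary charges, ``lj_c6``/``lj_c12`` in
    kcal*mol^-1*A^6 and kcal*mol^-1*A^12, ``pb_radius`` (the solute cavity
    radius used by the PB and SASA models) in Angstrom.
    """

    atom_id: int
    atom_name: str
    residue_id: int
    residue_name: str
    charge: float
    lj_c6: float
    lj_c12: float
    pb_radius: float


@dataclass
class Topology:
    """Ordered atom table plus receptor/ligand index groups.

    Groups hold 1-based atom ids.  They may be unset (``None``) for
    single-molecule systems (e.g. a lone Born ion); operations that
    difference bound and unbound states call :meth:`require_groups`.
    """

    atoms: list[AtomRecord]
    receptor_group: tuple[int, ...] | None = None
    ligand_group: tuple[int, ...] | None = None
    temperature: float = _DEFAULT_TEMPERATURE
    original_ids: tuple[int, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError("topology has no atoms")
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(1, len(ids) + 1)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValidationError(f"duplicate atom_id(s): {sorted(dupes)}")
            raise ValidationError("atom_ids must be contiguous and 1-based")
        for a in self.atoms:
            if a.lj_c6 < 0 or a.lj_c12 < 0:
                raise ValidationError(f"negative LJ coefficient on atom {a.atom_id}")
            if a.lj_c12 > 0 and a.pb_radius <= 0:
                raise ValidationError(
                    f"atom {a.atom_id} has repulsive LJ but pb_radius <= 0"
                )
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.receptor_group is not None and self.ligand_group is not None:
            self._validate_groups(self.receptor_group, self.ligand_group)

    def _validate_groups(self, rec: Sequence[int], lig: Sequence[int]) -> None:
        rec_s, lig_s = set(rec), set(lig)
        if not rec_s or not lig_s:
            raise ValidationError("receptor and ligand groups must be non-empty")
        overlap = rec_s & lig_s
        if overlap:
            raise ValidationError(f"groups overlap on atom_id(s) {sorted(overlap)}")
        known = {a.atom_id for a in self.atoms}
        stray = (rec_s | lig_s) - known
        if stray:
            raise ValidationError(f"group atom_id(s) not in topology: {sorted(stray)}")

    # -- array views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def c6(self) -> np.ndarray:
        return np.array([a.lj_c6 for a in self.atoms], dtype=float)

    @property
    def c12(self) -> np.ndarray:
        return np.array([a.lj_c12 for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.pb_radius for a in self.atoms], dtype=float)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)

    def require_groups(self) -> None:
        from .errors import StateError

        if self.receptor_group is None or self.ligand_group is None:
            raise StateError("receptor/ligand groups are not resolved")

    def group_indices(self, which: str) -> np.ndarray:
        """0-based atom indices for ``receptor``, ``ligand`` or ``complex``."""
        if which == "complex":
            return np.arange(self.n_atoms)
        self.require_groups()
        group = self.receptor_group if which == "receptor" else self.ligand_group
        return np.array(sorted(group), dtype=int) - 1

    def subset(self, atom_ids: Iterable[int]) -> "Topology":
        """New topology with the given atoms, renumbered contiguously.

        Original 1-based ids are retained in ``original_ids`` and group
        membership is remapped.
        """
        keep = sorted(set(atom_ids))
        known = {a.atom_id for a in self.atoms}
        stray = set(keep) - known
        if stray:
            raise ValidationError(f"unknown atom_id(s): {sorted(stray)}")
        remap = {old: new for new, old in enumerate(keep, start=1)}
        atoms = [
            replace(self.atoms[old - 1], atom_id=remap[old]) for old in keep
        ]
        def _remap_group(group):
            if group is None:
                return None
            kept = tuple(remap[i] for i in group if i in remap)
            return kept or None
        return Topology(
            atoms=atoms,
            receptor_group=_remap_group(self.receptor_group),
            ligand_group=_remap_group(self.ligand_group),
            temperature=self.temperature,
            original_ids=tuple(keep),
        )


# ---------------------------------------------------------------------------
# sidecar I/O


def _split_sections(text: str):
    """Split sidecar text into metadata lines, table lines and ndx lines."""
    meta, table, ndx = [], [], []
    in_ndx = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#@"):
            meta.append(line[2:].strip())
            continue
        if line.startswith("#") or line.startswith(";"):
            continue
        if line.startswith("["):
            in_ndx = True
        (ndx if in_ndx else table).append(line)
    return meta, table, ndx


def parse_ndx(text: str) -> dict[str, tuple[int, ...]]:
    """Parse GROMACS index-file syntax into {group name: atom ids}."""
    groups: dict[str, list[int]] = {}
    current: list[int] | None = None
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        m = re.fullmatch(r"\[\s*(.+?)\s*\]", line)
        if m:
            current = groups.setdefault(m.group(1), [])
            continue
        if current is None:
            raise SchemaError("index data before any [ group ] header")
        try:
            current.extend(int(tok) for tok in line.split())
        except ValueError as exc:
            raise SchemaError(f"non-integer atom id in index file: {line!r}") from exc
    return {name: tuple(ids) for name, ids in groups.items()}


def load_ndx(path: str | Path) -> dict[str, tuple[int, ...]]:
    return parse_ndx(Path(path).read_text())


def load_topology(path: str | Path) -> Topology:
    """Read the topology sidecar; see module docstring for the schema.

    Solvent/ion residues (SOL/WAT/NA/CL...) are dropped with a warning:
    the implicit-solvent models replace explicit water, so only solute
    atoms belong in the energy evaluation.
    """
    text = Path(path).read_text()
    meta, table_lines, ndx_lines = _split_sections(text)
    if not table_lines:
        raise SchemaError(f"{path}: no table rows found")

    # dtype=str + explicit float(): Python's parser is bit-exact on repr()
    # output, which pandas' own float conversion is not
    df = pd.read_csv(
        io.StringIO("\n".join(table_lines)), sep=r"[,\s]+", engine="python", dtype=str
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in df.columns:
        if col not in ("atom_name", "residue_name"):
            df[col] = df[col].map(float)

    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    if {"sigma", "epsilon"} <= set(df.columns):
        sigma = df["sigma"]
        eps = df["epsilon"]
        df["c6"] = 4.0 * eps * sigma**6
        df["c12"] = 4.0 * eps * sigma**12
    if "c6" not in df.columns or "c12" not in df.columns:
        raise SchemaError(f"{path}: need either c6/c12 or sigma/epsilon columns")
    if "radius" not in df.columns:
        raise SchemaError(f"{path}: missing required column(s): ['radius']")

    ids = df["atom_id"].astype(int)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate atom_id(s): {sorted(set(dupes))}")

    solvent = df["residue_name"].str.upper().isin(SOLVENT_RESIDUES)
    if solvent.any():
        logger.warning(
            "dropping %d solvent/ion atoms (%s); MM-PBSA operates on solute only",
            int(solvent.sum()),
            ", ".join(sorted(df.loc[solvent, "residue_name"].unique())),
        )
        df = df[~solvent].reset_index(drop=True)
        if df.empty:
            raise ValidationError(f"{path}: no solute atoms after solvent removal")

    original = tuple(int(i) for i in df["atom_id"])
    remap = {old: new for new, old in enumerate(original, start=1)}
    atoms = [
        AtomRecord(
            atom_id=remap[int(r.atom_id)],
            atom_name=str(r.atom_name),
            residue_id=int(r.residue_id),
            residue_name=str(r.residue_name),
            charge=float(r.charge),
            lj_c6=float(r.c6),
            lj_c12=float(r.c12),
            pb_radius=float(r.radius),
        )
        for r in df.itertuples()
    ]

    temperature = _DEFAULT_TEMPERATURE
    for entry in meta:
        key, _, value = entry.replace("=", " ").partition(" ")
        if key.strip().lower() == "temperature":
            temperature = float(value)

    receptor = ligand = None
    if ndx_lines:
        groups = parse_ndx("\n".join(ndx_lines))
        receptor = tuple(remap[i] for i in groups.get("receptor", ()) if i in remap) or None
        ligand = tuple(remap[i] for i in groups.get("ligand", ()) if i in remap) or None

    return Topology(
        atoms=atoms,
        receptor_group=receptor,
        ligand_group=ligand,
        temperature=temperature,
        original_ids=original if original != tuple(range(1, len(atoms) + 1)) else None,
    )


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the sidecar (table + inline groups); round-trips with
    :func:`load_topology` to full float precision."""
    lines = [f"#@ temperature {topology.temperature!r}"]
    lines.append("atom_id atom_name residue_id residue_name charge c6 c12 radius")
    for a in topology.atoms:
        lines.append(
            f"{a.atom_id} {a.atom_name} {a.residue_id} {a.residue_name} "
            f"{a.charge!r} {a.lj_c6!r} {a.lj_c12!r} {a.pb_radius!r}"
        )
    for name in ("receptor", "ligand"):
        group = getattr(topology, f"{name}_group")
        if group:
            lines.append(f"[ {name} ]")
            lines.append(" ".join(str(i) for i in group))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# group resolution

_RESID_SPEC = re.compile(r"resid\s+(.+)", re.IGNORECASE)


def _resid_selection(topology: Topology, spec: str) -> tuple[int, ...] | None:
    m = _RESID_SPEC.fullmatch(spec.strip())
    if not m:
        return None
    wanted: set[int] = set()
    for part in m.group(1).replace(",", " ").split():
        lo, _, hi = part.partition("-")
        wanted.update(range(int(lo), int(hi or lo) + 1))
    return tuple(a.atom_id for a in topology.atoms if a.residue_id in wanted)


def resolve_groups(
    topology: Topology,
    receptor_spec: str,
    ligand_spec: str,
    ndx_path: str | Path | None = None,
) -> Topology:
    """Populate receptor/ligand groups from an ndx file or resid ranges.

    Specs are either group names in ``ndx_path`` (when given) or residue
    selections of the form ``"resid 1-120"`` / ``"resid 3"`` /
    ``"resid 1-5,9"``.
    """
    ndx: Mapping[str, tuple[int, ...]] = load_ndx(ndx_path) if ndx_path else {}

    def _resolve(spec: str) -> tuple[int, ...]:
        if spec in ndx:
            return ndx[spec]
        sel = _resid_selection(topology, spec)
        if sel:
            return sel
        if ndx:
            raise GroupLookupError(
                f"group {spec!r} not found; available: {sorted(ndx)}"
            )
        raise GroupLookupError(
            f"cannot resolve selection {spec!r} (expected ndx group name or 'resid A-B')"
        )

    return Topology(
        atoms=topology.atoms,
        receptor_group=_resolve(receptor_spec),
        ligand_group=_resolve(ligand_spec),
        temperature=topology.temperature,
        original_ids=topology.original_ids,
    )
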