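"""Multi-frame structure I/O and single-trajectory-protocol sub-frames.

Under the single-trajectory protocol (STP) the receptor and ligand
conformations are taken verbatim from the complex trajectory, so every
intramolecular energy term is identical in the bound and unbound states
and cancels exactly in the binding difference.  :func:`extract_group`
therefore only slices coordinates — it never re-minimizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyInputError, TrajectoryFormatError
from .topology import Topology

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0


@dataclass
class Frame:
    """One trajectory snapshot: coordinates in Angstrom plus optional box."""

    index: int
    time: float  # ps
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    box: np.ndarray | None = None  # (3,) box edge lengths, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryFormatError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise TrajectoryFormatError(f"non-finite coordinates in frame {self.index}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# readers


def _read_pdb_frames(path: Path) -> list[Frame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except (IndexError, ValueError) as exc:
            raise EmptyInputError(f"{path}: no frames found ({exc})") from exc
        frames = []
        for ts in u.trajectory:
            box = None
            if ts.dimensions is not None and ts.dimensions[:3].any():
                box = np.array(ts.dimensions[:3], dtype=float)
            frames.append(
                Frame(
                    index=len(frames),
                    time=float(getattr(ts, "time", 0.0) or 0.0),
                    coords=ts.positions.astype(float).copy(),
                    box=box,
                )
            )
    return frames


def _read_gro_frames(path: Path) -> list[Frame]:
    """Parse (possibly concatenated) GRO: title / natoms / atom lines / box,
    repeated per frame.  Coordinates converted nm -> Angstrom."""
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        title = lines[pos]
        try:
            natoms = int(lines[pos + 1].strip())
        except (IndexError, ValueError) as exc:
            raise TrajectoryFormatError(
                f"{path}: bad atom-count line at line {pos + 2}"
            ) from exc
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise TrajectoryFormatError(
                f"{path}: truncated frame {len(frames)} (expected {natoms} atoms)"
            )
        coords = np.empty((natoms, 3))
        for i, line in enumerate(atom_lines):
            # fixed columns: resid(5) resname(5) name(5) atomid(5) x y z (8.3 each)
            coords[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
        box_line = lines[pos + 2 + natoms].split()
        box = np.array([float(v) for v in box_line[:3]]) * NM_TO_ANGSTROM
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        frames.append(
            Frame(
                index=len(frames),
                time=time,
                coords=coords * NM_TO_ANGSTROM,
                box=box if box.any() else None,
            )
        )
        pos += 3 + natoms
    return frames


def read_frames(
    path: str | Path,
    format: str = "auto",
    frame_range: tuple[int, int | None, int] | None = None,
) -> list[Frame]:
    """Read a multi-MODEL PDB or concatenated GRO trajectory.

    ``frame_range`` is a ``(start, stop, step)`` slice over file order.
    All coordinates are returned in Angstrom; a changing atom count
    between frames is a format error.
    """
    path = Path(path)
    if format == "auto":
        format = "gro" if path.suffix.lower() == ".gro" else "pdb"
    if format == "pdb":
        frames = _read_pdb_frames(path)
    elif format == "gro":
        frames = _read_gro_frames(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")

    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    n0 = frames[0].n_atoms
    for f in frames:
        if f.n_atoms != n0:
            raise TrajectoryFormatError(
                f"{path}: atom count changed at frame {f.index} ({f.n_atoms} != {n0})"
            )
    if frame_range is not None:
        start, stop, step = frame_range
        frames = frames[slice(start, stop, step)]
        if not frames:
            raise EmptyInputError(f"{path}: frame_range selected no frames")
        for new_index, f in enumerate(frames):
            f.index = new_index
    return frames


def check_pbc_artifacts(frame: Frame, topology: Topology) -> bool:
    """Warn if any intra-solute pair distance exceeds half the box edge.

    Periodic-boundary repair is assumed done upstream; this is only a
    heuristic tripwire for molecules split across the box.
    """
    if frame.box is None:
        return False
    d = frame.coords[:, None, :] - frame.coords[None, :, :]
    max_span = np.abs(d).max(axis=(0, 1))
    broken = bool((max_span > frame.box / 2.0).any())
    if broken:
        logger.warning(
            "frame %d: intra-solute span %s A exceeds half box %s A; "
            "possible unfixed periodic-boundary artifact",
            frame.index,
            np.round(max_span, 2),
            np.round(frame.box / 2.0, 2),
        )
    return broken


def extract_group(frame: Frame, topology: Topology, which: str) -> Frame:
    """STP sub-frame: identical coordinates of the selected atoms.

    ``which`` is ``complex`` (identity), ``receptor`` or ``ligand``.
    """
    if which == "complex":
        return frame
    if which not in ("receptor", "ligand"):
        raise ValueError(f"unknown group {which!r}")
    idx = topology.group_indices(which)
    return Frame(
        index=frame.index,
        time=frame.time,
        coords=frame.coords[idx],
        box=frame.box,
    )


# ---------------------------------------------------------------------------
# writers


def _pdb_atom_name(name: str) -> str:
    # PDB convention: names of <4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_pdb(
    path: str | Path,
    frames: Frame | Sequence[Frame],
    topology: Topology,
    bfactors: np.ndarray | None = None,
    occupancies: np.ndarray | None = None,
) -> None:
    """Write a (multi-MODEL) PDB; B-factors clamped to the column width."""
    if isinstance(frames, Frame):
        frames = [frames]
    n = topology.n_atoms
    b = np.zeros(n) if bfactors is None else np.asarray(bfactors, dtype=float)
    occ = np.ones(n) if occupancies is None else np.asarray(occupancies, dtype=float)
    clamped = np.clip(b, -999.99, 999.99)
    if (clamped != b).any():
        logger.warning("B-factor values clamped to [-999.99, 999.99] for PDB output")
    lines: list[str] = []
    multi = len(frames) > 1
    for frame in frames:
        if frame.n_atoms != n:
            raise TrajectoryFormatError("frame/topology atom count mismatch")
        if multi:
            lines.append(f"MODEL     {frame.index + 1:4d}")
        for a, xyz, bf, oc in zip(topology.atoms, frame.coords, clamped, occ):
            lines.append(
                f"ATOM  {a.atom_id:5d} {_pdb_atom_name(a.atom_name)} "
                f"{a.residue_name[:3]:>3s} A{a.residue_id:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{oc:6.2f}{bf:6.2f}"
            )
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gro(
    path: str | Path, frames: Frame | Sequence[Frame], topology: Topology
) -> None:
    """Write a (concatenated multi-frame) GRO file, Angstrom -> nm."""
    if isinstance(frames, Frame):
        frames = [frames]
    lines: list[str] = []
    for frame in frames:
        lines.append(f"pbsakit frame t= {frame.time:.3f}")
        lines.append(f"{topology.n_atoms:5d}")
        for a, xyz in zip(topology.atoms, frame.coords):
            x, y, z = xyz / NM_TO_ANGSTROM
            lines.append(
                f"{a.residue_id:5d}{a.residue_name:<5s}{a.atom_name:>5s}"
                f"{a.atom_id:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        box = frame.box if frame.box is not None else np.zeros(3)
        bx, by, bz = np.asarray(box) / NM_TO_ANGSTROM
        lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")
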