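"""Seeded toy-system generator and canonical analytic fixtures.

All test inputs are produced here: a deterministic generator places
non-overlapping "receptor" and "ligand" atoms with randomized charges,
Lennard-Jones parameters and PB radii in documented ranges, and jitters
them into a short multi-frame trajectory.  Canonical named fixtures with
closed-form expectations are also provided:

- ``born_ion``       one +1 e sphere of radius 2 A (Born solvation oracle)
- ``two_ion_dimer``  a +1/-1 ion pair 5 A apart (Coulomb/PB composition)
- ``lj_dimer``       two neutral identical LJ atoms (well-depth oracle)
- ``homo_dimer``     two mirror-image 3-atom molecules (symmetry checks)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .topology import AtomRecord, Topology, write_topology
from .trajectory import Frame, write_pdb


@dataclass
class ToySpec:
    """Generator settings; ranges are typical of organic/protein atoms."""

    n_receptor_atoms: int = 10
    n_ligand_atoms: int = 3
    box: float = 30.0  # A, cubic placement region
    charge_scale: float = 0.5  # |q| upper bound, e
    sigma_range: tuple[float, float] = (2.5, 3.5)  # A
    epsilon_range: tuple[float, float] = (0.05, 0.2)  # kcal/mol
    radius_range: tuple[float, float] = (1.2, 2.0)  # A
    min_separation: float = 2.5  # A between atom centres
    n_frames: int = 5
    jitter: float = 0.15  # A per-coordinate Gaussian frame noise
    seed: int = 0


def _place_atoms(rng: np.ndarray, spec: ToySpec) -> np.ndarray:
    """Rejection-sample non-overlapping positions in the box."""
    n = spec.n_receptor_atoms + spec.n_ligand_atoms
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n:
        attempts += 1
        if attempts > 20000:
            raise ValidationError(
                "cannot pack atoms: box too small for requested count/separation"
            )
        p = rng.uniform(0.0, spec.box, size=3)
        if len(coords) == spec.n_receptor_atoms:
            # start the ligand near the receptor surface so the two groups interact
            centre = np.mean(coords, axis=0)
            p = centre + rng.uniform(-0.35, 0.35, size=3) * spec.box
        if all(np.linalg.norm(p - c) >= spec.min_separation for c in coords):
            coords.append(p)
    return np.array(coords)


def generate_toy_system(spec: ToySpec | None = None) -> tuple[Topology, list[Frame]]:
    """Deterministic random receptor/ligand system plus jittered frames."""
    spec = spec or ToySpec()
    if spec.n_receptor_atoms < 1 or spec.n_ligand_atoms < 1:
        raise ValidationError("need at least one atom per group")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_receptor_atoms + spec.n_ligand_atoms
    base = _place_atoms(rng, spec)

    charges = rng.uniform(-spec.charge_scale, spec.charge_scale, size=n)
    sigma = rng.uniform(*spec.sigma_range, size=n)
    eps = rng.uniform(*spec.epsilon_range, size=n)
    radii = rng.uniform(*spec.radius_range, size=n)

    atoms = []
    for i in range(n):
        in_receptor = i < spec.n_receptor_atoms
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                atom_name=f"C{i + 1}",
                residue_id=(i // 5) + 1 if in_receptor else 1000 + (i - spec.n_receptor_atoms),
                residue_name="REC" if in_receptor else "LIG",
                charge=float(charges[i]),
                lj_c6=float(4.0 * eps[i] * sigma[i] ** 6),
                lj_c12=float(4.0 * eps[i] * sigma[i] ** 12),
                pb_radius=float(radii[i]),
            )
        )
    topology = Topology(
        atoms=atoms,
        receptor_group=tuple(range(1, spec.n_receptor_atoms + 1)),
        ligand_group=tuple(range(spec.n_receptor_atoms + 1, n + 1)),
    )
    frames = [
        Frame(
            index=k,
            time=float(k),
            coords=base + rng.normal(0.0, spec.jitter, size=(n, 3)),
            box=np.full(3, spec.box * 2.0),
        )
        for k in range(spec.n_frames)
    ]
    return topology, frames


def write_toy_files(
    topology: Topology, frames: list[Frame], directory: str | Path
) -> tuple[Path, Path]:
    """Emit the sidecar and multi-MODEL PDB for a generated system."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = directory / "system.top"
    traj = directory / "traj.pdb"
    write_topology(topology, sidecar)
    write_pdb(traj, frames, topology)
    return sidecar, traj


# ---------------------------------------------------------------------------
# canonical fixtures


def born_ion(charge: float = 1.0, radius: float = 2.0) -> tuple[Topology, Frame]:
    """Single charged sphere; closed-form Born solvation oracle."""
    top = Topology(
        atoms=[AtomRecord(1, "ION", 1, "ION", charge, 0.0, 0.0, radius)],
    )
    return top, Frame(index=0, time=0.0, coords=np.zeros((1, 3)))


def two_ion_dimer(separation: float = 5.0, radius: float = 2.0) -> tuple[Topology, Frame]:
    """+1/-1 ion pair as a minimal receptor/ligand complex."""
    top = Topology(
        atoms=[
            AtomRecord(1, "NA", 1, "REC", 1.0, 0.0, 0.0, radius),
            AtomRecord(2, "CL", 2, "LIG", -1.0, 0.0, 0.0, radius),
        ],
        receptor_group=(1,),
        ligand_group=(2,),
    )
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return top, Frame(index=0, time=0.0, coords=coords)


def lj_dimer(
    sigma: float = 2.0, epsilon: float = 0.5, separation: float | None = None
) -> tuple[Topology, Frame]:
    """Two neutral identical LJ atoms; default separation at the well minimum."""
    if separation is None:
        separation = 2.0 ** (1.0 / 6.0) * sigma
    c6 = 4.0 * epsilon * sigma**6
    c12 = 4.0 * epsilon * sigma**12
    top = Topology(
        atoms=[
            AtomRecord(1, "AR", 1, "REC", 0.0, c6, c12, sigma / 2.0),
            AtomRecord(2, "AR", 2, "LIG", 0.0, c6, c12, sigma / 2.0),
        ],
        receptor_group=(1,),
        ligand_group=(2,),
    )
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return top, Frame(index=0, time=0.0, coords=coords)


def homo_dimer(gap: float = 4.0) -> tuple[Topology, Frame]:
    """Two mirror-image 3-atom molecules; per-monomer sums must be equal."""
    monomer = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0]])
    other = monomer * np.array([-1.0, 1.0, 1.0]) + np.array([gap, 0.0, 0.0])
    charges = [0.3, -0.2, -0.1]
    atoms = []
    for m, (prefix, rid, rname) in enumerate(
        (("A", 1, "MOA"), ("B", 2, "MOB"))
    ):
        for i in range(3):
            atoms.append(
                AtomRecord(
                    atom_id=3 * m + i + 1,
                    atom_name=f"{prefix}{i + 1}",
                    residue_id=rid,
                    residue_name=rname,
                    charge=charges[i],
                    lj_c6=4.0 * 0.1 * 3.0**6,
                    lj_c12=4.0 * 0.1 * 3.0**12,
                    pb_radius=1.7,
                )
            )
    top = Topology(atoms=atoms, receptor_group=(1, 2, 3), ligand_group=(4, 5, 6))
    coords = np.vstack([monomer, other])
    return top, Frame(index=0, time=0.0, coords=coords)
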