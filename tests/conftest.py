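import numpy as np
import pytest

import pbsakit as pk
from pbsakit.toys import ToySpec, generate_toy_system, write_toy_files

#: Coarse-but-honest PB settings for desk-scale test systems.
FAST_PB = dict(grid_spacing=0.8, grid_margin=6.0)


@pytest.fixture(scope="session")
def toy_system():
    """Seeded 8+3 atom receptor/ligand system with 3 jittered frames."""
    return generate_toy_system(
        ToySpec(n_receptor_atoms=8, n_ligand_atoms=3, n_frames=3, seed=7)
    )


@pytest.fixture(scope="session")
def toy_files(toy_system, tmp_path_factory):
    top, frames = toy_system
    directory = tmp_path_factory.mktemp("toy")
    sidecar, traj = write_toy_files(top, frames, directory)
    return sidecar, traj


@pytest.fixture
def fast_pb():
    return pk.PBParams(**FAST_PB)


def random_pair_system(n_rec, n_lig, seed):
    """Random charged LJ system for brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n_rec + n_lig
    coords = rng.uniform(0, 12, size=(n, 3))
    # enforce minimal separation by rejection
    while True:
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        bad = np.argwhere(d < 1.5)
        if not len(bad):
            break
        coords[bad[0][0]] = rng.uniform(0, 12, size=3)
    atoms = [
        pk.AtomRecord(
            atom_id=i + 1,
            atom_name=f"X{i+1}",
            residue_id=1 if i < n_rec else 2,
            residue_name="REC" if i < n_rec else "LIG",
            charge=float(rng.uniform(-1, 1)),
            lj_c6=float(rng.uniform(0, 200.0)),
            lj_c12=float(rng.uniform(0, 5e4)),
            pb_radius=1.5,
        )
        for i in range(n)
    ]
    top = pk.Topology(
        atoms=atoms,
        receptor_group=tuple(range(1, n_rec + 1)),
        ligand_group=tuple(range(n_rec + 1, n + 1)),
    )
    return top, pk.Frame(index=0, time=0.0, coords=coords)
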