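"""Vacuum molecular-mechanics interaction energies between receptor and ligand.

Only inter-group (receptor x ligand) pairs contribute: under the
single-trajectory protocol every intra-group term is identical in the
bound and unbound states and cancels exactly, so the binding MM energy is

    dE_MM = dE_elec + dE_vdW,

with the Coulomb term optionally damped by a Debye-Hueckel factor
exp(-r_ij / lambda_D) to model ionic screening in salty media:

    dE_elec = sum_{i in rec} sum_{j in lig} k q_i q_j / (eps_in r_ij)
              * exp(-r_ij / lambda_D).

No distance cutoff is applied (end-state convention, desk-scale systems).
Each pair energy is split half/half between the two partner atoms to give
a conservative per-atom decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import constants
from .errors import SingularityError, ValidationError
from .topology import Topology
from .trajectory import Frame


@dataclass
class ScreeningParams:
    """Debye-Hueckel screening of the inter-group Coulomb energy.

    ``ion_species`` is a list of (concentration mol/L, integer charge)
    pairs for every mobile ion.  ``debye_length`` is derived from the
    species unless explicitly overridden.  ``epsilon_in`` enters the
    screened Coulomb formula; with screening disabled the plain Coulomb
    sum uses ``epsilon_in`` as well (default 1 = vacuum).
    """

    enabled: bool = False
    epsilon_in: float = 1.0
    epsilon_solvent: float = 80.0
    ion_species: Sequence[tuple[float, int]] = field(
        default_factory=lambda: [(0.15, 1), (0.15, -1)]
    )
    debye_length_override: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon_in < 1 or self.epsilon_solvent < 1:
            raise ValidationError("relative dielectric constants must be >= 1")
        for conc, _z in self.ion_species:
            if conc < 0:
                raise ValidationError("ion concentrations must be non-negative")

    def debye_length(self, temperature: float) -> float:
        if self.debye_length_override is not None:
            return self.debye_length_override
        return debye_length(self.ion_species, self.epsilon_solvent, temperature)


@dataclass
class PairEnergyResult:
    """Total pair energy (kcal/mol) plus its per-atom decomposition."""

    total: float
    per_atom: Mapping[int, float]  # atom_id -> kcal/mol


def debye_length(
    ion_species: Sequence[tuple[float, int]],
    epsilon_solvent: float,
    temperature: float,
) -> float:
    """Debye screening length in Angstrom.

    lambda_D = sqrt(eps_0 eps_r k_B T / sum_i n_i e^2 z_i^2), with the
    molar concentrations converted to number densities and the sum taken
    over all mobile ion species.  Zero ionic strength gives infinity
    (screening factor -> 1).
    """
    ionic = 0.0
    for conc, z in ion_species:
        if conc < 0:
            raise ValidationError("ion concentrations must be non-negative")
        n_per_m3 = conc * 1000.0 * constants.AVOGADRO
        ionic += n_per_m3 * z * z
    if ionic == 0.0:
        return math.inf
    num = (
        constants.VACUUM_PERMITTIVITY_SI
        * epsilon_solvent
        * constants.BOLTZMANN_SI
        * temperature
    )
    lam_m = math.sqrt(num / (ionic * constants.ELEMENTARY_CHARGE_SI**2))
    return lam_m * 1e10  # m -> Angstrom


def _pair_geometry(frame: Frame, topology: Topology):
    topology.require_groups()
    rec = topology.group_indices("receptor")
    lig = topology.group_indices("ligand")
    d = frame.coords[rec][:, None, :] - frame.coords[lig][None, :, :]
    r = np.sqrt((d * d).sum(axis=-1))
    if (r == 0.0).any():
        i, j = np.argwhere(r == 0.0)[0]
        raise SingularityError(
            f"coincident inter-group atoms: atom_id {rec[i] + 1} and {lig[j] + 1}"
        )
    return rec, lig, r


def _per_atom_halves(
    pair_energy: np.ndarray, rec: np.ndarray, lig: np.ndarray
) -> dict[int, float]:
    per = {}
    rec_share = 0.5 * pair_energy.sum(axis=1)
    lig_share = 0.5 * pair_energy.sum(axis=0)
    for idx, share in zip(rec, rec_share):
        per[int(idx) + 1] = float(share)
    for idx, share in zip(lig, lig_share):
        per[int(idx) + 1] = float(share)
    return per


def elec_energy(
    frame: Frame, topology: Topology, screening: ScreeningParams | None = None
) -> PairEnergyResult:
    """Inter-group Coulomb energy, optionally Debye-Hueckel screened."""
    screening = screening or ScreeningParams()
    rec, lig, r = _pair_geometry(frame, topology)
    q = topology.charges
    qq = q[rec][:, None] * q[lig][None, :]
    pair = constants.COULOMB_KCAL * qq / (screening.epsilon_in * r)
    if screening.enabled:
        lam = screening.debye_length(topology.temperature)
        if math.isfinite(lam):
            pair = pair * np.exp(-r / lam)
    return PairEnergyResult(total=float(pair.sum()), per_atom=_per_atom_halves(pair, rec, lig))


def _cross_c6_c12(topology: Topology, rec, lig, combining: str):
    c6, c12 = topology.c6, topology.c12
    if combining == "geometric":
        c6_ij = np.sqrt(c6[rec][:, None] * c6[lig][None, :])
        c12_ij = np.sqrt(c12[rec][:, None] * c12[lig][None, :])
        return c6_ij, c12_ij
    if combining == "lorentz_berthelot":
        # recover sigma/eps per atom, average sigma arithmetically
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.where(c6 > 0, (c12 / np.where(c6 > 0, c6, 1.0)) ** (1.0 / 6.0), 0.0)
            eps = np.where(c12 > 0, c6 * c6 / (4.0 * np.where(c12 > 0, c12, 1.0)), 0.0)
        s_ij = 0.5 * (sigma[rec][:, None] + sigma[lig][None, :])
        e_ij = np.sqrt(eps[rec][:, None] * eps[lig][None, :])
        return 4.0 * e_ij * s_ij**6, 4.0 * e_ij * s_ij**12
    raise ValueError(f"unknown combining rule {combining!r}")


def vdw_energy(
    frame: Frame, topology: Topology, combining: str = "geometric"
) -> PairEnergyResult:
    """Inter-group Lennard-Jones energy, C12/r^12 - C6/r^6 per pair."""
    rec, lig, r = _pair_geometry(frame, topology)
    c6_ij, c12_ij = _cross_c6_c12(topology, rec, lig, combining)
    pair = c12_ij / r**12 - c6_ij / r**6
    return PairEnergyResult(total=float(pair.sum()), per_atom=_per_atom_halves(pair, rec, lig))


def mm_terms(
    frame: Frame,
    topology: Topology,
    screening: ScreeningParams | None = None,
    combining: str = "geometric",
) -> tuple[PairEnergyResult, PairEnergyResult, float]:
    """(elec, vdw, e_mm) with e_mm = elec.total + vdw.total.

    The internal (bonded) term is identically zero under the
    single-trajectory protocol and is not computed.
    """
    elec = elec_energy(frame, topology, screening)
    vdw = vdw_energy(frame, topology, combining)
    return elec, vdw, elec.total + vdw.total
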