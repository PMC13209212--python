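"""Finite-difference linear Poisson-Boltzmann solver for polar solvation.

The linearized PBE is solved on a uniform Cartesian grid:

    div( eps(r) grad phi(r) ) - kappa_bar^2(r) phi(r) = -4 pi rho_f(r),

with the solute interior (union of atom spheres of radius ``pb_radius``)
at ``epsilon_in``, everything else at ``epsilon_solvent``, and the
modified screening factor kappa_bar^2 = eps_solvent / lambda_D^2 applied
only beyond a Stern layer (atom radius + ion probe).  Potentials are kept
in Gaussian-style units (charge in e, length in Angstrom) in which an
isolated point charge obeys phi = q / (eps r); energies convert to
kcal/mol through the Coulomb constant.

The polar solvation free energy is the reaction-field energy

    G_polar = 1/2 sum_i q_i [ phi_solv(r_i) - phi_ref(r_i) ] * k_coul,

where phi_ref is solved on the *identical* grid with a homogeneous
``epsilon_in`` dielectric and no salt, so the (spacing-dependent) grid
self-energy cancels exactly.  Binding differences additionally reuse one
grid geometry for complex, receptor and ligand so that discretization
artifacts cancel in the difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg

from . import constants
from .errors import ConvergenceError, GridSizeError, ValidationError
from .mm import debye_length
from .topology import Topology
from .trajectory import Frame, extract_group


@dataclass
class PBParams:
    """Grid, dielectric and solver settings for the LPBE.

    Defaults are field-standard continuum-electrostatics values: 0.5 A
    spacing, 10 A margin, solute dielectric 2, solvent dielectric 80,
    2.0 A ion-exclusion (Stern) probe.
    """

    epsilon_in: float = 2.0
    epsilon_solvent: float = 80.0
    ion_species: Sequence[tuple[float, int]] = field(default_factory=tuple)
    temperature: float = 298.15
    grid_spacing: float = 0.5
    grid_margin: float = 10.0
    probe_radius_ion: float = 2.0
    tolerance: float = 1e-6
    max_iterations: int = 5000
    boundary: str = "debye_huckel"  # per-atom sum; or "debye_huckel_monopole", "zero"
    max_nodes: int = 12_000_000
    debye_length_override: float | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValidationError("grid_spacing must be positive")
        if not (0.0 < self.tolerance < 1.0):
            raise ValidationError("tolerance must be in (0, 1)")
        if self.grid_margin < 5.0:
            raise ValidationError("grid_margin must be >= 5 A")
        if self.boundary not in ("zero", "debye_huckel", "debye_huckel_monopole"):
            raise ValidationError(f"unknown boundary condition {self.boundary!r}")

    def debye_length(self) -> float:
        if self.debye_length_override is not None:
            return self.debye_length_override
        return debye_length(self.ion_species, self.epsilon_solvent, self.temperature)


@dataclass
class PBGrid:
    """Coefficient maps and (after solving) the electrostatic potential."""

    dims: tuple[int, int, int]
    origin: np.ndarray  # (3,), Angstrom
    spacing: float
    eps_nodes: np.ndarray  # node-centered relative dielectric
    eps_edges: tuple[np.ndarray, np.ndarray, np.ndarray]  # edge-centered
    kappa2: np.ndarray  # node-centered modified screening, A^-2
    charge: np.ndarray  # node-centered source, e per node
    homogeneous: bool = False  # reference (eps_in everywhere, no salt)?
    monopole_center: np.ndarray | None = None  # |q|-weighted solute centroid
    solute_coords: np.ndarray | None = None
    solute_charges: np.ndarray | None = None
    potential: np.ndarray | None = None
    iterations_used: int = 0
    final_residual: float = math.nan

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.dims))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        )


@dataclass
class PolarResult:
    """Polar solvation energy (kcal/mol) with its per-atom decomposition."""

    g_polar: float
    per_atom: Mapping[int, float]
    iterations_used: int
    final_residual: float


# ---------------------------------------------------------------------------
# grid construction


def grid_geometry(
    coords: np.ndarray, radii: np.ndarray, params: PBParams
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Origin and node counts covering the solute plus margin."""
    lo = (coords - radii[:, None]).min(axis=0) - params.grid_margin
    hi = (coords + radii[:, None]).max(axis=0) + params.grid_margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / params.grid_spacing)) + 1 for k in range(3))
    return lo, dims


def _mark_spheres(
    out: np.ndarray,
    value: float,
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    h: float,
) -> None:
    """Set ``out`` nodes lying inside any sphere to ``value`` (in place)."""
    dims = out.shape
    for c, r in zip(coords, radii):
        lo_idx = np.maximum(np.floor((c - r - origin) / h).astype(int), 0)
        hi_idx = np.minimum(np.ceil((c + r - origin) / h).astype(int), np.array(dims) - 1)
        if (lo_idx > hi_idx).any():
            continue
        ax = [origin[k] + h * np.arange(lo_idx[k], hi_idx[k] + 1) - c[k] for k in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        sub = out[
            lo_idx[0] : hi_idx[0] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[2] : hi_idx[2] + 1,
        ]
        sub[d2 <= r * r] = value


def _signed_distance(
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    h: float,
    dims,
    pad: float = 3.0,
) -> np.ndarray:
    """min_i(|r - c_i| - R_i) near the solute surface; large positive elsewhere.

    Only a band of ``pad`` Angstrom around each sphere is evaluated: the
    exact value far from the surface is irrelevant (only the sign is
    used there) and every such node is solvent.
    """
    out = np.full(dims, 1e6)
    for c, r in zip(coords, radii):
        reach = r + pad
        lo_idx = np.maximum(np.floor((c - reach - origin) / h).astype(int), 0)
        hi_idx = np.minimum(
            np.ceil((c + reach - origin) / h).astype(int), np.array(dims) - 1
        )
        if (lo_idx > hi_idx).any():
            continue
        ax = [origin[k] + h * np.arange(lo_idx[k], hi_idx[k] + 1) - c[k] for k in range(3)]
        d = np.sqrt(
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        ) - r
        sub = out[
            lo_idx[0] : hi_idx[0] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[2] : hi_idx[2] + 1,
        ]
        np.minimum(sub, d, out=sub)
    return out


def _spread_charges(
    charges: np.ndarray, coords: np.ndarray, origin: np.ndarray, h: float, dims
) -> np.ndarray:
    """Trilinear distribution of point charges onto the 8 surrounding nodes."""
    out = np.zeros(dims)
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(out, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), charges * w)
    return out


def _interpolate(field_3d: np.ndarray, coords: np.ndarray, origin: np.ndarray, h: float):
    """Trilinear interpolation of a node field at atom positions."""
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    vals = np.zeros(len(coords))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                vals += w * field_3d[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return vals


def _fractional_edge_eps(da: np.ndarray, db: np.ndarray, eps_in: float, eps_out: float):
    """Harmonic edge dielectric from the solute fraction of each edge.

    The signed distance is linearly interpolated along the edge; the
    fraction f lying inside the solute weights the series (harmonic)
    average 1/eps = f/eps_in + (1-f)/eps_out, the 1-D exact result for a
    dielectric interface crossing the edge.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = da / (da - db)
    f = np.where(
        (da <= 0) & (db <= 0),
        1.0,
        np.where(
            (da > 0) & (db > 0),
            0.0,
            np.where(da <= 0, t_star, 1.0 - t_star),
        ),
    )
    f = np.clip(np.nan_to_num(f, nan=1.0), 0.0, 1.0)
    return 1.0 / (f / eps_in + (1.0 - f) / eps_out)


def _harmonic_edges(dist: np.ndarray, eps_in: float, eps_out: float):
    ex = _fractional_edge_eps(dist[:-1, :, :], dist[1:, :, :], eps_in, eps_out)
    ey = _fractional_edge_eps(dist[:, :-1, :], dist[:, 1:, :], eps_in, eps_out)
    ez = _fractional_edge_eps(dist[:, :, :-1], dist[:, :, 1:], eps_in, eps_out)
    return ex, ey, ez


def build_grid(
    frame: Frame,
    topology: Topology,
    params: PBParams,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
    homogeneous: bool = False,
) -> PBGrid:
    """Discretize dielectric, screening and charge maps for one solute.

    ``origin``/``dims`` may be supplied to reuse a common grid geometry
    (the binding difference computes complex, receptor and ligand on the
    complex's grid).  ``homogeneous=True`` builds the reference problem:
    ``epsilon_in`` everywhere and no mobile ions.
    """
    coords = frame.coords
    radii = topology.radii
    if (radii <= 0).any():
        raise ValidationError("all pb_radius values must be positive for PB")
    if origin is None or dims is None:
        origin, dims = grid_geometry(coords, radii, params)
    origin = np.asarray(origin, dtype=float)
    n_nodes = int(np.prod(dims))
    if n_nodes > params.max_nodes:
        raise GridSizeError(
            f"grid {dims} has {n_nodes} nodes > budget {params.max_nodes}; "
            "increase grid_spacing or lower grid_margin"
        )
    h = params.grid_spacing

    if homogeneous:
        eps = np.full(dims, params.epsilon_in)
        edges = (
            np.full((dims[0] - 1, dims[1], dims[2]), params.epsilon_in),
            np.full((dims[0], dims[1] - 1, dims[2]), params.epsilon_in),
            np.full((dims[0], dims[1], dims[2] - 1), params.epsilon_in),
        )
        kappa2 = np.zeros(dims)
    else:
        dist = _signed_distance(coords, radii, origin, h, dims, pad=2.0 * h + 1.0)
        eps = np.where(dist <= 0.0, params.epsilon_in, params.epsilon_solvent)
        edges = _harmonic_edges(dist, params.epsilon_in, params.epsilon_solvent)
        kappa2 = np.zeros(dims)
        lam = params.debye_length()
        if math.isfinite(lam):
            kappa2[:] = params.epsilon_solvent / lam**2
            _mark_spheres(kappa2, 0.0, coords, radii + params.probe_radius_ion, origin, h)

    charge = _spread_charges(topology.charges, coords, origin, h, dims)
    abs_q = np.abs(topology.charges)
    centre = (
        (abs_q[:, None] * coords).sum(axis=0) / abs_q.sum()
        if abs_q.sum() > 0
        else coords.mean(axis=0)
    )
    return PBGrid(
        dims=tuple(dims),
        origin=origin,
        spacing=h,
        eps_nodes=eps,
        eps_edges=edges,
        kappa2=kappa2,
        charge=charge,
        homogeneous=homogeneous,
        monopole_center=centre,
        solute_coords=coords,
        solute_charges=topology.charges,
    )


# ---------------------------------------------------------------------------
# solver


def _boundary_values(grid: PBGrid, params: PBParams) -> np.ndarray:
    """Dirichlet face potentials.

    ``debye_huckel`` (default) superposes one screened monopole per atom,
    q_i exp(-r_i/lambda) / (eps r_i) -- accurate enough at modest margins
    that boundary errors cancel between the solvated and reference solves
    and between complex and sub-system solves on a shared grid.
    ``debye_huckel_monopole`` lumps the net charge at the charge centroid;
    ``zero`` grounds the faces (test use).
    """
    dims = grid.dims
    phi_b = np.zeros(dims)
    if params.boundary == "zero":
        return phi_b
    eps_out = params.epsilon_in if grid.homogeneous else params.epsilon_solvent
    lam = math.inf if grid.homogeneous else params.debye_length()

    if params.boundary == "debye_huckel_monopole":
        total_q = grid.charge.sum()
        if total_q == 0.0:
            return phi_b
        sources = [(total_q, grid.monopole_center)]
    else:
        sources = [
            (q, c)
            for q, c in zip(grid.solute_charges, grid.solute_coords)
            if q != 0.0
        ]
        if not sources:
            return phi_b

    x, y, z = grid.axes()
    faces = (
        (0, slice(None), slice(None)),
        (-1, slice(None), slice(None)),
        (slice(None), 0, slice(None)),
        (slice(None), -1, slice(None)),
        (slice(None), slice(None), 0),
        (slice(None), slice(None), -1),
    )
    xg = np.broadcast_to(x[:, None, None], dims)
    yg = np.broadcast_to(y[None, :, None], dims)
    zg = np.broadcast_to(z[None, None, :], dims)
    for face in faces:
        fx, fy, fz = xg[face], yg[face], zg[face]
        acc = np.zeros_like(fx, dtype=float)
        for q, c in sources:
            rr = np.sqrt((fx - c[0]) ** 2 + (fy - c[1]) ** 2 + (fz - c[2]) ** 2)
            rr = np.maximum(rr, grid.spacing)
            term = q / (eps_out * rr)
            if math.isfinite(lam):
                term = term * np.exp(-rr / lam)
            acc += term
        phi_b[face] = acc
    return phi_b


def solve_lpbe(grid: PBGrid, params: PBParams) -> PBGrid:
    """Solve the 7-point discretization by preconditioned conjugate gradient.

    Unknowns are the interior nodes; face nodes carry Dirichlet values
    (zero or Debye-Hueckel monopole).  The operator is symmetric positive
    definite; Jacobi-preconditioned CG is deterministic for fixed inputs.
    """
    nx, ny, nz = grid.dims
    h = grid.spacing
    n = grid.n_nodes
    lin = np.arange(n).reshape(grid.dims)

    boundary = np.zeros(grid.dims, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    unknown = ~boundary
    unk_index = -np.ones(n, dtype=np.int64)
    unk_index[unknown.ravel()] = np.arange(int(unknown.sum()))
    nu = int(unknown.sum())

    phi_b = _boundary_values(grid, params)

    diag = (grid.kappa2 * h * h)[unknown].astype(float)
    rhs = (4.0 * math.pi / h) * grid.charge[unknown].astype(float)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag_flat = np.zeros(nu)
    diag_flat += diag
    rhs_flat = rhs

    ex, ey, ez = grid.eps_edges
    edge_sets = (
        (lin[:-1, :, :], lin[1:, :, :], ex),
        (lin[:, :-1, :], lin[:, 1:, :], ey),
        (lin[:, :, :-1], lin[:, :, 1:], ez),
    )
    unknown_flat = unknown.ravel()
    phi_b_flat = phi_b.ravel()
    for a, b, w in edge_sets:
        a = a.ravel()
        b = b.ravel()
        w = w.ravel().astype(float)
        ua = unknown_flat[a]
        ub = unknown_flat[b]
        both = ua & ub
        ia, ib, wab = unk_index[a[both]], unk_index[b[both]], w[both]
        rows.append(ia)
        cols.append(ib)
        vals.append(-wab)
        rows.append(ib)
        cols.append(ia)
        vals.append(-wab)
        np.add.at(diag_flat, ia, wab)
        np.add.at(diag_flat, ib, wab)
        # unknown-boundary edges fold the Dirichlet value into the RHS
        a_only = ua & ~ub
        ia = unk_index[a[a_only]]
        np.add.at(diag_flat, ia, w[a_only])
        np.add.at(rhs_flat, ia, w[a_only] * phi_b_flat[b[a_only]])
        b_only = ub & ~ua
        ib = unk_index[b[b_only]]
        np.add.at(diag_flat, ib, w[b_only])
        np.add.at(rhs_flat, ib, w[b_only] * phi_b_flat[a[b_only]])

    rows.append(np.arange(nu))
    cols.append(np.arange(nu))
    vals.append(diag_flat)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nu, nu),
    ).tocsr()

    from scipy.sparse import diags as sp_diags

    M = sp_diags(1.0 / diag_flat)
    b_norm = float(np.linalg.norm(rhs_flat))
    history: list[float] = []
    if b_norm == 0.0:
        x = np.zeros(nu)
        info = 0
    else:
        def _track(xk):
            history.append(float(np.linalg.norm(rhs_flat - A @ xk)) / b_norm)

        x, info = cg(
            A,
            rhs_flat,
            rtol=params.tolerance,
            atol=0.0,
            maxiter=params.max_iterations,
            M=M,
            callback=_track,
        )
    residual = (
        float(np.linalg.norm(rhs_flat - A @ x)) / b_norm if b_norm else 0.0
    )
    if info != 0:
        raise ConvergenceError(
            f"LPBE solve did not reach rtol={params.tolerance} in "
            f"{params.max_iterations} iterations (residual {residual:.3e})",
            residual_history=history,
        )
    phi = phi_b.copy()
    phi[unknown] = x
    grid.potential = phi
    grid.iterations_used = len(history)
    grid.final_residual = residual
    return grid


# ---------------------------------------------------------------------------
# solvation energies


def polar_solvation(
    frame: Frame,
    topology: Topology,
    params: PBParams,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
) -> PolarResult:
    """Reaction-field polar solvation energy of one solute.

    Two solves on the identical grid: the solvated problem (dielectric
    contrast + salt) and the homogeneous reference; the per-atom energy is
    1/2 q_i [phi_solv - phi_ref](r_i), which removes the grid self-energy.
    """
    solv = solve_lpbe(build_grid(frame, topology, params, origin, dims), params)
    ref = solve_lpbe(
        build_grid(frame, topology, params, solv.origin, solv.dims, homogeneous=True),
        params,
    )
    dphi = _interpolate(
        solv.potential - ref.potential, frame.coords, solv.origin, solv.spacing
    )
    q = topology.charges
    per_atom_vals = 0.5 * constants.COULOMB_KCAL * q * dphi
    per_atom = {a.atom_id: float(v) for a, v in zip(topology.atoms, per_atom_vals)}
    return PolarResult(
        g_polar=float(per_atom_vals.sum()),
        per_atom=per_atom,
        iterations_used=solv.iterations_used + ref.iterations_used,
        final_residual=max(solv.final_residual, ref.final_residual),
    )


def binding_polar(
    frame: Frame, topology: Topology, params: PBParams
) -> tuple[float, dict[int, float]]:
    """ddG_polar = G(complex) - G(receptor) - G(ligand), one shared grid.

    All three solves use the complex's grid geometry so discretization
    artifacts cancel; per-atom values are differenced on complex atom ids.
    """
    topology.require_groups()
    origin, dims = grid_geometry(frame.coords, topology.radii, params)

    res_complex = polar_solvation(frame, topology, params, origin, dims)
    per_atom = {aid: float(v) for aid, v in res_complex.per_atom.items()}
    total = res_complex.g_polar
    for which in ("receptor", "ligand"):
        ids = topology.group_indices(which) + 1
        sub_top = topology.subset(ids)
        sub_frame = extract_group(frame, topology, which)
        res = polar_solvation(sub_frame, sub_top, params, origin, dims)
        total -= res.g_polar
        for new_id, orig_id in zip(
            (a.atom_id for a in sub_top.atoms), sub_top.original_ids
        ):
            per_atom[orig_id] -= res.per_atom[new_id]
    return total, per_atom


# ---------------------------------------------------------------------------
# debug export


def write_dx(grid: PBGrid, field_name: str, path: str | Path) -> None:
    """Dump a node field (eps_nodes, kappa2, charge, potential) as OpenDX."""
    data = getattr(grid, field_name)
    if data is None:
        raise ValidationError(f"grid field {field_name!r} is not populated")
    nx, ny, nz = grid.dims
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing:.6f} 0.0 0.0",
        f"delta 0.0 {grid.spacing:.6f} 0.0",
        f"delta 0.0 0.0 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_nodes} data follows",
    ]
    flat = data.ravel()
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")
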