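import math

import numpy as np
import pytest

import pbsakit as pk
from pbsakit.errors import GridSizeError
from pbsakit.pb import build_grid, grid_geometry, solve_lpbe
from pbsakit.topology import AtomRecord, Topology
from pbsakit.trajectory import Frame

BORN_CLOSED_FORM = -(166.03 / 2.0) * (1.0 - 1.0 / 80.0)  # q=1e, a=2A, eps 1->80


def born_params(spacing, **kw):
    return pk.PBParams(
        epsilon_in=1.0, epsilon_solvent=80.0, grid_spacing=spacing, grid_margin=8.0, **kw
    )


class TestGrid:
    def test_charge_map_conserves_total_charge(self, toy_system):
        top, frames = toy_system
        grid = build_grid(frames[0], top, pk.PBParams(grid_spacing=1.0, grid_margin=6.0))
        assert grid.charge.sum() == pytest.approx(top.charges.sum(), abs=1e-9)

    def test_dielectric_region_assignment(self):
        top, frame = pk.born_ion(radius=2.0)
        grid = build_grid(frame, top, born_params(0.5))
        centre_idx = tuple(
            int(round((0.0 - grid.origin[k]) / grid.spacing)) for k in range(3)
        )
        assert grid.eps_nodes[centre_idx] == 1.0
        assert grid.eps_nodes[0, 0, 0] == 80.0
        assert grid.eps_nodes.min() >= 1.0 and grid.eps_nodes.max() <= 80.0

    def test_no_salt_means_zero_screening_map(self):
        top, frame = pk.born_ion()
        grid = build_grid(frame, top, born_params(0.6))
        assert not grid.kappa2.any()

    def test_stern_layer_excludes_ions(self):
        top, frame = pk.born_ion(radius=2.0)
        params = born_params(0.5, ion_species=[(0.15, 1), (0.15, -1)])
        grid = build_grid(frame, top, params)
        centre_idx = tuple(
            int(round((0.0 - grid.origin[k]) / grid.spacing)) for k in range(3)
        )
        assert grid.kappa2[centre_idx] == 0.0  # inside solute + Stern layer
        assert grid.kappa2[0, 0, 0] > 0.0

    def test_node_budget_enforced(self):
        top, frame = pk.born_ion()
        with pytest.raises(GridSizeError, match="spacing"):
            build_grid(frame, top, born_params(0.5, max_nodes=1000))


class TestSolver:
    def test_zero_charge_gives_zero_potential(self):
        top, frame = pk.born_ion(charge=0.0)
        params = born_params(0.8)
        grid = solve_lpbe(build_grid(frame, top, params), params)
        assert not grid.potential.any()

    def test_point_charge_matches_coulomb_potential(self):
        # uniform dielectric: tiny atom so the medium is effectively homogeneous
        top = Topology(atoms=[AtomRecord(1, "Q", 1, "ION", 1.0, 0.0, 0.0, 0.3)])
        frame = Frame(0, 0.0, np.zeros((1, 3)))
        params = pk.PBParams(
            epsilon_in=2.0, epsilon_solvent=2.0, grid_spacing=0.5, grid_margin=10.0
        )
        grid = solve_lpbe(build_grid(frame, top, params), params)
        x = grid.origin[0] + grid.spacing * np.arange(grid.dims[0])
        ic = int(np.abs(x).argmin())
        for r_target in (2.5, 4.0, 6.0):  # all >= 5 spacings from the charge
            i = int(np.argmin(np.abs(x - r_target)))
            exact = 1.0 / (2.0 * x[i])
            assert grid.potential[i, ic, ic] == pytest.approx(exact, rel=0.03)

    def test_point_charge_matches_yukawa_potential(self):
        top = Topology(atoms=[AtomRecord(1, "Q", 1, "ION", 1.0, 0.0, 0.0, 0.3)])
        frame = Frame(0, 0.0, np.zeros((1, 3)))
        lam = 8.0
        params = pk.PBParams(
            epsilon_in=2.0,
            epsilon_solvent=2.0,
            grid_spacing=0.5,
            grid_margin=10.0,
            probe_radius_ion=0.0,
            ion_species=[(0.1, 1), (0.1, -1)],
            debye_length_override=lam,
        )
        grid = solve_lpbe(build_grid(frame, top, params), params)
        x = grid.origin[0] + grid.spacing * np.arange(grid.dims[0])
        ic = int(np.abs(x).argmin())
        for r_target in (2.5, 4.0, 6.0):
            i = int(np.argmin(np.abs(x - r_target)))
            exact = math.exp(-x[i] / lam) / (2.0 * x[i])
            assert grid.potential[i, ic, ic] == pytest.approx(exact, rel=0.05)

    def test_solver_reports_residual_below_tolerance(self):
        top, frame = pk.born_ion()
        params = born_params(0.8)
        grid = solve_lpbe(build_grid(frame, top, params), params)
        assert grid.final_residual <= params.tolerance
        assert grid.iterations_used > 0


class TestPolarSolvation:
    def test_born_ion_against_closed_form(self):
        top, frame = pk.born_ion(charge=1.0, radius=2.0)
        res = pk.polar_solvation(frame, top, born_params(0.6))
        assert res.g_polar == pytest.approx(BORN_CLOSED_FORM, rel=0.02)

    def test_grid_refinement_improves_monotonically(self):
        top, frame = pk.born_ion()
        errors = []
        for h in (1.0, 0.8, 0.6):
            res = pk.polar_solvation(frame, top, born_params(h))
            errors.append(abs(res.g_polar - BORN_CLOSED_FORM))
        assert errors[0] > errors[1] > errors[2]

    def test_no_dielectric_contrast_gives_exact_zero(self):
        top, frame = pk.born_ion()
        params = pk.PBParams(
            epsilon_in=2.0, epsilon_solvent=2.0, grid_spacing=0.9, grid_margin=6.0
        )
        res = pk.polar_solvation(frame, top, params)
        assert res.g_polar == pytest.approx(0.0, abs=1e-8)

    def test_per_atom_sums_to_total(self, toy_system, fast_pb):
        top, frames = toy_system
        res = pk.polar_solvation(frames[0], top, fast_pb)
        assert sum(res.per_atom.values()) == pytest.approx(res.g_polar, rel=1e-9)

    def test_homo_dimer_monomers_get_equal_shares(self):
        top, frame = pk.homo_dimer()
        res = pk.polar_solvation(frame, top, pk.PBParams(grid_spacing=0.6, grid_margin=8.0))
        a = sum(res.per_atom[i] for i in (1, 2, 3))
        b = sum(res.per_atom[i] for i in (4, 5, 6))
        assert a == pytest.approx(b, rel=0.02)


class TestBindingPolar:
    def test_two_ion_composition_oracle(self, fast_pb):
        """The binding difference equals three independent single-species
        solvation runs combined on the shared complex grid."""
        top, frame = pk.two_ion_dimer(separation=5.0)
        delta, per_atom = pk.binding_polar(frame, top, fast_pb)
        origin, dims = grid_geometry(frame.coords, top.radii, fast_pb)
        g_complex = pk.polar_solvation(frame, top, fast_pb, origin, dims).g_polar
        parts = []
        for which in ("receptor", "ligand"):
            sub_top = top.subset(top.group_indices(which) + 1)
            sub_frame = pk.extract_group(frame, top, which)
            parts.append(
                pk.polar_solvation(sub_frame, sub_top, fast_pb, origin, dims).g_polar
            )
        assert delta == pytest.approx(g_complex - parts[0] - parts[1], rel=1e-9)
        assert sum(per_atom.values()) == pytest.approx(delta, rel=1e-6)

    def test_all_charges_zero_gives_zero(self, fast_pb):
        top, frame = pk.lj_dimer()
        delta, _ = pk.binding_polar(frame, top, fast_pb)
        assert delta == pytest.approx(0.0, abs=1e-8)

    def test_distant_ion_pair_matches_continuum_limit(self):
        """At large separation ddG_polar approaches the screened-interaction
        form 332 (1/eps_s - 1/eps_in) q1 q2 / r, decaying to 0 as r -> inf."""
        params = pk.PBParams(
            epsilon_in=1.0, epsilon_solvent=80.0, grid_spacing=1.2, grid_margin=6.0
        )
        for sep in (20.0, 30.0):
            top, frame = pk.two_ion_dimer(separation=sep)
            delta, _ = pk.binding_polar(frame, top, params)
            analytic = 332.0637 * (1.0 / 80.0 - 1.0) * (-1.0) / sep
            assert delta == pytest.approx(analytic, rel=0.05)
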