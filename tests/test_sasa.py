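import numpy as np
import pytest

import pbsakit as pk
from pbsakit.sasa import golden_spiral_points
from pbsakit.trajectory import Frame


def single_atom_frame():
    return Frame(0, 0.0, np.zeros((1, 3)))


class TestShrakeRupley:
    def test_isolated_sphere_is_exact(self):
        areas = pk.shrake_rupley(
            single_atom_frame(), np.array([1.0]), pk.SasaParams(probe_radius=1.4)
        )
        assert areas[0] == pytest.approx(4.0 * np.pi * 2.4**2, rel=1e-12)

    def test_fully_buried_atom_has_zero_area(self):
        # small atom caged by 6 large overlapping spheres on the axes
        centres = np.vstack([np.zeros(3), 3.0 * np.eye(3), -3.0 * np.eye(3)])
        radii = np.array([1.0] + [4.0] * 6)
        areas = pk.shrake_rupley(Frame(0, 0.0, centres), radii)
        assert areas[0] == 0.0

    def test_partial_overlap_symmetry_and_occlusion(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.0, 1.0])
        areas = pk.shrake_rupley(Frame(0, 0.0, coords), radii)
        isolated = 4.0 * np.pi * 2.4**2
        # the fixed world-frame point set breaks exact mirror symmetry;
        # equality holds to the point-sampling resolution
        assert areas[0] == pytest.approx(areas[1], rel=0.01)
        assert areas[0] < isolated and areas[1] < isolated

    def test_isolated_sphere_exact_at_any_point_count(self):
        # unoccluded fraction is exactly 1, so the estimate carries no
        # sampling error at any resolution
        for n in (24, 120, 960):
            areas = pk.shrake_rupley(
                single_atom_frame(), np.array([1.5]), pk.SasaParams(n_sphere_points=n)
            )
            assert areas[0] == pytest.approx(4.0 * np.pi * 2.9**2, rel=1e-12)

    def test_point_count_convergence_for_occluded_pair(self):
        """The area estimate of a partially occluded sphere stabilizes as the
        point set grows."""
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.0, 1.0])
        estimates = [
            pk.shrake_rupley(
                Frame(0, 0.0, coords), radii, pk.SasaParams(n_sphere_points=n)
            )[0]
            for n in (120, 960, 7680)
        ]
        assert abs(estimates[0] - estimates[-1]) / estimates[-1] < 0.02
        assert abs(estimates[1] - estimates[-1]) / estimates[-1] < 0.005

    def test_rotation_invariance_below_two_tenths_percent(self, toy_system):
        top, frames = toy_system
        frame = frames[0]
        base = pk.shrake_rupley(frame, top.radii).sum()
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = Frame(0, 0.0, frame.coords @ rot.T + 3.0)
        total = pk.shrake_rupley(rotated, top.radii).sum()
        assert abs(total - base) / base < 0.002

    def test_complex_area_subadditive(self, toy_system):
        top, frames = toy_system
        frame = frames[0]
        radii = top.radii
        a_complex = pk.shrake_rupley(frame, radii).sum()
        total_parts = 0.0
        for which in ("receptor", "ligand"):
            idx = top.group_indices(which)
            sub = pk.extract_group(frame, top, which)
            total_parts += pk.shrake_rupley(sub, radii[idx]).sum()
        assert a_complex <= total_parts + 1e-9

    def test_golden_spiral_is_deterministic_unit_set(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, golden_spiral_points(960))

    def test_matches_independent_shrake_rupley_implementation(self, toy_system):
        """Cross-check against biotite's Shrake-Rupley (different point set)."""
        biotite_struc = pytest.importorskip("biotite.structure")
        top, frames = toy_system
        frame = frames[0]
        atoms = biotite_struc.AtomArray(top.n_atoms)
        atoms.coord = frame.coords
        atoms.element = np.array(["C"] * top.n_atoms)
        ours = pk.shrake_rupley(frame, top.radii, pk.SasaParams(n_sphere_points=1920))
        theirs = biotite_struc.sasa(
            atoms, probe_radius=1.4, vdw_radii=top.radii, point_number=1000
        )
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.02)


class TestNonpolarModel:
    def test_zero_area_returns_offset(self):
        total, _ = pk.nonpolar_energy(np.zeros(3))
        assert total == pytest.approx(0.92)

    def test_linear_form(self):
        params = pk.SasaParams(gamma=0.005, offset_b=0.92)
        total, per_atom = pk.nonpolar_energy(np.array([400.0, 600.0]), params)
        assert total == pytest.approx(0.005 * 1000.0 + 0.92)
        assert sum(per_atom.values()) == pytest.approx(total, rel=1e-12)

    def test_homogeneity_without_offset(self):
        params = pk.SasaParams(gamma=0.00542, offset_b=0.0)
        a = np.array([100.0, 250.0])
        t1, _ = pk.nonpolar_energy(a, params)
        t2, _ = pk.nonpolar_energy(2 * a, params)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)


class TestBindingNonpolar:
    def test_composition_oracle(self, toy_system):
        top, frames = toy_system
        frame = frames[0]
        params = pk.SasaParams(n_sphere_points=480)
        delta, per_atom = pk.binding_nonpolar(frame, top, params)
        pieces = {}
        for which in ("complex", "receptor", "ligand"):
            idx = top.group_indices(which)
            sub = pk.extract_group(frame, top, which)
            areas = pk.shrake_rupley(sub, top.radii[idx], params)
            pieces[which], _ = pk.nonpolar_energy(areas, params)
        assert delta == pytest.approx(
            pieces["complex"] - pieces["receptor"] - pieces["ligand"], rel=1e-12
        )
        assert sum(per_atom.values()) == pytest.approx(delta, abs=1e-9)

    def test_distant_ligand_gives_minus_offset(self):
        top, frame = pk.lj_dimer(separation=60.0)
        params = pk.SasaParams(offset_b=0.92)
        delta, _ = pk.binding_nonpolar(frame, top, params)
        assert delta == pytest.approx(-0.92, abs=1e-9)

    def test_cancel_mode_drops_offset(self):
        top, frame = pk.lj_dimer(separation=60.0)
        params = pk.SasaParams(offset_b=0.92, offset_mode="cancel")
        delta, per_atom = pk.binding_nonpolar(frame, top, params)
        assert delta == pytest.approx(0.0, abs=1e-9)
        assert sum(per_atom.values()) == pytest.approx(delta, abs=1e-9)

    def test_buried_interface_is_favourable(self, toy_system):
        top, frames = toy_system
        params = pk.SasaParams(offset_b=0.0)
        delta, _ = pk.binding_nonpolar(frames[0], top, params)
        assert delta <= 0.0  # occlusion only removes area, gamma > 0
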