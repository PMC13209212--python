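import numpy as np
import pytest

import pbsakit as pk
from pbsakit.alanine import ALANINE_CHARGES, mutate_to_alanine
from pbsakit.errors import ScopeError, UnsupportedResidueError


def peptide_complex():
    """Two-residue receptor (LEU-like + GLY) plus a one-atom ligand.

    The LEU side chain extends beyond CB (CG, HG, CD1, CD2) and must be
    removed on mutation; backbone, CB and its hydrogens stay.
    """
    names_res1 = [
        ("N", -0.4), ("H", 0.3), ("CA", 0.0), ("HA", 0.1),
        ("CB", -0.1), ("HB1", 0.05), ("HB2", 0.05),
        ("CG", -0.2), ("HG", 0.1), ("CD1", -0.05), ("CD2", -0.05),
        ("C", 0.6), ("O", -0.55),
    ]
    names_res2 = [("N", -0.4), ("CA", 0.0), ("C", 0.6), ("O", -0.55)]
    atoms = []
    coords = []
    rng = np.random.default_rng(1)
    aid = 1
    for rid, rname, names in ((1, "LEU", names_res1), (2, "GLY", names_res2)):
        for name, q in names:
            atoms.append(
                pk.AtomRecord(aid, name, rid, rname, q, 10.0, 1000.0, 1.6)
            )
            coords.append(rng.uniform(0, 8, 3))
            aid += 1
    atoms.append(pk.AtomRecord(aid, "LIG", 3, "MOL", 0.5, 10.0, 1000.0, 1.6))
    coords.append(np.array([12.0, 4.0, 4.0]))
    top = pk.Topology(
        atoms=atoms,
        receptor_group=tuple(range(1, aid)),
        ligand_group=(aid,),
    )
    return top, pk.Frame(0, 0.0, np.array(coords))


class TestMutateToAlanine:
    def test_truncates_to_backbone_plus_cb(self):
        top, frame = peptide_complex()
        new_frame, new_top = mutate_to_alanine(frame, top, 1)
        res1 = [a for a in new_top.atoms if a.residue_id == 1]
        assert {a.atom_name for a in res1} == {
            "N", "H", "CA", "HA", "CB", "HB1", "HB2", "C", "O"
        }
        assert all(a.residue_name == "ALA" for a in res1)

    def test_retained_coordinates_are_bitwise_identical(self):
        top, frame = peptide_complex()
        new_frame, new_top = mutate_to_alanine(frame, top, 1)
        for new_id, orig_id in zip(
            (a.atom_id for a in new_top.atoms), new_top.original_ids
        ):
            assert np.array_equal(
                new_frame.coords[new_id - 1], frame.coords[orig_id - 1]
            )

    def test_atom_count_bookkeeping(self):
        top, frame = peptide_complex()
        new_frame, new_top = mutate_to_alanine(frame, top, 1)
        # CG, HG, CD1, CD2 deleted
        assert new_top.n_atoms == top.n_atoms - 4
        assert new_frame.n_atoms == new_top.n_atoms
        assert len(new_top.ligand_group) == 1

    def test_charges_reassigned_from_template(self):
        top, frame = peptide_complex()
        _, new_top = mutate_to_alanine(frame, top, 1)
        by_name = {a.atom_name: a for a in new_top.atoms if a.residue_id == 1}
        for name in ("N", "CA", "CB", "C", "O", "HB1"):
            assert by_name[name].charge == ALANINE_CHARGES[name]

    @pytest.mark.parametrize(
        "rid,builder_patch",
        [(2, None)],  # GLY has no CB
    )
    def test_glycine_rejected(self, rid, builder_patch):
        top, frame = peptide_complex()
        with pytest.raises(UnsupportedResidueError, match="glycine"):
            mutate_to_alanine(frame, top, rid)

    def test_alanine_and_proline_rejected(self):
        top, frame = peptide_complex()
        atoms = [
            a if a.residue_id != 1
            else pk.AtomRecord(a.atom_id, a.atom_name, 1, "ALA", a.charge,
                               a.lj_c6, a.lj_c12, a.pb_radius)
            for a in top.atoms
        ]
        top_ala = pk.Topology(atoms=atoms, receptor_group=top.receptor_group,
                              ligand_group=top.ligand_group)
        with pytest.raises(UnsupportedResidueError, match="already"):
            mutate_to_alanine(frame, top_ala, 1)
        atoms = [
            a if a.residue_id != 1
            else pk.AtomRecord(a.atom_id, a.atom_name, 1, "PRO", a.charge,
                               a.lj_c6, a.lj_c12, a.pb_radius)
            for a in top.atoms
        ]
        top_pro = pk.Topology(atoms=atoms, receptor_group=top.receptor_group,
                              ligand_group=top.ligand_group)
        with pytest.raises(UnsupportedResidueError, match="proline"):
            mutate_to_alanine(frame, top_pro, 1)

    def test_ligand_residue_rejected(self):
        top, frame = peptide_complex()
        with pytest.raises(ScopeError):
            mutate_to_alanine(frame, top, 3)


FAST = dict(
    pb_params=None,
    sasa_params=None,
)


def fast_params():
    return dict(
        screening=pk.ScreeningParams(),
        pb_params=pk.PBParams(grid_spacing=1.0, grid_margin=6.0),
        sasa_params=pk.SasaParams(n_sphere_points=120),
    )


class TestAlanineScan:
    def test_empty_scan_returns_wild_type_only(self):
        top, frame = peptide_complex()
        wt, mutants = pk.alanine_scan([frame], top, [], **fast_params())
        assert mutants == {}
        assert wt.delta_g == pytest.approx(wt.mean["dh"])  # 1 frame: no entropy

    def test_failing_residue_does_not_abort_scan(self):
        top, frame = peptide_complex()
        wt, mutants = pk.alanine_scan([frame], top, [2, 1], **fast_params())
        assert mutants[2] is None  # GLY cannot be mutated
        assert mutants[1] is not None

    def test_two_residue_scan_equals_independent_single_scans(self):
        """Mutants are independent: a joint scan reproduces single scans."""
        top, frame = peptide_complex()
        params = fast_params()
        wt_joint, joint = pk.alanine_scan([frame], top, [1], **params)
        wt_single, single = pk.alanine_scan([frame], top, [1], **params)
        assert wt_joint.mean == wt_single.mean
        assert joint[1].mean == single[1].mean

    def test_wild_type_matches_standalone_run(self):
        top, frame = peptide_complex()
        params = fast_params()
        wt, _ = pk.alanine_scan([frame], top, [], **params)
        series = pk.compute_series(
            [frame], top, params["screening"], params["pb_params"],
            params["sasa_params"],
        )
        standalone = pk.summarize(series, top.temperature)
        assert wt.mean == standalone.mean
        assert wt.delta_g == standalone.delta_g

    def test_null_side_chain_leaves_mm_elec_unchanged(self):
        """Truncating a side chain whose deleted atoms carry no charge or LJ
        cannot change the inter-group MM terms."""
        top, frame = peptide_complex()
        # zero out the deleted atoms' charges and LJ (CG, HG, CD1, CD2)
        atoms = []
        for a in top.atoms:
            if a.residue_id == 1 and a.atom_name in ("CG", "HG", "CD1", "CD2"):
                atoms.append(
                    pk.AtomRecord(a.atom_id, a.atom_name, 1, a.residue_name,
                                  0.0, 0.0, 0.0, a.pb_radius)
                )
            else:
                atoms.append(a)
        top0 = pk.Topology(atoms=atoms, receptor_group=top.receptor_group,
                           ligand_group=top.ligand_group)
        before = pk.elec_energy(frame, top0).total
        new_frame, new_top = mutate_to_alanine(frame, top0, 1)
        # keep original charges on retained atoms for a pure deletion test
        kept = [
            pk.AtomRecord(a.atom_id, a.atom_name, a.residue_id, a.residue_name,
                          top0.atoms[orig - 1].charge, a.lj_c6, a.lj_c12,
                          a.pb_radius)
            for a, orig in zip(new_top.atoms, new_top.original_ids)
        ]
        new_top2 = pk.Topology(atoms=kept, receptor_group=new_top.receptor_group,
                               ligand_group=new_top.ligand_group)
        after = pk.elec_energy(new_frame, new_top2).total
        assert after == pytest.approx(before, rel=1e-12)
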