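"""Binding-site selection, Kabsch superposition and chain correspondence."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_rotation
from poselens.datamodel import Atom, Chain, ComplexRecord, ProteinStructure, Residue
from poselens.fixtures import FixtureSpec, make_helix, make_toy_complex, perturb_pose
from poselens.pocket_align import (
    CorrespondenceError,
    DegenerateAlignmentError,
    EmptySiteError,
    align_to_pocket,
    build_correspondence,
    kabsch,
    select_binding_site,
)
from poselens.pose_metrics import ligand_rmsd


def _single_atom_protein(positions: dict[tuple, np.ndarray]) -> ProteinStructure:
    residues = []
    for (num,), xyz in positions.items():
        key = ("A", num, "")
        residues.append(Residue("GLY", key, [Atom("CA", "C", xyz, key)]))
    return ProteinStructure([Chain("A", residues)])


class TestSelectBindingSite:
    def test_boundary_inclusive_at_cutoff(self):
        from rdkit import Chem
        from poselens.datamodel import LigandPose

        methane = LigandPose(
            "M", Chem.MolFromSmiles("C"), np.zeros((1, 3)), "C", (0,)
        )
        prot = _single_atom_protein({
            (1,): np.array([9.9, 0.0, 0.0]),
            (2,): np.array([10.0, 0.0, 0.0]),
            (3,): np.array([10.1, 0.0, 0.0]),
        })
        rec = ComplexRecord("t", prot, [methane], "M")
        site = select_binding_site(rec, cutoff=10.0)
        nums = {k[1] for k in site.residue_keys}
        assert nums == {1, 2}  # <= is inclusive; 10.1 A is out

    def test_matches_brute_force_scan(self, multi_record):
        site = select_binding_site(multi_record, cutoff=10.0)
        lig_xyz = multi_record.ligand_heavy_coords()
        expected = set()
        for res in multi_record.protein.iter_residues():
            for atom in res.heavy_atoms():
                if any(np.linalg.norm(atom.coords - l) <= 10.0 for l in lig_xyz):
                    expected.add(res.key)
                    break
        assert site.residue_keys == frozenset(expected)

    def test_monotone_in_cutoff(self, multi_record):
        s6 = select_binding_site(multi_record, cutoff=6.0).residue_keys
        s10 = select_binding_site(multi_record, cutoff=10.0).residue_keys
        s14 = select_binding_site(multi_record, cutoff=14.0).residue_keys
        assert s6 <= s10 <= s14

    def test_empty_site_raises(self, toy_record):
        far = _single_atom_protein({(1,): np.array([500.0, 0, 0])})
        rec = ComplexRecord("t", far, [toy_record.ligands[0]], "LIG1")
        with pytest.raises(EmptySiteError):
            select_binding_site(rec, cutoff=10.0)


class TestKabsch:
    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        fixed = rng.uniform(0, 10, (8, 3))
        mobile = fixed - np.array([1.0, 2.0, 3.0])
        tf, rmsd = kabsch(fixed, mobile)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, [1.0, 2.0, 3.0], atol=1e-9)

    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 10, (6, 3))
        tf, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_known_rigid_motion_recovered(self):
        rng = np.random.default_rng(3)
        fixed = rng.uniform(-5, 5, (10, 3))
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        mobile = (fixed - t) @ R  # fixed = mobile @ R.T + t
        tf, rmsd = kabsch(fixed, mobile)
        assert rmsd < 1e-9
        np.testing.assert_allclose(tf.apply(mobile), fixed, atol=1e-8)

    def test_reflection_rejected(self):
        # a mirrored point set must NOT be fit to zero by an improper rotation
        rng = np.random.default_rng(4)
        fixed = rng.uniform(-5, 5, (10, 3))
        mirrored = fixed * np.array([-1.0, 1.0, 1.0])
        tf, rmsd = kabsch(fixed, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.5

    @pytest.mark.parametrize("pts", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_sets_raise(self, pts):
        with pytest.raises(DegenerateAlignmentError):
            kabsch(pts, pts + 1.0)


class TestCorrespondence:
    def test_identity_on_identical_complexes(self, toy_record):
        corr = build_correspondence(toy_record, toy_record)
        assert corr.chain_map == {"A": "A"}
        assert all(k == v for k, v in corr.residue_map.items())
        assert not corr.mismatched

    def test_homodimer_label_swap_recovered(self, toy_record):
        helix = toy_record.protein
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        second = helix.transformed(R, np.array([40.0, 0.0, 0.0]))
        # reference: chains A (near ligand) and B (far)
        chains_ref = [Chain("A", helix.chains[0].residues), second.chains[0]]

        def rekey(chain, cid):
            residues = []
            for res in chain.residues:
                key = (cid, res.key[1], res.key[2])
                atoms = [Atom(a.name, a.element, a.coords, key) for a in res.atoms]
                residues.append(Residue(res.name, key, atoms))
            return Chain(cid, residues)

        ref = ComplexRecord(
            "dimer",
            ProteinStructure([rekey(chains_ref[0], "A"), rekey(chains_ref[1], "B")]),
            [toy_record.ligands[0]],
            "LIG1",
        )
        # prediction: same coordinates, labels swapped
        pred = ComplexRecord(
            "dimer",
            ProteinStructure([rekey(chains_ref[1], "A"), rekey(chains_ref[0], "B")]),
            [toy_record.ligands[0]],
            "LIG1",
        )
        corr = build_correspondence(pred, ref)
        assert corr.chain_map == {"A": "B", "B": "A"}
        site = select_binding_site(ref)
        _, fit = align_to_pocket(pred, ref, site, corr)
        assert fit == pytest.approx(0.0, abs=1e-9)

    def test_unrelated_sequence_raises(self, toy_record):
        # a glycine-only chain shares no identity with poly-alanine above 30%
        rng = np.random.default_rng(6)
        residues = []
        for i in range(12):
            key = ("A", i + 1, "")
            xyz = rng.uniform(0, 20, 3)
            residues.append(Residue("TRP", key, [
                Atom("CA", "C", xyz, key), Atom("N", "N", xyz + [1.4, 0, 0], key),
                Atom("C", "C", xyz + [0, 1.4, 0], key),
            ]))
        pred = ComplexRecord(
            "t", ProteinStructure([Chain("A", residues)]), [toy_record.ligands[0]], "LIG1"
        )
        with pytest.raises(CorrespondenceError):
            build_correspondence(pred, toy_record)


class TestAlignToPocket:
    def test_rigid_motion_of_prediction_is_undone(self, toy_record):
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = toy_record.transformed(R, t)
        site = select_binding_site(toy_record)
        corr = build_correspondence(moved, toy_record)
        aligned, fit = align_to_pocket(moved, toy_record, site, corr)
        assert fit == pytest.approx(0.0, abs=1e-9)
        assert ligand_rmsd(aligned.ligands[0], toy_record.ligands[0])[0] < 1e-9

    def test_ligand_offset_survives_alignment(self, toy_record):
        # identical protein, ligand shifted 2 A: pocket fit 0, ligand RMSD 2
        shifted = ComplexRecord(
            toy_record.target_id,
            toy_record.protein,
            [perturb_pose(toy_record.ligands[0], translation=(2.0, 0.0, 0.0))],
            "LIG1",
        )
        rng = np.random.default_rng(8)
        R = random_rotation(rng)
        moved = shifted.transformed(R, np.array([5.0, -3.0, 11.0]))
        site = select_binding_site(toy_record)
        corr = build_correspondence(moved, toy_record)
        aligned, fit = align_to_pocket(moved, toy_record, site, corr)
        assert fit == pytest.approx(0.0, abs=1e-9)
        assert ligand_rmsd(aligned.ligands[0], toy_record.ligands[0])[0] == pytest.approx(
            2.0, abs=1e-6
        )

    def test_pocket_fit_equals_direct_kabsch_on_site_atoms(self, toy_record):
        # perturb 30% of pocket CA positions, then compare to a direct fit
        rng = np.random.default_rng(9)
        site = select_binding_site(toy_record)
        noisy_chains = []
        for ch in toy_record.protein.chains:
            residues = []
            for res in ch.residues:
                atoms = []
                for a in res.atoms:
                    xyz = a.coords.copy()
                    if res.key in site.residue_keys and rng.random() < 0.3:
                        xyz = xyz + rng.normal(0, 0.4, 3)
                    atoms.append(Atom(a.name, a.element, xyz, a.residue_key))
                residues.append(Residue(res.name, res.key, atoms))
            noisy_chains.append(Chain(ch.chain_id, residues))
        pred = ComplexRecord(
            toy_record.target_id,
            ProteinStructure(noisy_chains),
            toy_record.ligands,
            "LIG1",
        )
        corr = build_correspondence(pred, toy_record)
        _, fit = align_to_pocket(pred, toy_record, site, corr)

        fixed, mobile = [], []
        for key in site.residue_keys:
            rres = toy_record.protein.residue_by_key(key)
            pres = pred.protein.residue_by_key(key)
            for ra in rres.heavy_atoms():
                pa = pres.atom(ra.name)
                fixed.append(ra.coords)
                mobile.append(pa.coords)
        _, direct = kabsch(np.array(fixed), np.array(mobile))
        assert fit == pytest.approx(direct, abs=1e-12)

    def test_downstream_metrics_invariant_to_global_motion(self, toy_record):
        site = select_binding_site(toy_record)
        base = ComplexRecord(
            toy_record.target_id,
            toy_record.protein,
            [perturb_pose(toy_record.ligands[0], translation=(1.0, 1.0, 0.0))],
            "LIG1",
        )
        rmsds = []
        for seed in (10, 11):
            rng = np.random.default_rng(seed)
            moved = base.transformed(random_rotation(rng), rng.uniform(-50, 50, 3))
            corr = build_correspondence(moved, toy_record)
            aligned, _ = align_to_pocket(moved, toy_record, site, corr)
            rmsds.append(ligand_rmsd(aligned.ligands[0], toy_record.ligands[0])[0])
        assert rmsds[0] == pytest.approx(rmsds[1], abs=1e-9)
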