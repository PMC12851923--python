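"""Geometric interaction detection: constructed geometries, invariances
and threshold self-consistency."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from rdkit import Chem

from conftest import random_rotation
from poselens.datamodel import Atom, Chain, LigandPose, ProteinStructure, Residue
from poselens.fixtures import embed_ligand, perturb_pose
from poselens.plif import (
    InteractionConfig,
    complex_fingerprint,
    detect_interactions,
    fingerprint_histogram,
)


def _residue(name: str, atoms: dict[str, tuple[str, np.ndarray]], num: int = 1):
    key = ("A", num, "")
    return Residue(
        name, key, [Atom(n, el, xyz, key) for n, (el, xyz) in atoms.items()]
    )


def _protein(*residues) -> ProteinStructure:
    return ProteinStructure([Chain("A", list(residues))])


def _acetone_pose(offset=np.zeros(3)) -> LigandPose:
    """Acetone with the carbonyl O at ``offset``; an H-bond acceptor."""
    mol = Chem.MolFromSmiles("CC(=O)C")
    coords = np.array([
        [-1.3, 0.8, 0.0],  # C
        [0.0, 0.6, 0.0],   # C (carbonyl)
        [0.0, 0.0, 0.0],   # O at origin before offset (shifted below)
        [1.3, 0.8, 0.0],   # C
    ]) + offset
    return LigandPose("ACT", mol, coords, "CC(=O)C", (0, 1, 2, 3))


class TestHydrogenBonds:
    def test_backbone_nh_to_carbonyl_acceptor(self):
        # protein N-H donor at 2.9 A from the ligand carbonyl O, D-H...A 165 deg
        o_pos = np.array([0.0, 0.0, 0.0])
        n_pos = np.array([2.9, 0.0, 0.0])
        # H on the N, nearly on the N-O axis (angle ~165 deg)
        h_pos = n_pos + 1.0 * np.array([-np.cos(np.radians(15)), np.sin(np.radians(15)), 0])
        res = _residue("GLY", {
            "N": ("N", n_pos),
            "H": ("H", h_pos),
            "CA": ("C", n_pos + [1.0, 1.0, 0.0]),
            "C": ("C", n_pos + [2.0, 1.0, 0.0]),
            "O": ("O", n_pos + [2.5, 2.0, 0.0]),
        })
        inters = detect_interactions(_protein(res), _acetone_pose())
        types = {i.interaction_type for i in inters}
        assert "HBond-Acceptor" in types
        hb = next(i for i in inters if i.interaction_type == "HBond-Acceptor")
        assert hb.geometry["distance"] == pytest.approx(2.9, abs=1e-9)
        assert hb.geometry["dha_angle"] > 130.0

    def test_poor_angle_rejects_hbond_with_explicit_hydrogen(self):
        o_pos = np.array([0.0, 0.0, 0.0])
        n_pos = np.array([2.9, 0.0, 0.0])
        h_pos = n_pos + 1.0 * np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0])
        res = _residue("GLY", {
            "N": ("N", n_pos),
            "H": ("H", h_pos),
            "CA": ("C", n_pos + [1.0, 1.0, 0.0]),
        })
        inters = detect_interactions(_protein(res), _acetone_pose())
        assert "HBond-Acceptor" not in {i.interaction_type for i in inters}

    def test_ligand_donor_to_protein_acceptor(self):
        # ethanol O-H donating to a backbone carbonyl O at 3.0 A
        ethanol = embed_ligand("CCO", seed=1, ligand_id="ETH", role="primary")
        o_idx = next(
            a.GetIdx() for a in ethanol.mol.GetAtoms() if a.GetSymbol() == "O"
        )
        shift = np.array([3.0, 0.0, 0.0]) - ethanol.coords[o_idx]
        ethanol = replace(ethanol, coords=ethanol.coords + shift)
        res = _residue("ALA", {
            "N": ("N", [-2.0, 2.0, 0.0]),
            "CA": ("C", [-1.0, 1.5, 0.0]),
            "C": ("C", [-0.7, 0.5, 0.0]),
            "O": ("O", [0.0, 0.0, 0.0]),
            "CB": ("C", [-1.5, 2.5, 1.0]),
        })
        inters = detect_interactions(_protein(res), ethanol)
        assert "HBond-Donor" in {i.interaction_type for i in inters}


class TestOtherTypes:
    def test_remote_ligand_yields_empty_list(self, toy_record):
        lig = perturb_pose(toy_record.ligands[0], translation=(100.0, 0.0, 0.0))
        assert detect_interactions(toy_record.protein, lig) == []

    def test_parallel_stacked_benzene_on_phe(self, benzene_pose):
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring = {}
        for k, name in enumerate(ring_names):
            ang = np.radians(60 * k)
            ring[name] = ("C", np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]))
        ring["CB"] = ("C", np.array([2.8, 0.0, -0.5]))
        ring["CA"] = ("C", np.array([3.9, 0.8, 0.0]))
        ring["N"] = ("N", np.array([4.9, 0.0, 0.5]))
        ring["C"] = ("C", np.array([4.4, 2.0, 0.0]))
        ring["O"] = ("O", np.array([3.8, 3.0, 0.2]))
        res = _residue("PHE", ring)
        # place benzene parallel, 3.8 A above the PHE ring plane
        shift = np.array([0.0, 0.0, 3.8]) - benzene_pose.centroid()
        pts = benzene_pose.coords - benzene_pose.centroid()
        normal = np.linalg.svd(pts)[2][2]
        # rotate the ring normal onto z first
        v = np.cross(normal, [0, 0, 1.0])
        s, c = np.linalg.norm(v), float(np.dot(normal, [0, 0, 1.0]))
        if s > 1e-12:
            K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]) / s
            R = np.eye(3) + s * K + (1 - c) * (K @ K)
        else:
            R = np.eye(3)
        stacked = replace(benzene_pose, coords=pts @ R.T + [0.0, 0.0, 3.8])
        inters = detect_interactions(_protein(res), stacked)
        pi = [i for i in inters if i.interaction_type == "PiStacking"]
        assert len(pi) == 1
        assert pi[0].geometry["plane_angle"] <= 35.0

    def test_salt_bridge_between_ammonium_and_aspartate(self):
        mol = Chem.MolFromSmiles("C[NH3+]")
        lig = LigandPose(
            "AMM", mol, np.array([[1.5, 0.0, 0.0], [0.0, 0.0, 0.0]]), "C[NH3+]", (0, 1)
        )
        res = _residue("ASP", {
            "CB": ("C", [-4.5, 0.0, 0.0]),
            "CG": ("C", [-3.8, 0.0, 0.0]),
            "OD1": ("O", [-3.0, 0.0, 0.0]),
            "OD2": ("O", [-4.2, 1.1, 0.0]),
            "CA": ("C", [-5.5, 1.0, 0.0]),
            "N": ("N", [-6.5, 0.5, 0.0]),
            "C": ("C", [-5.9, 2.2, 0.0]),
            "O": ("O", [-7.0, 2.6, 0.0]),
        })
        inters = detect_interactions(_protein(res), lig)
        cationic = [i for i in inters if i.interaction_type == "Cationic"]
        assert len(cationic) == 1
        assert cationic[0].residue_name == "ASP"


class TestInvariantsAndHistogram:
    def test_detection_invariant_under_rigid_motion(self, toy_record):
        base = detect_interactions(toy_record.protein, toy_record.ligands[0])
        rng = np.random.default_rng(40)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = toy_record.transformed(R, t)
        after = detect_interactions(moved.protein, moved.ligands[0])
        assert [i.tuple_key for i in base] == [i.tuple_key for i in after]

    def test_tightening_thresholds_never_adds_interactions(self, multi_record):
        loose = InteractionConfig()
        tight = InteractionConfig(
            hbond_distance=3.0, hydrophobic_distance=4.0, ionic_distance=4.0,
            pi_stack_distance=4.5, pi_cation_distance=4.0, halogen_distance=3.0,
            metal_distance=2.4,
        )
        for lig in multi_record.ligands:
            n_loose = len(detect_interactions(multi_record.protein, lig, loose))
            n_tight = len(detect_interactions(multi_record.protein, lig, tight))
            assert n_tight <= n_loose

    def test_emitted_geometry_satisfies_own_thresholds(self, multi_record):
        cfg = InteractionConfig()
        limits = {
            "HBond-Donor": cfg.hbond_distance,
            "HBond-Acceptor": cfg.hbond_distance,
            "Hydrophobic": cfg.hydrophobic_distance,
            "Cationic": cfg.ionic_distance,
            "Anionic": cfg.ionic_distance,
            "PiStacking": cfg.pi_stack_distance,
            "PiCation": cfg.pi_cation_distance,
            "HalogenBond": cfg.halogen_distance,
            "MetalCoordination": cfg.metal_distance,
        }
        for lig in multi_record.ligands:
            for inter in detect_interactions(multi_record.protein, lig, cfg):
                assert inter.geometry["distance"] <= limits[inter.interaction_type]

    def test_site_restriction_matches_whole_protein_scan(self, multi_record):
        near = complex_fingerprint(multi_record.protein, multi_record.ligands)
        wide = complex_fingerprint(
            multi_record.protein, multi_record.ligands,
            InteractionConfig(site_cutoff=500.0),
        )
        assert near == wide

    def test_histogram_counts_and_order_invariance(self):
        from poselens.plif import Interaction

        a = Interaction("L", "ALA", "Hydrophobic")
        b = Interaction("L", "SER", "HBond-Donor")
        hist = fingerprint_histogram([a, a, a, b])
        assert hist.counts[("L", "ALA", "Hydrophobic")] == 3
        assert hist.counts[("L", "SER", "HBond-Donor")] == 1
        assert hist.total == 4
        assert fingerprint_histogram([b, a, a, a]) == hist

    def test_empty_interaction_list_gives_empty_histogram(self):
        hist = fingerprint_histogram([])
        assert hist.total == 0
        assert not hist
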