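"""Chemical and structural sanity checks for predicted poses.

A documented subset of the standard pose-busting checklist, yielding a
single boolean flag per ligand: the molecular graph sanitizes, bond
lengths and angles stay near template-idealized values, aromatic rings
are flat, and no heavy-atom pair — within the ligand, against the
protein, or between ligand fragments — overlaps beyond a van der Waals
clash tolerance. Force-field energy-ratio inspection is not part of the
default flag; externally computed flags can be imported instead when
exact parity with the external suite matters.

All tolerances are configurable and echoed into report provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial import cKDTree

from .datamodel import ComplexRecord, LigandPose

#: Bondi van der Waals radii (Å); fallback 1.7 for anything unlisted
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}
_DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class ValidityConfig:
    bond_length_tolerance: float = 0.25  # fractional deviation from ideal
    bond_angle_tolerance: float = 25.0  # degrees
    ring_flatness_max_dev: float = 0.25  # Å out-of-plane
    clash_tolerance: float = 0.5  # Å subtracted from the vdW-sum contact limit
    min_graph_separation: int = 4  # bonds; closer pairs skip the internal clash test

    def __post_init__(self) -> None:
        if not 0 < self.bond_length_tolerance < 1:
            raise ValueError("bond_length_tolerance must be in (0, 1)")
        if self.bond_angle_tolerance <= 0 or self.clash_tolerance < 0:
            raise ValueError("nonpositive tolerance")


@dataclass(frozen=True)
class ValidityReport:
    """Per-check outcomes; ``pb_valid`` is the conjunction of all checks."""

    sanitizes: bool
    bond_lengths_ok: bool
    bond_angles_ok: bool
    ring_flatness_ok: bool
    internal_clash_free: bool
    protein_clash_free: bool
    interligand_clash_free: bool
    reason: str = ""

    @property
    def pb_valid(self) -> bool:
        return (
            self.sanitizes
            and self.bond_lengths_ok
            and self.bond_angles_ok
            and self.ring_flatness_ok
            and self.internal_clash_free
            and self.protein_clash_free
            and self.interligand_clash_free
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["pb_valid"] = self.pb_valid
        return d


_FAILED_ALL = ValidityReport(*([False] * 7))


def _vdw(element: str) -> float:
    return VDW_RADII.get(element, _DEFAULT_VDW)


@lru_cache(maxsize=256)
def _ideal_geometry(template_smiles: str) -> Optional[Chem.Mol]:
    """Distance-geometry embedded template used as the ideal-value source."""
    mol = Chem.MolFromSmiles(template_smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 20260930
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return Chem.RemoveHs(mol)


def _conformer_coords(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )


def _bond_lengths(mol: Chem.Mol, coords: np.ndarray) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        out[(min(i, j), max(i, j))] = float(np.linalg.norm(coords[i] - coords[j]))
    return out


def _angle_triples(mol: Chem.Mol) -> list[tuple[int, int, int]]:
    triples = []
    for atom in mol.GetAtoms():
        nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        j = atom.GetIdx()
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = sorted((nbrs[a], nbrs[b]))
                triples.append((i, j, k))
    return triples


def _angle_deg(coords: np.ndarray, i: int, j: int, k: int) -> float:
    v1 = coords[i] - coords[j]
    v2 = coords[k] - coords[j]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ring_flat(coords: np.ndarray, max_dev: float) -> bool:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return float(np.abs(centred @ vt[2]).max()) <= max_dev


def _graph_distances(mol: Chem.Mol) -> np.ndarray:
    return Chem.GetDistanceMatrix(mol)


def check_ligand_geometry(
    ligand: LigandPose, cfg: ValidityConfig = ValidityConfig()
) -> dict[str, bool]:
    """Graph-sanitization, bond-length/angle, ring-flatness and internal
    clash checks for one pose; returns one boolean per check."""
    mol = Chem.Mol(ligand.mol)
    try:
        Chem.SanitizeMol(mol)
        sanitizes = True
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        sanitizes = False

    coords = ligand.coords
    ideal = _ideal_geometry(ligand.template_smiles)

    bond_lengths_ok = True
    bond_angles_ok = True
    if ideal is not None:
        # pose atom order mapped into template order for the comparison
        tmap = list(ligand.template_map)
        pose_in_template_order = coords[tmap]
        ideal_coords = _conformer_coords(ideal)
        obs = _bond_lengths(ideal, pose_in_template_order)
        ref = _bond_lengths(ideal, ideal_coords)
        for key, ideal_len in ref.items():
            if abs(obs[key] - ideal_len) > cfg.bond_length_tolerance * ideal_len:
                bond_lengths_ok = False
                break
        for i, j, k in _angle_triples(ideal):
            if abs(
                _angle_deg(pose_in_template_order, i, j, k)
                - _angle_deg(ideal_coords, i, j, k)
            ) > cfg.bond_angle_tolerance:
                bond_angles_ok = False
                break

    ring_flatness_ok = True
    for ring in ligand.mol.GetRingInfo().AtomRings():
        if all(ligand.mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            if not _ring_flat(coords[list(ring)], cfg.ring_flatness_max_dev):
                ring_flatness_ok = False
                break

    internal_clash_free = True
    n = ligand.n_heavy
    if n > 1:
        gdist = _graph_distances(ligand.mol)
        elements = [a.GetSymbol() for a in ligand.mol.GetAtoms()]
        for i in range(n):
            for j in range(i + 1, n):
                if gdist[i, j] < cfg.min_graph_separation:
                    continue
                limit = _vdw(elements[i]) + _vdw(elements[j]) - cfg.clash_tolerance
                if np.linalg.norm(coords[i] - coords[j]) < limit:
                    internal_clash_free = False
                    break
            if not internal_clash_free:
                break

    return {
        "sanitizes": sanitizes,
        "bond_lengths_ok": bond_lengths_ok,
        "bond_angles_ok": bond_angles_ok,
        "ring_flatness_ok": ring_flatness_ok,
        "internal_clash_free": internal_clash_free,
    }


def _min_vdw_gap(
    coords_a: np.ndarray, elements_a: Sequence[str],
    coords_b: np.ndarray, elements_b: Sequence[str],
    clash_tolerance: float,
) -> bool:
    """True when no cross pair is closer than (vdW sum − tolerance)."""
    if coords_a.size == 0 or coords_b.size == 0:
        return True
    tree = cKDTree(coords_b)
    max_limit = 2 * max(VDW_RADII.values())
    for i, xyz in enumerate(coords_a):
        for j in tree.query_ball_point(xyz, max_limit):
            limit = _vdw(elements_a[i]) + _vdw(elements_b[j]) - clash_tolerance
            if np.linalg.norm(xyz - coords_b[j]) < limit:
                return False
    return True


def has_interligand_clash(
    ligands: Sequence[LigandPose], cfg: ValidityConfig = ValidityConfig()
) -> bool:
    """Whether any two distinct fragments overlap beyond the vdW tolerance."""
    elems = [[a.GetSymbol() for a in lig.mol.GetAtoms()] for lig in ligands]
    for i in range(len(ligands)):
        for j in range(i + 1, len(ligands)):
            if not _min_vdw_gap(
                ligands[i].coords, elems[i], ligands[j].coords, elems[j],
                cfg.clash_tolerance,
            ):
                return True
    return False


def check_pose_validity(
    predicted: ComplexRecord, cfg: ValidityConfig = ValidityConfig()
) -> dict[str, ValidityReport]:
    """Full validity report per ligand of a predicted complex."""
    prot_xyz = predicted.protein.heavy_coords()
    prot_elems = [a.element for a in predicted.protein.iter_heavy_atoms()]
    lig_elems = [[a.GetSymbol() for a in lig.mol.GetAtoms()] for lig in predicted.ligands]
    reports: dict[str, ValidityReport] = {}
    for idx, lig in enumerate(predicted.ligands):
        geo = check_ligand_geometry(lig, cfg)
        protein_clash_free = _min_vdw_gap(
            lig.coords, lig_elems[idx], prot_xyz, prot_elems, cfg.clash_tolerance
        )
        inter_ok = all(
            _min_vdw_gap(
                lig.coords, lig_elems[idx],
                predicted.ligands[j].coords, lig_elems[j],
                cfg.clash_tolerance,
            )
            for j in range(len(predicted.ligands))
            if j != idx
        )
        reports[lig.ligand_id] = ValidityReport(
            sanitizes=geo["sanitizes"],
            bond_lengths_ok=geo["bond_lengths_ok"],
            bond_angles_ok=geo["bond_angles_ok"],
            ring_flatness_ok=geo["ring_flatness_ok"],
            internal_clash_free=geo["internal_clash_free"],
            protein_clash_free=protein_clash_free,
            interligand_clash_free=inter_ok,
        )
    return reports


def failed_report(reason: str) -> ValidityReport:
    """Report for a pose whose template never matched: every check false."""
    return ValidityReport(*([False] * 7), reason=reason)


def interligand_clash_rate(
    predictions: Sequence[ComplexRecord], cfg: ValidityConfig = ValidityConfig()
) -> float:
    """Fraction of multiligand targets with at least one ligand–ligand clash."""
    multi = [p for p in predictions if len(p.ligands) >= 2]
    if not multi:
        return 0.0
    clashing = sum(has_interligand_clash(p.ligands, cfg) for p in multi)
    return clashing / len(multi)
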