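"""Geometric protein–ligand interaction detection.

Interactions are detected from heavy-atom geometry with the residue- and
ligand-level typing conventions of standard fingerprinting tools: each
detected contact is a tuple ⟨ligand id, amino-acid type, interaction
type⟩, and at most one interaction of a given type is emitted per
(ligand, residue instance) pair — the closest-geometry instance — so a
fingerprint is a residue-level multiset, not an atom-pair count.

All thresholds are configurable through :class:`InteractionConfig` and
recorded in report provenance. Protonation is inferred from the graph:
donors are N/O bearing explicit or implicit hydrogens, acceptors are
uncharged-or-anionic N/O, and charge centres come from formal charges.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import LigandPose, ProteinStructure, Residue
from .plif_score import PlifHistogram

INTERACTION_TYPES = (
    "HBond-Donor",
    "HBond-Acceptor",
    "Hydrophobic",
    "Cationic",
    "Anionic",
    "PiStacking",
    "PiCation",
    "HalogenBond",
    "MetalCoordination",
)

_METALS = {"Li", "Na", "K", "Mg", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg"}

# per-residue side-chain donor / acceptor / charge / ring tables
_SC_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
}
_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_CATION_CENTRES = {"LYS": {"NZ"}, "ARG": {"CZ"}}
_ANION_CENTRES = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}


@dataclass(frozen=True)
class InteractionConfig:
    """Geometric thresholds (Å, degrees) for every interaction type."""

    hbond_distance: float = 3.5
    hbond_angle: float = 130.0  # D-H...A, applied only with an explicit H
    hydrophobic_distance: float = 4.5
    ionic_distance: float = 4.5
    pi_stack_distance: float = 5.5
    pi_stack_face_angle: float = 35.0
    pi_stack_edge_angles: tuple[float, float] = (50.0, 90.0)
    pi_cation_distance: float = 4.5
    halogen_distance: float = 3.5
    metal_distance: float = 2.8
    merge_hbond_directions: bool = False
    site_cutoff: float = 10.0  # residues farther than this are never scanned

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                if value <= 0:
                    raise ValueError(f"{name} must be positive")
        if not 0 < self.hbond_angle <= 180:
            raise ValueError("hbond_angle must be in (0, 180]")


@dataclass(frozen=True)
class Interaction:
    ligand_id: str
    residue_name: str
    interaction_type: str
    residue_key: tuple = ()
    geometry: dict = field(default_factory=dict, compare=False)

    @property
    def tuple_key(self) -> tuple[str, str, str]:
        return (self.ligand_id, self.residue_name, self.interaction_type)


# ---------------------------------------------------------------------------
# ligand atom typing (from the RDKit graph)
# ---------------------------------------------------------------------------

def _ligand_features(ligand: LigandPose) -> dict[str, list]:
    mol = ligand.mol
    feats: dict[str, list] = {
        "donor": [], "acceptor": [], "hydrophobic": [], "cation": [],
        "anion": [], "halogen": [], "metal": [], "rings": [],
    }
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        if sym in ("N", "O") and atom.GetTotalNumHs() > 0:
            feats["donor"].append(i)
        if sym in ("N", "O") and charge <= 0 and atom.GetTotalValence() < 4:
            feats["acceptor"].append(i)
        if sym in ("C", "S"):
            feats["hydrophobic"].append(i)
        if charge > 0:
            feats["cation"].append(i)
        if charge < 0:
            feats["anion"].append(i)
        if sym in ("Cl", "Br", "I"):
            feats["halogen"].append(i)
        if sym in _METALS:
            feats["metal"].append(i)
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            feats["rings"].append(tuple(ring))
    return feats


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring from its atom coordinates."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = abs(float(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _site_residues(
    protein: ProteinStructure, ligand: LigandPose, cutoff: float
) -> list[Residue]:
    tree = cKDTree(ligand.coords)
    out = []
    for res in protein.iter_residues():
        pts = np.array([a.coords for a in res.heavy_atoms()])
        if pts.size and np.any(tree.query(pts)[0] <= cutoff):
            out.append(res)
    return out


def _residue_hbond_partners(res: Residue) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(donor heavy atoms, acceptor heavy atoms) of one residue, by name."""
    donors: dict[str, np.ndarray] = {}
    acceptors: dict[str, np.ndarray] = {}
    for a in res.heavy_atoms():
        if a.name == "N" and res.name != "PRO":
            donors[a.name] = a.coords
        if a.name in ("O", "OXT"):
            acceptors[a.name] = a.coords
        if a.name in _SC_DONORS.get(res.name, ()):
            donors[a.name] = a.coords
        if a.name in _SC_ACCEPTORS.get(res.name, ()):
            acceptors[a.name] = a.coords
    return donors, acceptors


def detect_interactions(
    protein: ProteinStructure,
    ligand: LigandPose,
    cfg: InteractionConfig = InteractionConfig(),
) -> list[Interaction]:
    """Detect all protein–ligand interactions for one ligand pose.

    The scan is restricted to residues within ``cfg.site_cutoff`` of the
    ligand; since every geometric threshold is smaller than that cutoff
    the result is identical to a whole-protein scan.
    """
    feats = _ligand_features(ligand)
    xyz = ligand.coords
    found: dict[tuple, Interaction] = {}

    def emit(res: Residue, itype: str, distance: float, geometry: dict) -> None:
        if cfg.merge_hbond_directions and itype in ("HBond-Donor", "HBond-Acceptor"):
            itype = "HBond"
        key = (ligand.ligand_id, res.key, itype)
        prev = found.get(key)
        if prev is None or distance < prev.geometry["distance"]:
            found[key] = Interaction(
                ligand_id=ligand.ligand_id,
                residue_name=res.name,
                interaction_type=itype,
                residue_key=res.key,
                geometry={"distance": float(distance), **geometry},
            )

    lig_rings = [
        _ring_geometry(xyz[list(ring)]) for ring in feats["rings"]
    ]

    for res in _site_residues(protein, ligand, cfg.site_cutoff):
        res_heavy = res.heavy_atoms()
        donors, acceptors = _residue_hbond_partners(res)
        h_atoms = {a.name: a.coords for a in res.atoms if not a.is_heavy}

        # hydrogen bonds: ligand donor -> protein acceptor
        for li in feats["donor"]:
            for aname, axyz in acceptors.items():
                d = float(np.linalg.norm(xyz[li] - axyz))
                if d <= cfg.hbond_distance:
                    emit(res, "HBond-Donor", d, {"acceptor_atom": aname})
        # protein donor -> ligand acceptor (D-H...A angle if H present)
        for li in feats["acceptor"]:
            for dname, dxyz in donors.items():
                d = float(np.linalg.norm(xyz[li] - dxyz))
                if d > cfg.hbond_distance:
                    continue
                h_name = "H" if dname == "N" else f"H{dname[1:]}"
                hxyz = h_atoms.get(h_name)
                if hxyz is not None:
                    v1 = dxyz - hxyz
                    v2 = xyz[li] - hxyz
                    ang = float(np.degrees(np.arccos(np.clip(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1.0, 1.0))))
                    if ang < cfg.hbond_angle:
                        continue
                    emit(res, "HBond-Acceptor", d, {"donor_atom": dname, "dha_angle": ang})
                else:
                    emit(res, "HBond-Acceptor", d, {"donor_atom": dname})

        # hydrophobic: ligand C/S vs protein C/S
        prot_cs = np.array([a.coords for a in res_heavy if a.element in ("C", "S")])
        if prot_cs.size and feats["hydrophobic"]:
            dmat = np.linalg.norm(
                xyz[feats["hydrophobic"]][:, None, :] - prot_cs[None, :, :], axis=-1
            )
            dmin = float(dmat.min())
            if dmin <= cfg.hydrophobic_distance:
                emit(res, "Hydrophobic", dmin, {})

        # ionic pairs
        for li in feats["cation"]:
            for aname in _ANION_CENTRES.get(res.name, ()):
                atom = res.atom(aname)
                if atom is None:
                    continue
                d = float(np.linalg.norm(xyz[li] - atom.coords))
                if d <= cfg.ionic_distance:
                    emit(res, "Cationic", d, {"protein_atom": aname})
        for li in feats["anion"]:
            for cname in _CATION_CENTRES.get(res.name, ()):
                atom = res.atom(cname)
                if atom is None:
                    continue
                d = float(np.linalg.norm(xyz[li] - atom.coords))
                if d <= cfg.ionic_distance:
                    emit(res, "Anionic", d, {"protein_atom": cname})

        # aromatic ring geometry of the residue
        res_rings = []
        for ring_names in _RINGS.get(res.name, ()):
            pts = [res.atom(n) for n in ring_names]
            if all(p is not None for p in pts):
                res_rings.append(_ring_geometry(np.array([p.coords for p in pts])))

        for lc, ln in lig_rings:
            for rc, rn in res_rings:
                d = float(np.linalg.norm(lc - rc))
                if d > cfg.pi_stack_distance:
                    continue
                ang = _angle_deg(ln, rn)
                lo, hi = cfg.pi_stack_edge_angles
                if ang <= cfg.pi_stack_face_angle or lo <= ang <= hi:
                    emit(res, "PiStacking", d, {"plane_angle": ang})

        # pi-cation, both directions
        for lc, _ in lig_rings:
            for cname in _CATION_CENTRES.get(res.name, ()):
                atom = res.atom(cname)
                if atom is not None:
                    d = float(np.linalg.norm(lc - atom.coords))
                    if d <= cfg.pi_cation_distance:
                        emit(res, "PiCation", d, {"protein_atom": cname})
        for li in feats["cation"]:
            for rc, _ in res_rings:
                d = float(np.linalg.norm(xyz[li] - rc))
                if d <= cfg.pi_cation_distance:
                    emit(res, "PiCation", d, {"ligand_atom": int(li)})

        # halogen bonds: ligand X ... protein acceptor
        for li in feats["halogen"]:
            for aname, axyz in acceptors.items():
                d = float(np.linalg.norm(xyz[li] - axyz))
                if d <= cfg.halogen_distance:
                    emit(res, "HalogenBond", d, {"acceptor_atom": aname})

        # metal coordination: ligand metal ... protein N/O/S
        if feats["metal"]:
            for a in res_heavy:
                if a.element not in ("N", "O", "S"):
                    continue
                for li in feats["metal"]:
                    d = float(np.linalg.norm(xyz[li] - a.coords))
                    if d <= cfg.metal_distance:
                        emit(res, "MetalCoordination", d, {"protein_atom": a.name})

    return sorted(found.values(), key=lambda x: (x.residue_key, x.interaction_type))


def fingerprint_histogram(interactions: Iterable[Interaction]) -> PlifHistogram:
    """Count fingerprint tuples ⟨ligand id, residue type, interaction type⟩."""
    hist = PlifHistogram()
    for inter in interactions:
        hist.add(inter.tuple_key)
    return hist


def complex_fingerprint(
    protein: ProteinStructure,
    ligands: Iterable[LigandPose],
    cfg: InteractionConfig = InteractionConfig(),
    key_by: str = "ligand_id",
) -> PlifHistogram:
    """Pooled fingerprint histogram over every ligand of a complex.

    ``key_by="template"`` uses the canonical template SMILES as the
    ligand type in each tuple, making histograms comparable across
    predictions that order identical fragments differently.
    """
    from rdkit import Chem as _Chem

    hist = PlifHistogram()
    for lig in ligands:
        if key_by == "template":
            lig_key = _Chem.MolToSmiles(_Chem.MolFromSmiles(lig.template_smiles))
        elif key_by == "ligand_id":
            lig_key = lig.ligand_id
        else:
            raise ValueError("key_by must be 'ligand_id' or 'template'")
        for inter in detect_interactions(protein, lig, cfg):
            hist.add((lig_key,) + inter.tuple_key[1:])
    return hist
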