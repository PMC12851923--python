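"""Deterministic synthetic complexes and controlled pose perturbations.

Every metric in this package is testable without downloading structures:
a toy target is an ideal poly-alanine α-helix (canonical φ/ψ of −57°,
−47° and standard backbone geometry, built by internal-coordinate
chaining) with one or more small-molecule ligands embedded by seeded
distance geometry and placed against the helix face so the 10 Å
binding-site selection is guaranteed non-empty and clash-free.

Perturbations are exact rigid motions (about the ligand centroid)
followed by optional per-atom Gaussian jitter, so ground-truth RMSD
values are known by construction: a pure translation of magnitude *d*
must be reported as an RMSD of exactly *d*.

Mock "methods" wrap this: each method has an error scale that sets the
magnitude of the rigid offset applied to its predicted ligands, and each
prediction additionally receives a random global rigid motion of the
whole complex, which a correct pocket alignment must undo exactly.

No physical realism is attempted (no energetics, no rotamers); the
scaffold only needs to be rigid, clash-free and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .datamodel import (
    Atom,
    Chain,
    ComplexRecord,
    LigandPose,
    Manifest,
    ManifestEntry,
    ProteinStructure,
    Residue,
)
from .structio import pose_from_mol, save_manifest, write_ligands, write_protein

# backbone geometry: bond lengths (Å) and angles (deg) of the peptide unit
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_residues: int = 12
    ligand_templates: tuple[str, ...] = ("CCO",)
    pocket_radius: float = 10.0
    target_id: str = "toy1"
    dataset: str = "toy"

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_templates)


class GenerationError(RuntimeError):
    """A ligand template could not be embedded in 3-D."""


# ---------------------------------------------------------------------------
# internal-coordinate chain building
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D bonded to C with given C–D length, B–C–D angle and
    A–B–C–D torsion (natural extension reference frame)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(n_residues: int, chain_id: str = "A") -> ProteinStructure:
    """Ideal poly-alanine α-helix with N, CA, C, O, CB per residue."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    coords: list[dict[str, np.ndarray]] = []
    # seed residue: N at origin, CA on x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = coords[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, _PHI)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O and CB once every backbone neighbour exists
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            res["O"] = _place_atom(
                coords[i + 1]["CA"], coords[i + 1]["N"], res["C"],
                _B_C_O, _A_CA_C_O, 180.0,
            )
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, _PSI + 180.0)
        prev_c = coords[i - 1]["C"] if i > 0 else res["C"] + np.array([0.0, 0.0, 2.4])
        res["CB"] = _place_atom(prev_c, res["N"], res["CA"], _B_CA_CB, _A_N_CA_CB, _PHI - 122.6)
    residues = []
    for i, res in enumerate(coords):
        key = (chain_id, i + 1, "")
        atoms = [Atom(name, name[0], xyz, key) for name, xyz in res.items()]
        residues.append(Residue("ALA", key, atoms))
    return ProteinStructure([Chain(chain_id, residues)])


# ---------------------------------------------------------------------------
# ligand embedding and placement
# ---------------------------------------------------------------------------

def embed_ligand(template_smiles: str, seed: int, ligand_id: str, role: str) -> LigandPose:
    """Seeded distance-geometry embedding of a template SMILES."""
    mol = Chem.MolFromSmiles(template_smiles)
    if mol is None:
        raise GenerationError(f"unparseable template: {template_smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise GenerationError(f"cannot embed template: {template_smiles!r}")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
    return pose_from_mol(molh, template_smiles, ligand_id, role)


def _helix_frame(protein: ProteinStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, axis direction and one perpendicular of the helix."""
    ca = np.array([
        res.atom("CA").coords for res in protein.iter_residues() if res.atom("CA")
    ])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    perp = vt[1]
    return centroid, axis, perp


def make_toy_complex(spec: FixtureSpec) -> ComplexRecord:
    """Build one toy target: helix plus placed ligands.

    Each ligand is centred on a point set off the helix face, pushed
    outward until no protein–ligand heavy-atom pair is closer than
    3.6 Å, while construction guarantees at least three residues within
    ``spec.pocket_radius`` of the ligand.
    """
    protein = make_helix(spec.n_residues)
    centroid, axis, perp = _helix_frame(protein)
    prot_xyz = protein.heavy_coords()
    span = 6.0 * max(spec.n_ligands - 1, 0)
    offsets = np.linspace(-span / 2, span / 2, spec.n_ligands) if spec.n_ligands > 1 else [0.0]

    ligands = []
    for k, smiles in enumerate(spec.ligand_templates):
        role = "primary" if k == 0 else "fragment"
        lig = embed_ligand(smiles, spec.seed * 1009 + k, f"LIG{k + 1}", role)
        anchor = centroid + float(offsets[k]) * axis
        dist = 5.0
        while dist < spec.pocket_radius - 1.0:
            target = anchor + dist * perp
            moved = lig.coords - lig.centroid() + target
            gap = np.min(np.linalg.norm(moved[:, None, :] - prot_xyz[None, :, :], axis=-1))
            if gap >= 3.4:
                break
            dist += 0.25
        lig = replace(lig, coords=lig.coords - lig.centroid() + anchor + dist * perp)
        ligands.append(lig)

    return ComplexRecord(
        target_id=spec.target_id,
        protein=protein,
        ligands=ligands,
        primary_ligand_id="LIG1",
        dataset=spec.dataset,
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm == 0 or angle_deg == 0:
        return np.eye(3)
    axis = axis / norm
    t = math.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def perturb_pose(
    pose: LigandPose,
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
    rotation_angle: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> LigandPose:
    """Rigid motion (rotation about the centroid, then translation)
    followed by per-atom isotropic Gaussian jitter.

    With zero jitter and identity rotation the resulting RMSD against
    the original pose equals the translation magnitude exactly.
    """
    R = _axis_angle_matrix(np.asarray(rotation_axis, float), rotation_angle)
    centre = pose.centroid()
    coords = (pose.coords - centre) @ R.T + centre + np.asarray(translation, float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
    return replace(pose, coords=coords)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a translation in ±20 Å."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


# ---------------------------------------------------------------------------
# datasets and mock method runs on disk
# ---------------------------------------------------------------------------

#: small, quickly embeddable templates cycled over toy targets
DEFAULT_TEMPLATE_POOL = (
    "CCO",
    "c1ccccc1",
    "CC(=O)Nc1ccccc1",
    "OC(=O)c1ccccc1O",
    "CCN(CC)CC",
    "Cc1ccc(O)cc1",
)


def make_fixture_dataset(
    out_dir: Path | str,
    n_targets: int = 4,
    seed: int = 7,
    n_residues: int = 14,
    multiligand: bool = False,
    dataset: str = "toy",
) -> tuple[Manifest, list[ComplexRecord]]:
    """Write a reference dataset of toy targets plus its manifest."""
    out_dir = Path(out_dir)
    ref_dir = out_dir / "references"
    ref_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    records = []
    for t in range(n_targets):
        pool = DEFAULT_TEMPLATE_POOL
        templates = [pool[t % len(pool)]]
        if multiligand:
            templates += [pool[(t + 1) % len(pool)], pool[(t + 3) % len(pool)]]
        spec = FixtureSpec(
            seed=seed + 101 * t,
            n_residues=n_residues,
            ligand_templates=tuple(templates),
            target_id=f"target{t + 1}",
            dataset=dataset,
        )
        record = make_toy_complex(spec)
        ppath = ref_dir / f"{record.target_id}_protein.pdb"
        lpath = ref_dir / f"{record.target_id}_ligands.sdf"
        write_protein(record.protein, ppath)
        write_ligands(record.ligands, lpath)
        records.append(record)
        entries.append(
            ManifestEntry(
                target_id=record.target_id,
                protein_path=str(ppath),
                ligand_path=str(lpath),
                ligand_smiles=[lig.template_smiles for lig in record.ligands],
                ligand_roles=[lig.role for lig in record.ligands],
                ligand_ids=[lig.ligand_id for lig in record.ligands],
            )
        )
    manifest = Manifest(dataset=dataset, entries=entries)
    save_manifest(manifest, out_dir / "manifest.yaml")
    return manifest, records


@dataclass
class MethodProfile:
    """A mock predictor: its ligand placements err by ``error_scale`` Å."""

    name: str
    error_scale: float
    rotation_scale: float = 0.0  # deg of in-place ligand rotation per unit error


def make_mock_method_runs(
    records: Sequence[ComplexRecord],
    method_profiles: Sequence[MethodProfile],
    n_runs: int,
    seed: int,
    out_dir: Optional[Path | str] = None,
) -> dict[str, dict[int, list[ComplexRecord]]]:
    """Generate per-method, per-run predictions for a set of targets.

    Each prediction keeps the reference protein, offsets every ligand by
    a random direction scaled by the method's error scale, then applies
    one random global rigid motion to the whole complex (protein and
    ligands together). When ``out_dir`` is given, predictions are written
    in the discovery layout
    ``<dataset>/<method>/run_<k>/<target>_protein.pdb|_ligands.sdf``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out: dict[str, dict[int, list[ComplexRecord]]] = {}
    for m_idx, profile in enumerate(method_profiles):
        out[profile.name] = {}
        for run in range(1, n_runs + 1):
            run_records = []
            for t_idx, record in enumerate(records):
                rng = np.random.default_rng(
                    [seed % (2**31), m_idx, run, t_idx]
                )
                new_ligands = []
                for lig in record.ligands:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    magnitude = profile.error_scale * (0.5 + abs(rng.normal())) \
                        if profile.error_scale > 0 else 0.0
                    angle = profile.rotation_scale * rng.normal() \
                        if profile.rotation_scale > 0 else 0.0
                    new_ligands.append(
                        perturb_pose(
                            lig,
                            translation=direction * magnitude,
                            rotation_axis=rng.normal(size=3),
                            rotation_angle=angle,
                        )
                    )
                pred = ComplexRecord(
                    target_id=record.target_id,
                    protein=record.protein,
                    ligands=new_ligands,
                    primary_ligand_id=record.primary_ligand_id,
                    dataset=record.dataset,
                )
                R, t = random_rigid_motion(rng)
                pred = pred.transformed(R, t)
                run_records.append(pred)
                if out_dir is not None:
                    run_dir = Path(out_dir) / record.dataset / profile.name / f"run_{run}"
                    run_dir.mkdir(parents=True, exist_ok=True)
                    write_protein(pred.protein, run_dir / f"{pred.target_id}_protein.pdb")
                    write_ligands(pred.ligands, run_dir / f"{pred.target_id}_ligands.sdf")
            out[profile.name][run] = run_records
    return out
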