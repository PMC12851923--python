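"""Structure and manifest I/O.

Proteins are read from PDB/mmCIF through :mod:`gemmi`; ligand poses are
read from SDF through RDKit and validated against a template SMILES by
heavy-atom graph isomorphism (element, bond order, formal charge). A
prediction whose ligand graph cannot be matched to the template raises
:class:`~poselens.datamodel.TemplateMismatchError`, which the benchmark
layer turns into an excluded row.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
import yaml
from rdkit import Chem

from .datamodel import (
    Atom,
    Chain,
    ComplexRecord,
    LigandPose,
    LIGAND_ROLES,
    Manifest,
    ManifestEntry,
    ProteinStructure,
    Residue,
    TemplateMismatchError,
)

PathLike = Union[str, os.PathLike]


class EmptyStructureError(ValueError):
    """A structure file contained no protein residues."""


class ManifestError(ValueError):
    """A manifest failed schema validation; the message names the field."""


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_protein(path: PathLike, fmt: Optional[str] = None) -> ProteinStructure:
    """Read the amino-acid chains of a PDB or mmCIF file.

    Hydrogens are retained (flagged non-heavy); alternate locations are
    resolved to the highest-occupancy conformer; waters, ligands and
    nucleic acids are dropped. ``fmt`` may be ``"pdb"`` or ``"cif"``;
    by default it is inferred from the file extension.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such structure file: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            coor = {"pdb": gemmi.CoorFormat.Pdb, "cif": gemmi.CoorFormat.Mmcif}[fmt.lower()]
            st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError, KeyError) as exc:
        raise IOError(f"cannot parse structure file {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            key = (ch.name, res.seqid.num, (res.seqid.icode or " ").strip())
            atoms = []
            for a in _resolve_altlocs(res):
                element = a.element.name if a.element else "X"
                atoms.append(Atom(a.name, element, np.array([a.pos.x, a.pos.y, a.pos.z]), key))
            if any(at.is_heavy for at in atoms):
                residues.append(Residue(res.name, key, atoms))
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no protein residues")
    return ProteinStructure(chains)


def write_protein(protein: ProteinStructure, path: PathLike) -> None:
    """Write a ProteinStructure as a PDB file (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = "poselens"
    model = gemmi.Model("1")
    for ch in protein.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.key[1], res.key[2] or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------

def _charge_consistent(template: Chem.Mol, pose: Chem.Mol, match: Sequence[int]) -> bool:
    return all(
        template.GetAtomWithIdx(i).GetFormalCharge()
        == pose.GetAtomWithIdx(int(j)).GetFormalCharge()
        for i, j in enumerate(match)
    )


def match_template(template: Chem.Mol, pose: Chem.Mol) -> Optional[tuple[int, ...]]:
    """First template-atom -> pose-atom graph isomorphism, or None.

    Matching is on element, aromaticity and bond order (RDKit substructure
    semantics) with formal charges checked explicitly.
    """
    if template.GetNumAtoms() != pose.GetNumAtoms():
        return None
    if template.GetNumBonds() != pose.GetNumBonds():
        return None
    for match in pose.GetSubstructMatches(template, uniquify=False, maxMatches=50000):
        if _charge_consistent(template, pose, match):
            return tuple(int(j) for j in match)
    return None


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def pose_from_mol(
    mol3d: Chem.Mol,
    template_smiles: str,
    ligand_id: str,
    role: str = "primary",
) -> LigandPose:
    """Build a LigandPose from an RDKit mol with a conformer."""
    template = mol_from_smiles(template_smiles)
    heavy = Chem.RemoveHs(mol3d)
    conf = heavy.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(heavy.GetNumAtoms())]
    )
    mapping = match_template(template, heavy)
    if mapping is None:
        raise TemplateMismatchError(
            f"ligand {ligand_id}: heavy-atom graph does not match template "
            f"{template_smiles!r}"
        )
    return LigandPose(
        ligand_id=ligand_id,
        mol=heavy,
        coords=coords,
        template_smiles=template_smiles,
        template_map=mapping,
        role=role,
    )


def read_ligands(
    path: PathLike,
    template_smiles: Sequence[str],
    ligand_ids: Optional[Sequence[str]] = None,
    roles: Optional[Sequence[str]] = None,
) -> list[LigandPose]:
    """Read a (multi-record) SDF; record *k* is validated against template *k*.

    Each SDF record is one fragment ligand, in file order.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such SDF file: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = [m for m in supplier]
    if any(m is None for m in mols):
        raise IOError(f"unparseable SDF record in {path}")
    if len(mols) != len(template_smiles):
        raise TemplateMismatchError(
            f"{path}: {len(mols)} SDF records but {len(template_smiles)} templates"
        )
    if ligand_ids is None:
        ligand_ids = [f"LIG{i + 1}" for i in range(len(mols))]
    if roles is None:
        roles = ["primary"] + ["fragment"] * (len(mols) - 1)
    return [
        pose_from_mol(mol, smi, lid, role)
        for mol, smi, lid, role in zip(mols, template_smiles, ligand_ids, roles)
    ]


def read_ligand(path: PathLike, template_smiles: str, ligand_id: str = "LIG1") -> LigandPose:
    """Read a single-record SDF ligand validated against one template."""
    return read_ligands(path, [template_smiles], [ligand_id])[0]


def write_ligands(ligands: Sequence[LigandPose], path: PathLike) -> None:
    """Write ligand poses as a multi-record SDF (one record per fragment)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for lig in ligands:
            mol = Chem.Mol(lig.mol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(lig.coords):
                conf.SetAtomPosition(i, [float(x) for x in xyz])
            mol.RemoveAllConformers()
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", lig.ligand_id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# manifests and complex records
# ---------------------------------------------------------------------------

_REQUIRED_ENTRY_KEYS = ("target_id", "protein_path", "ligand_path", "ligand_smiles", "ligand_roles")


def load_manifest(path: PathLike) -> Manifest:
    """Load and validate a YAML/JSON benchmark manifest."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such manifest: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ManifestError("manifest root must be a mapping")
    if "dataset" not in data:
        raise ManifestError("missing required field: dataset")
    if "targets" not in data or not isinstance(data["targets"], list):
        raise ManifestError("missing required field: targets (list)")
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    root = path.parent
    for i, raw in enumerate(data["targets"]):
        for key in _REQUIRED_ENTRY_KEYS:
            if key not in raw:
                raise ManifestError(f"targets[{i}]: missing required field: {key}")
        tid = raw["target_id"]
        if tid in seen:
            raise ManifestError(f"targets[{i}]: duplicate target_id: {tid}")
        seen.add(tid)
        roles = list(raw["ligand_roles"])
        for role in roles:
            if role not in LIGAND_ROLES:
                raise ManifestError(
                    f"targets[{i}].ligand_roles: invalid role {role!r} "
                    f"(allowed: {', '.join(LIGAND_ROLES)})"
                )
        smiles = list(raw["ligand_smiles"])
        if len(smiles) != len(roles):
            raise ManifestError(f"targets[{i}]: ligand_smiles and ligand_roles length mismatch")
        if roles.count("primary") > 1:
            raise ManifestError(f"targets[{i}].ligand_roles: more than one primary ligand")
        for smi in smiles:
            if Chem.MolFromSmiles(smi) is None:
                raise ManifestError(f"targets[{i}].ligand_smiles: unparseable SMILES {smi!r}")
        ppath = root / raw["protein_path"]
        lpath = root / raw["ligand_path"]
        for p in (ppath, lpath):
            if not p.is_file():
                raise ManifestError(f"targets[{i}]: path not resolvable: {p}")
        entries.append(
            ManifestEntry(
                target_id=tid,
                protein_path=str(ppath),
                ligand_path=str(lpath),
                ligand_smiles=smiles,
                ligand_roles=roles,
                ligand_ids=list(raw.get("ligand_ids", [])),
            )
        )
    return Manifest(dataset=str(data["dataset"]), entries=entries)


def save_manifest(manifest: Manifest, path: PathLike) -> None:
    """Write a manifest as YAML with paths relative to the manifest location."""
    root = Path(path).parent
    targets = []
    for e in manifest.entries:
        targets.append(
            {
                "target_id": e.target_id,
                "protein_path": os.path.relpath(e.protein_path, root),
                "ligand_path": os.path.relpath(e.ligand_path, root),
                "ligand_smiles": list(e.ligand_smiles),
                "ligand_roles": list(e.ligand_roles),
                "ligand_ids": list(e.ligand_ids),
            }
        )
    payload = {"dataset": manifest.dataset, "targets": targets}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_complex(entry: ManifestEntry, dataset: str = "") -> ComplexRecord:
    """Materialize one manifest entry into a ComplexRecord."""
    protein = read_protein(entry.protein_path)
    ids = list(entry.ligand_ids) or [f"LIG{i + 1}" for i in range(len(entry.ligand_smiles))]
    ligands = read_ligands(entry.ligand_path, entry.ligand_smiles, ids, entry.ligand_roles)
    primary = None
    for lig, role in zip(ligands, entry.ligand_roles):
        if role == "primary":
            primary = lig.ligand_id
    return ComplexRecord(
        target_id=entry.target_id,
        protein=protein,
        ligands=ligands,
        primary_ligand_id=primary,
        dataset=dataset,
    )
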