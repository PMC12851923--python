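"""Core in-memory containers shared by every metric module.

The containers are deliberately light: a protein is an ordered hierarchy
of chains, residues and atoms (as read from PDB/mmCIF); a ligand pose is
an RDKit molecular graph plus an ``(n_heavy, 3)`` coordinate array in the
same frame as the protein; a complex record bundles one benchmark target.
All coordinates are in angstroms and all metrics operate on heavy atoms
only — hydrogens are parsed but flagged and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
from rdkit import Chem

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)

#: roles a ligand may play in a benchmark target
LIGAND_ROLES = ("primary", "cofactor", "fragment")


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element, position and parent-residue key."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    residue_key: ResidueKey

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    name: str  # 3-letter code
    key: ResidueKey
    atoms: list[Atom]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]


@dataclass
class ProteinStructure:
    """Ordered chains → residues → atoms, as read from file."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        for ch in self.chains:
            keys = [r.key for r in ch.residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue keys in chain {ch.chain_id}")

    def iter_residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def iter_heavy_atoms(self) -> Iterator[Atom]:
        for res in self.iter_residues():
            yield from res.heavy_atoms()

    def residue_by_key(self, key: ResidueKey) -> Optional[Residue]:
        for ch in self.chains:
            if ch.chain_id != key[0]:
                continue
            for res in ch.residues:
                if res.key == key:
                    return res
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.iter_heavy_atoms()]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        new_chains = []
        for ch in self.chains:
            new_res = []
            for res in ch.residues:
                atoms = [
                    Atom(a.name, a.element, rotation @ a.coords + translation, a.residue_key)
                    for a in res.atoms
                ]
                new_res.append(Residue(res.name, res.key, atoms))
            new_chains.append(Chain(ch.chain_id, new_res))
        return ProteinStructure(new_chains)


class TemplateMismatchError(ValueError):
    """Ligand heavy-atom graph does not match its template SMILES."""


@dataclass
class LigandPose:
    """A ligand molecular graph with one 3-D heavy-atom conformation.

    ``mol`` holds the heavy-atom graph (bond orders, aromaticity, formal
    charges); ``coords`` is row-aligned with ``mol`` atom indices;
    ``template_map`` maps template-SMILES atom index -> pose atom index,
    so metric code can put any two poses of the same template into a
    common atom order.
    """

    ligand_id: str
    mol: Chem.Mol  # heavy atoms only
    coords: np.ndarray  # (n_heavy, 3)
    template_smiles: str
    template_map: tuple[int, ...]  # template atom i -> pose atom template_map[i]
    role: str = "primary"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.mol.GetNumAtoms()
        if n < 1:
            raise ValueError("ligand must have at least one heavy atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"ligand {self.ligand_id}: coords shape {self.coords.shape} "
                f"does not match {n} heavy atoms"
            )
        if len(self.template_map) != n:
            raise ValueError("template_map must cover every heavy atom")

    @property
    def n_heavy(self) -> int:
        return self.mol.GetNumAtoms()

    def template_coords(self) -> np.ndarray:
        """Coordinates reordered into template-SMILES atom order."""
        return self.coords[list(self.template_map)]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        return replace(self, coords=self.coords @ rotation.T + translation)


@dataclass
class ComplexRecord:
    """One benchmark target: protein, its ligands and metadata."""

    target_id: str
    protein: ProteinStructure
    ligands: list[LigandPose]
    primary_ligand_id: Optional[str] = None
    dataset: str = ""

    def __post_init__(self) -> None:
        ids = [lig.ligand_id for lig in self.ligands]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.target_id}: duplicate ligand ids")
        if self.primary_ligand_id is not None and self.primary_ligand_id not in ids:
            raise ValueError(
                f"{self.target_id}: primary ligand {self.primary_ligand_id!r} not present"
            )

    @property
    def primary_ligand(self) -> Optional[LigandPose]:
        if self.primary_ligand_id is None:
            return None
        for lig in self.ligands:
            if lig.ligand_id == self.primary_ligand_id:
                return lig
        return None

    def ligand_heavy_coords(self) -> np.ndarray:
        """All ligand heavy-atom coordinates, stacked."""
        return np.vstack([lig.coords for lig in self.ligands])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexRecord":
        return ComplexRecord(
            target_id=self.target_id,
            protein=self.protein.transformed(rotation, translation),
            ligands=[lig.transformed(rotation, translation) for lig in self.ligands],
            primary_ligand_id=self.primary_ligand_id,
            dataset=self.dataset,
        )


@dataclass
class ManifestEntry:
    target_id: str
    protein_path: str
    ligand_path: str
    ligand_smiles: list[str]
    ligand_roles: list[str]
    ligand_ids: list[str] = field(default_factory=list)


@dataclass
class Manifest:
    dataset: str
    entries: list[ManifestEntry]
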