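"""Binding-site definition and pocket-focused superposition.

The binding site of a reference complex is every amino-acid residue with
at least one heavy atom within 10 Å (inclusive) of any crystallized
ligand heavy atom, all ligands considered jointly. Predicted complexes
are mapped onto the reference chain-by-chain via global sequence
alignment (Hungarian/exhaustive tie-breaking among identical chains on
pocket Cα fit), then rigidly superposed by a Kabsch fit on the mapped
binding-site heavy atoms. The fitted transform moves the *whole*
predicted complex — protein and ligands together — so ligand placement
errors are preserved, as blind-docking evaluation requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .datamodel import ComplexRecord, ProteinStructure, ResidueKey

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class EmptySiteError(ValueError):
    """No residue lies within the cutoff of any ligand heavy atom."""


class DegenerateAlignmentError(ValueError):
    """Too few (or collinear) points for a rigid superposition."""


class CorrespondenceError(ValueError):
    """No acceptable chain/residue mapping between prediction and reference."""


@dataclass(frozen=True)
class BindingSite:
    residue_keys: frozenset[ResidueKey]
    cutoff: float = 10.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class Correspondence:
    """Predicted-to-reference chain and residue maps."""

    chain_map: dict[str, str]
    residue_map: dict[ResidueKey, ResidueKey]  # predicted key -> reference key
    mismatched: set[ResidueKey] = field(default_factory=set)

    def reverse_residue_map(self) -> dict[ResidueKey, ResidueKey]:
        return {v: k for k, v in self.residue_map.items()}


# ---------------------------------------------------------------------------
# binding site
# ---------------------------------------------------------------------------

def select_binding_site(reference: ComplexRecord, cutoff: float = 10.0) -> BindingSite:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom."""
    if not reference.ligands:
        raise EmptySiteError(f"{reference.target_id}: no ligands")
    lig_xyz = reference.ligand_heavy_coords()
    if lig_xyz.size == 0:
        raise EmptySiteError(f"{reference.target_id}: ligands have no heavy atoms")
    tree = cKDTree(lig_xyz)
    keys: set[ResidueKey] = set()
    for res in reference.protein.iter_residues():
        pts = np.array([a.coords for a in res.heavy_atoms()])
        if pts.size and np.any(tree.query(pts)[0] <= cutoff):
            keys.add(res.key)
    if not keys:
        raise EmptySiteError(f"{reference.target_id}: empty binding site at {cutoff} A")
    return BindingSite(frozenset(keys), cutoff)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(fixed: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``mobile`` onto ``fixed``.

    Returns the transform and the fit RMSD. Reflections are never
    produced (chirality is preserved). Raises
    :class:`DegenerateAlignmentError` for fewer than three points or a
    collinear point set.
    """
    fixed = np.asarray(fixed, float)
    mobile = np.asarray(mobile, float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be matching k x 3 arrays")
    k = fixed.shape[0]
    if k < 3:
        raise DegenerateAlignmentError(f"need >= 3 points, got {k}")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    H = (mobile - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the points carry no plane: rotation is underdetermined
    if np.sum(S > 1e-8 * max(S[0], 1e-30)) < 2:
        raise DegenerateAlignmentError("collinear or coincident point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


# ---------------------------------------------------------------------------
# chain/residue correspondence
# ---------------------------------------------------------------------------

def _chain_sequence(chain) -> str:
    return "".join(_THREE_TO_ONE.get(res.name, "X") for res in chain.residues)


def _align_chains(seq_a: str, seq_b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner.align(seq_a, seq_b)[0]


def _identity_and_pairs(alignment) -> tuple[float, list[tuple[int, int]]]:
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            i, j = a_start + off, b_start + off
            pairs.append((i, j))
            if alignment.sequences[0][i] == alignment.sequences[1][j]:
                matches += 1
    shorter = min(len(alignment.sequences[0]), len(alignment.sequences[1]))
    identity = matches / shorter if shorter else 0.0
    return identity, pairs


def _pocket_ca_rmsd(
    predicted: ProteinStructure,
    reference: ProteinStructure,
    residue_map: dict[ResidueKey, ResidueKey],
    site_keys: frozenset[ResidueKey],
) -> float:
    """Binding-site Cα RMSD under a whole-complex Cα fit (inf if degenerate).

    The fit uses every mapped Cα pair so that competing chain assignments
    of a homo-oligomer are distinguished by how well the *pocket* lands,
    not by per-chain self-similarity.
    """
    fixed, mobile, in_site = [], [], []
    for pkey, rkey in residue_map.items():
        pres = predicted.residue_by_key(pkey)
        rres = reference.residue_by_key(rkey)
        if pres is None or rres is None:
            continue
        pa, ra = pres.atom("CA"), rres.atom("CA")
        if pa is not None and ra is not None:
            mobile.append(pa.coords)
            fixed.append(ra.coords)
            in_site.append(rkey in site_keys)
    in_site = np.array(in_site, bool)
    if len(fixed) < 3 or in_site.sum() < 1:
        return float("inf")
    try:
        tf, _ = kabsch(np.array(fixed), np.array(mobile))
    except DegenerateAlignmentError:
        return float("inf")
    moved = tf.apply(np.array(mobile))
    dev = moved[in_site] - np.array(fixed)[in_site]
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def build_correspondence(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    min_identity: float = 0.30,
    site: BindingSite | None = None,
    max_exhaustive_chains: int = 6,
) -> Correspondence:
    """Pair predicted chains to reference chains and map residues.

    Chains are paired by maximum global sequence identity; among
    assignments whose identities tie (homo-oligomers), the one with the
    smallest pocket Cα fit RMSD wins — exhaustively for up to
    ``max_exhaustive_chains`` chains, else by Hungarian assignment on
    per-pair pocket RMSD.
    """
    pred_chains = predicted.protein.chains
    ref_chains = reference.protein.chains
    if not pred_chains or not ref_chains:
        raise CorrespondenceError("both complexes need at least one protein chain")

    n_p, n_r = len(pred_chains), len(ref_chains)
    identity = np.zeros((n_p, n_r))
    pair_maps: dict[tuple[int, int], dict[ResidueKey, ResidueKey]] = {}
    mismatched_by_pair: dict[tuple[int, int], set[ResidueKey]] = {}
    for i, pch in enumerate(pred_chains):
        for j, rch in enumerate(ref_chains):
            aln = _align_chains(_chain_sequence(pch), _chain_sequence(rch))
            ident, pairs = _identity_and_pairs(aln)
            identity[i, j] = ident
            rmap: dict[ResidueKey, ResidueKey] = {}
            mism: set[ResidueKey] = set()
            for pi, rj in pairs:
                pres, rres = pch.residues[pi], rch.residues[rj]
                rmap[pres.key] = rres.key
                if pres.name != rres.name:
                    mism.add(pres.key)
            pair_maps[(i, j)] = rmap
            mismatched_by_pair[(i, j)] = mism

    usable = identity >= min_identity
    if not usable.any():
        raise CorrespondenceError(
            f"no chain pair reaches {min_identity:.0%} sequence identity"
        )

    if site is None:
        site = select_binding_site(reference)

    def assignment_cost(assign: list[tuple[int, int]]) -> float:
        merged: dict[ResidueKey, ResidueKey] = {}
        for i, j in assign:
            merged.update(pair_maps[(i, j)])
        rmsd = _pocket_ca_rmsd(predicted.protein, reference.protein, merged, site.residue_keys)
        # identity dominates; pocket fit breaks ties among equal-identity maps
        ident_sum = sum(identity[i, j] for i, j in assign)
        return -1000.0 * ident_sum + min(rmsd, 999.0)

    candidates: list[list[tuple[int, int]]] = []
    if max(n_p, n_r) <= max_exhaustive_chains:
        smaller, larger = (range(n_p), range(n_r)) if n_p <= n_r else (range(n_r), range(n_p))
        for perm in itertools.permutations(larger, len(list(smaller))):
            if n_p <= n_r:
                assign = [(i, perm[i]) for i in range(n_p)]
            else:
                assign = [(perm[j], j) for j in range(n_r)]
            if all(usable[i, j] for i, j in assign):
                candidates.append(assign)
    if not candidates:
        cost = np.where(usable, 1.0 - identity, 1e6)
        rows, cols = linear_sum_assignment(cost)
        assign = [(int(i), int(j)) for i, j in zip(rows, cols) if usable[i, j]]
        if not assign:
            raise CorrespondenceError("Hungarian assignment found no usable chain pair")
        candidates.append(assign)

    best = min(candidates, key=assignment_cost)
    chain_map = {pred_chains[i].chain_id: ref_chains[j].chain_id for i, j in best}
    residue_map: dict[ResidueKey, ResidueKey] = {}
    mismatched: set[ResidueKey] = set()
    for i, j in best:
        residue_map.update(pair_maps[(i, j)])
        mismatched |= mismatched_by_pair[(i, j)]
    return Correspondence(chain_map, residue_map, mismatched)


# ---------------------------------------------------------------------------
# pocket-focused alignment
# ---------------------------------------------------------------------------

def _site_atom_pairs(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    site: BindingSite,
    corr: Correspondence,
    ca_only: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    fixed, mobile = [], []
    n_residues = 0
    rev = corr.reverse_residue_map()
    for rkey in sorted(site.residue_keys):
        pkey = rev.get(rkey)
        if pkey is None:
            continue
        rres = reference.protein.residue_by_key(rkey)
        pres = predicted.protein.residue_by_key(pkey)
        if rres is None or pres is None:
            continue
        used = False
        if ca_only:
            ra, pa = rres.atom("CA"), pres.atom("CA")
            if ra is not None and pa is not None and ra.is_heavy:
                fixed.append(ra.coords)
                mobile.append(pa.coords)
                used = True
        else:
            pnames = {a.name: a for a in pres.heavy_atoms()}
            for ra in rres.heavy_atoms():
                pa = pnames.get(ra.name)
                if pa is not None:
                    fixed.append(ra.coords)
                    mobile.append(pa.coords)
                    used = True
        n_residues += used
    return (
        np.array(fixed, float).reshape(-1, 3),
        np.array(mobile, float).reshape(-1, 3),
        n_residues,
    )


def align_to_pocket(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    site: BindingSite,
    corr: Correspondence,
) -> tuple[ComplexRecord, float]:
    """Superpose a predicted complex onto the reference binding site.

    The Kabsch fit runs on mapped binding-site heavy atoms paired by atom
    name (falling back to Cα atoms when the heavy-atom name sets fail to
    pair at least three residues); the resulting single rigid transform
    is applied to every predicted protein and ligand atom, so predicted
    ligands are never independently re-superposed.

    Returns the transformed complex and the pocket fit RMSD.
    """
    fixed, mobile, n_res = _site_atom_pairs(predicted, reference, site, corr, ca_only=False)
    if n_res < 3:
        fixed, mobile, n_res = _site_atom_pairs(predicted, reference, site, corr, ca_only=True)
    if n_res < 3 or len(fixed) < 3:
        raise DegenerateAlignmentError(
            f"{reference.target_id}: only {n_res} usable binding-site residues"
        )
    transform, fit_rmsd = kabsch(fixed, mobile)
    return predicted.transformed(transform.rotation, transform.translation), fit_rmsd
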