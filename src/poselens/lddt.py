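"""Superposition-free local distance difference test (lDDT) and its
protein–ligand interface variant.

For every heavy atom *i* of the reference structure, its neighbourhood
is the set of reference heavy atoms *j* in a *different* residue with
``d_ij < R0`` (inclusion radius, default 15 Å). The per-atom score is
the mean over four tolerance thresholds (0.5, 1, 2, 4 Å) of the
fraction of neighbour distances preserved within that tolerance by the
prediction, and the final score is the mean over atoms that have at
least one neighbour. Atoms absent from the prediction preserve nothing
(score contribution zero) rather than being dropped — incomplete
predictions are penalized, not excused.

The interface variant (lDDT-PLI) restricts the distance set to cross
pairs — one protein atom and one ligand heavy atom — with ligand atoms
paired under the RMSD-minimizing symmetry mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import ComplexRecord
from .pocket_align import Correspondence
from .pose_metrics import assign_fragments, best_symmetry_mapping


class UndefinedScoreError(ValueError):
    """No reference atom has a neighbour: the score is undefined."""


@dataclass(frozen=True)
class LddtConfig:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    exclude_same_residue: bool = True
    interface_only: bool = False
    interface_radius: float = 15.0

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if any(x <= 0 for x in t) or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be positive and strictly increasing")
        radius = self.interface_radius if self.interface_only else self.inclusion_radius
        if radius <= max(t):
            raise ValueError("inclusion radius must exceed the largest threshold")


def lddt_from_arrays(
    ref_coords: np.ndarray,
    pred_coords: np.ndarray,
    residue_ids: np.ndarray,
    present: np.ndarray,
    cfg: LddtConfig = LddtConfig(),
    group_ids: np.ndarray | None = None,
) -> float:
    """Core lDDT over index-aligned reference/predicted atom arrays.

    ``present[i]`` marks reference atoms that exist in the prediction
    (rows of ``pred_coords`` for absent atoms are ignored).
    ``group_ids`` splits atoms into sides (e.g. protein vs ligand); when
    ``cfg.interface_only`` is set, only cross-side pairs are scored.
    """
    ref_coords = np.asarray(ref_coords, float)
    pred_coords = np.asarray(pred_coords, float)
    residue_ids = np.asarray(residue_ids)
    present = np.asarray(present, bool)
    n = len(ref_coords)
    if n == 0:
        raise UndefinedScoreError("no reference atoms")

    radius = cfg.interface_radius if cfg.interface_only else cfg.inclusion_radius
    d_ref = cdist(ref_coords, ref_coords)
    neighbours = d_ref < radius
    np.fill_diagonal(neighbours, False)
    if cfg.exclude_same_residue:
        neighbours &= residue_ids[:, None] != residue_ids[None, :]
    if cfg.interface_only:
        if group_ids is None:
            raise ValueError("interface_only requires group_ids")
        group_ids = np.asarray(group_ids)
        neighbours &= group_ids[:, None] != group_ids[None, :]

    n_neigh = neighbours.sum(axis=1)
    scored = n_neigh > 0
    if not scored.any():
        raise UndefinedScoreError("no reference atom has a neighbour")

    d_pred = cdist(pred_coords, pred_coords)
    both_present = present[:, None] & present[None, :]
    diff = np.abs(d_pred - d_ref)

    per_atom = np.zeros(n)
    for delta in cfg.thresholds:
        preserved = neighbours & both_present & (diff < delta)
        with np.errstate(invalid="ignore"):
            frac = np.where(scored, preserved.sum(axis=1) / np.maximum(n_neigh, 1), 0.0)
        per_atom += frac
    per_atom /= len(cfg.thresholds)
    return float(per_atom[scored].mean())


# ---------------------------------------------------------------------------
# structure-level wrappers
# ---------------------------------------------------------------------------

def _protein_atom_table(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    corr: Correspondence,
) -> tuple[list[np.ndarray], list[np.ndarray], list[int], list[bool]]:
    """Reference protein heavy atoms with their predicted counterparts.

    Pairing is by (mapped residue key, atom name); reference atoms with
    no predicted counterpart are kept as absent.
    """
    rev = corr.reverse_residue_map()
    ref_xyz: list[np.ndarray] = []
    pred_xyz: list[np.ndarray] = []
    res_ids: list[int] = []
    present: list[bool] = []
    res_counter = 0
    for rres in reference.protein.iter_residues():
        pkey = rev.get(rres.key)
        pres = predicted.protein.residue_by_key(pkey) if pkey is not None else None
        pred_names = {a.name: a for a in pres.heavy_atoms()} if pres else {}
        for ra in rres.heavy_atoms():
            pa = pred_names.get(ra.name)
            ref_xyz.append(ra.coords)
            pred_xyz.append(pa.coords if pa is not None else np.zeros(3))
            res_ids.append(res_counter)
            present.append(pa is not None)
        res_counter += 1
    return ref_xyz, pred_xyz, res_ids, present


def lddt_protein(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    corr: Correspondence,
    cfg: LddtConfig = LddtConfig(),
) -> float:
    """All-heavy-atom lDDT of the predicted protein vs the reference."""
    ref_xyz, pred_xyz, res_ids, present = _protein_atom_table(predicted, reference, corr)
    return lddt_from_arrays(
        np.array(ref_xyz), np.array(pred_xyz), np.array(res_ids), np.array(present), cfg
    )


def lddt_pli(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    corr: Correspondence,
    cfg: LddtConfig | None = None,
) -> float:
    """Interface lDDT: distances restricted to protein–ligand cross pairs.

    Predicted ligands are assigned to reference ligands by identical-graph
    Hungarian matching on centroids; atoms within each assigned pair are
    matched under the symmetry mapping minimizing pose RMSD. Reference
    ligands left unassigned count as fully absent.
    """
    if cfg is None:
        cfg = LddtConfig(interface_only=True)
    if not cfg.interface_only:
        raise ValueError("lddt_pli requires cfg.interface_only = True")

    ref_xyz, pred_xyz, res_ids, present = _protein_atom_table(predicted, reference, corr)
    groups = [0] * len(ref_xyz)
    res_counter = max(res_ids, default=-1) + 1

    assignment = assign_fragments(predicted.ligands, reference.ligands)
    pred_for_ref = {j: i for i, j in assignment}
    for j, ref_lig in enumerate(reference.ligands):
        pose_pairs: dict[int, np.ndarray] = {}
        i = pred_for_ref.get(j)
        if i is not None:
            for p_idx, r_idx in best_symmetry_mapping(predicted.ligands[i], ref_lig):
                pose_pairs[r_idx] = predicted.ligands[i].coords[p_idx]
        for r_idx in range(ref_lig.n_heavy):
            ref_xyz.append(ref_lig.coords[r_idx])
            hit = pose_pairs.get(r_idx)
            pred_xyz.append(hit if hit is not None else np.zeros(3))
            present.append(hit is not None)
            res_ids.append(res_counter)
            groups.append(1)
        res_counter += 1

    return lddt_from_arrays(
        np.array(ref_xyz),
        np.array(pred_xyz),
        np.array(res_ids),
        np.array(present),
        cfg,
        group_ids=np.array(groups),
    )
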