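"""Ligand pose accuracy metrics.

RMSD between a predicted and a reference pose is computed over heavy
atoms in the pocket-aligned frame, with no re-superposition of the
ligand, and is symmetry-corrected: the minimum over all heavy-atom graph
automorphisms of the template is reported, so a benzene rotated by 60°
in place scores 0 Å. The centroid RMSD (distance between unweighted
heavy-atom centroids) assesses whether the binding pocket itself was
found; it is automorphism-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment

from .datamodel import ComplexRecord, LigandPose, TemplateMismatchError
from .structio import match_template, mol_from_smiles

#: automorphism enumeration cap; beyond it the canonical mapping is used
DEFAULT_AUTOMORPHISM_CAP = 10_000


class ExtractionError(ValueError):
    """No predicted fragment matches the primary-ligand template."""


@dataclass(frozen=True)
class PoseScore:
    """Per-pose accuracy summary and success flags."""

    rmsd: float
    centroid_rmsd: float
    pb_valid: bool = True
    symmetry_fallback: bool = False  # automorphism cap hit; canonical map used

    @property
    def rmsd_le_2(self) -> bool:
        return self.rmsd <= 2.0

    @property
    def centroid_le_1(self) -> bool:
        return self.centroid_rmsd <= 1.0

    @property
    def success(self) -> bool:
        """Structurally accurate *and* chemically valid (the headline criterion)."""
        return self.rmsd_le_2 and self.pb_valid


def template_automorphisms(
    template: Chem.Mol, cap: int = DEFAULT_AUTOMORPHISM_CAP
) -> tuple[list[tuple[int, ...]], bool]:
    """Heavy-atom graph automorphisms of a template molecule.

    Returns (mappings, truncated). Each mapping sigma sends template atom
    i to template atom sigma[i]. The identity is always present; if the
    enumeration exceeds ``cap`` only the identity is returned and
    ``truncated`` is True.
    """
    matches = template.GetSubstructMatches(
        template, uniquify=False, maxMatches=cap + 1, useChirality=False
    )
    matches = [m for m in matches if all(
        template.GetAtomWithIdx(i).GetFormalCharge()
        == template.GetAtomWithIdx(int(j)).GetFormalCharge()
        for i, j in enumerate(m)
    )]
    if len(matches) > cap:
        n = template.GetNumAtoms()
        return [tuple(range(n))], True
    return [tuple(int(j) for j in m) for m in matches], False


def _paired_template_coords(
    predicted: LigandPose, reference: LigandPose
) -> tuple[np.ndarray, np.ndarray, Chem.Mol]:
    if predicted.template_smiles != reference.template_smiles:
        if match_template(mol_from_smiles(reference.template_smiles), predicted.mol) is None:
            raise TemplateMismatchError(
                f"poses {predicted.ligand_id}/{reference.ligand_id} have "
                "non-isomorphic heavy-atom graphs"
            )
    template = mol_from_smiles(reference.template_smiles)
    mapping = match_template(template, predicted.mol)
    if mapping is None:
        raise TemplateMismatchError(
            f"predicted pose {predicted.ligand_id} does not match template "
            f"{reference.template_smiles!r}"
        )
    pred_xyz = predicted.coords[list(mapping)]
    ref_xyz = reference.template_coords()
    return pred_xyz, ref_xyz, template


def rmsd_fixed_mapping(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation over row-paired coordinates."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ligand_rmsd(
    predicted: LigandPose,
    reference: LigandPose,
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> tuple[float, bool]:
    """Symmetry-corrected heavy-atom RMSD in the shared frame.

    Minimizes the RMSD over all template-graph automorphisms; returns
    ``(rmsd, fallback)`` where ``fallback`` is True when the automorphism
    count exceeded the cap and only the canonical mapping was scored.
    """
    pred_xyz, ref_xyz, template = _paired_template_coords(predicted, reference)
    autos, truncated = template_automorphisms(template, automorphism_cap)
    best = min(rmsd_fixed_mapping(pred_xyz[list(sigma)], ref_xyz) for sigma in autos)
    return best, truncated


def centroid_rmsd(predicted: LigandPose, reference: LigandPose) -> float:
    """Distance between unweighted heavy-atom centroids (pocket criterion)."""
    return float(np.linalg.norm(predicted.centroid() - reference.centroid()))


def best_symmetry_mapping(
    predicted: LigandPose,
    reference: LigandPose,
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> list[tuple[int, int]]:
    """Atom pairing (predicted idx, reference idx) under the RMSD-minimizing
    automorphism — the pairing the interface lDDT variant scores with."""
    pred_xyz, ref_xyz, template = _paired_template_coords(predicted, reference)
    mapping = match_template(template, predicted.mol)
    autos, _ = template_automorphisms(template, automorphism_cap)
    best_sigma = min(
        autos, key=lambda s: rmsd_fixed_mapping(pred_xyz[list(s)], ref_xyz)
    )
    # template atom i sits at predicted atom mapping[sigma[i]] and reference
    # atom reference.template_map[i]
    return [
        (mapping[best_sigma[i]], reference.template_map[i])
        for i in range(template.GetNumAtoms())
    ]


def score_pose(
    predicted: LigandPose,
    reference: LigandPose,
    pb_valid: bool = True,
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> PoseScore:
    rmsd, fallback = ligand_rmsd(predicted, reference, automorphism_cap)
    return PoseScore(
        rmsd=rmsd,
        centroid_rmsd=centroid_rmsd(predicted, reference),
        pb_valid=pb_valid,
        symmetry_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# primary-ligand extraction and multiligand assignment
# ---------------------------------------------------------------------------

def _graph_groups(ligands: list[LigandPose]) -> dict[str, list[int]]:
    """Group ligand indices by canonical template SMILES (identical graphs)."""
    groups: dict[str, list[int]] = {}
    for i, lig in enumerate(ligands):
        canon = Chem.MolToSmiles(mol_from_smiles(lig.template_smiles))
        groups.setdefault(canon, []).append(i)
    return groups


def extract_primary(
    predicted: ComplexRecord,
    reference: ComplexRecord,
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> tuple[LigandPose, list[tuple[int, int]]]:
    """Pick the predicted fragment that is the method's primary-ligand guess.

    Among predicted fragments whose graph matches the primary template,
    the copy with the smallest symmetry-corrected RMSD to the reference
    primary is selected. Remaining predicted fragments are paired to the
    remaining reference ligands by minimum-cost (Hungarian) assignment on
    centroid distance, restricted to identical-graph groups.

    Returns the chosen pose and the leftover assignment as
    ``(predicted index, reference index)`` pairs.
    """
    ref_primary = reference.primary_ligand
    if ref_primary is None:
        raise ValueError(f"{reference.target_id}: reference has no primary ligand")
    primary_template = mol_from_smiles(ref_primary.template_smiles)

    candidates = [
        i for i, lig in enumerate(predicted.ligands)
        if match_template(primary_template, lig.mol) is not None
    ]
    if not candidates:
        raise ExtractionError(
            f"{predicted.target_id}: no predicted fragment matches the primary template"
        )
    best_i = min(
        candidates,
        key=lambda i: ligand_rmsd(predicted.ligands[i], ref_primary, automorphism_cap)[0],
    )

    rest_pred = [i for i in range(len(predicted.ligands)) if i != best_i]
    ref_primary_idx = next(
        i for i, lig in enumerate(reference.ligands)
        if lig.ligand_id == reference.primary_ligand_id
    )
    rest_ref = [i for i in range(len(reference.ligands)) if i != ref_primary_idx]

    assignment = assign_fragments(
        [predicted.ligands[i] for i in rest_pred],
        [reference.ligands[i] for i in rest_ref],
    )
    remapped = [(rest_pred[i], rest_ref[j]) for i, j in assignment]
    return predicted.ligands[best_i], remapped


def assign_fragments(
    predicted: list[LigandPose], reference: list[LigandPose]
) -> list[tuple[int, int]]:
    """Hungarian pairing of predicted to reference fragments.

    Pairs are formed only within groups of identical molecular graphs;
    the cost is the centroid distance. Unmatched fragments on either side
    are left unpaired.
    """
    if not predicted or not reference:
        return []
    pred_groups = _graph_groups(predicted)
    ref_groups = _graph_groups(reference)
    pairs: list[tuple[int, int]] = []
    for canon, p_idx in pred_groups.items():
        r_idx = ref_groups.get(canon)
        if not r_idx:
            continue
        cost = np.array(
            [[centroid_rmsd(predicted[i], reference[j]) for j in r_idx] for i in p_idx]
        )
        rows, cols = linear_sum_assignment(cost)
        pairs.extend((p_idx[int(r)], r_idx[int(c)]) for r, c in zip(rows, cols))
    return sorted(pairs)
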