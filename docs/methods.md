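# Methods

This note records the scoring model implemented by `poselens`, the
choices made where the field's conventions are genuinely open, and what
the synthetic test surface does and does not demonstrate.

## Scope and data model

One benchmark target is a reference (crystal) complex — protein
structure, one or more ligand poses with roles (primary / cofactor /
fragment), and a template SMILES per ligand — plus, per method and run,
a predicted complex in the same formats. Proteins are read from
PDB/mmCIF via gemmi; ligands from SDF via RDKit, validated against
their template by heavy-atom graph isomorphism (element, bond order,
aromaticity, formal charge). All metrics operate on heavy atoms;
hydrogens are parsed but only consulted for hydrogen-bond angle checks
when present. Alternate locations resolve to the highest-occupancy
conformer (ties: first in file). A prediction whose ligand graph cannot
be matched to its template is excluded from scoring with a
machine-readable reason rather than silently repaired.

Covalently bound ligands are treated as ordinary ligands; nucleic-acid
chains are out of scope and dropped at parse time.

## Pocket-focused alignment

The binding site is the set of residues with ≥ 1 heavy atom within
10 Å (inclusive, ≤) of any reference ligand heavy atom, all ligands
pooled. Inclusivity at the boundary is a convention choice; it is fixed
here and surfaced in the config.

Chain correspondence pairs predicted to reference chains by global
sequence alignment (match +1 / mismatch −1 / gap open −2 / extend
−0.5, identity = matches over the shorter sequence, minimum 30% —
a configurable guard, not a biological claim). Among assignments tied
on identity (homo-oligomers), the winner minimizes binding-site Cα RMSD
*under a whole-complex Cα fit*: fitting on the pocket alone cannot
distinguish two rigid copies of the same chain, so the fit uses every
mapped Cα and only the evaluation is restricted to the pocket.
Assignments are enumerated exhaustively up to 6 chains, then by
Hungarian assignment on sequence identity.

The final superposition is a Kabsch fit (proper rotations only —
reflections are rejected to preserve chirality; degenerate below 3
non-collinear points) on mapped binding-site heavy atoms paired by atom
name, falling back to Cα atoms when name sets pair fewer than three
residues. The single resulting rigid transform moves the whole
predicted complex; predicted ligands are never independently refit, so
the ligand placement error the method actually made is preserved.

## Pose metrics

RMSD is computed in the pocket-aligned frame with no re-superposition,
minimized over all heavy-atom graph automorphisms of the template
(RDKit self-matches filtered for charge consistency). Automorphism
enumeration is capped at 10,000; beyond the cap the canonical mapping
is scored and the row is flagged. Symmetry correction is applied even
though the plain formula is written over a fixed indexing: without it,
symmetric ligands are penalized for chemically meaningless relabelings.
Centroid RMSD is the distance between unweighted heavy-atom centroids
and is automorphism-invariant by construction, so the question of
whether it needs symmetry correction does not arise.

Primary-ligand extraction selects, among predicted fragments whose
graph matches the primary template, the copy with the smallest
symmetry-corrected RMSD to the reference primary. Remaining fragments
pair to remaining reference ligands by Hungarian assignment on centroid
distance within identical-graph groups. Multiligand targets without a
primary annotation are scored over the full assignment (mean fragment
RMSD, joint centroid).

## lDDT and the interface variant

For each reference heavy atom *i*, the neighbourhood 𝒩ᵢ is every
reference heavy atom *j* of a different residue with dᵢⱼ < R₀ = 15 Å
(strict inequality; neighbourhoods are defined in the reference only).
The per-atom score is the mean over the thresholds Δ ∈ {0.5, 1, 2, 4} Å
of the fraction of neighbour distances with |d̂ᵢⱼ − dᵢⱼ| < Δ, and the
final score is the mean over atoms having at least one neighbour.
Reference atoms absent from the prediction preserve nothing (they score
zero and zero out the pairs they participate in) rather than being
dropped — incomplete predictions are penalized, not excused; this is a
deliberate, configurable reading.

The interface variant (lDDT-PLI) keeps the same kernel but restricts
the distance set to cross pairs — one protein atom, one ligand heavy
atom — with the interface radius surfaced in config (default 15 Å, the
same as R₀; the exact radius used by ligand-category assessors varies
between implementations, which is why it is a parameter rather than a
constant). Ligand atoms are paired under the RMSD-minimizing symmetry
mapping; reference ligands with no assigned predicted fragment count as
fully absent.

## Interaction fingerprints

Interactions are detected geometrically with residue-level typing
tables for the 20 standard amino acids and graph-derived typing for
ligands (donors: N/O bearing explicit or implicit H; acceptors:
uncharged-or-anionic N/O below valence 4; charge centres from formal
charges; aromatic rings from ring perception; halogen-bond donors: Cl,
Br, I). Default thresholds: H-bond heavy-atom distance ≤ 3.5 Å with a
D–H···A angle ≥ 130° enforced only when an explicit hydrogen exists
(distance-only otherwise); hydrophobic C/S–C/S ≤ 4.5 Å; ionic ≤ 4.5 Å;
π-stacking ring-centroid ≤ 5.5 Å with inter-planar angle ≤ 35° (face)
or 50–90° (edge); π-cation ≤ 4.5 Å; halogen ≤ 3.5 Å; metal ≤ 2.8 Å.
Every threshold is configurable and echoed into report provenance.

At most one interaction of a given type is emitted per (ligand, residue
instance) pair — the closest-geometry instance — so a fingerprint is a
residue-level multiset, matching fingerprinting-tool convention rather
than raw atom-pair counts. The scan is restricted to residues within
10 Å of the ligand; since every threshold is below 10 Å this is
provably identical to a whole-protein scan (asserted in tests).
Donor/acceptor directionality is kept as two distinct types, with a
config switch to merge them. Water-mediated interactions and pKa-based
protonation prediction are out of scope.

In benchmark comparisons the "ligand type" element of each tuple is the
canonical template SMILES rather than the per-file ligand id, making
histograms invariant to fragment ordering in the prediction files.

## Wasserstein fingerprint scores

The bins of the predicted histogram **u** and native histogram **v**
are unified first — the support is the union of their tuples — so a
method is penalized both for missing native interaction types and for
hallucinating non-native ones. The support is placed on consecutive
integers and both histograms are normalized to unit mass; the distance
is the 1-Wasserstein distance, computed by its exact 1-D closed form
(the sum over bins of the absolute CDF difference).

A 1-D embedding of categorical tuples makes the distance depend on the
bin order; this is the module's most consequential free choice. The
order is fixed as lexicographic on (ligand type, amino-acid type,
interaction type), recorded in every report. A count-transport
(unnormalized) mode exists for sensitivity analysis only.

Per-method distances pool as the mean of defined per-target distances
(pooled-histogram aggregation is available as an alternative).
Predictions with an empty fingerprint are dropped from pooling by
default — comparing "no interactions" to a native histogram is
reported as missing, not zero — with the dropped count visible in the
per-target rows. The matching score WM = 1 − (EMD − EMDmin)/(EMDmax −
EMDmin) is computed across exactly the methods present in a report run;
when all defined distances coincide every method scores 1 (degenerate
convention), and methods with no defined distance are reported missing
and excluded from the min/max.

## Validity checks

The PB-Valid flag is the conjunction of: RDKit sanitization of the pose
graph; bond lengths within ±25% of template-idealized values (ideal
geometry from a seeded distance-geometry embed + MMFF minimization of
the template); bond angles within ±25°; aromatic-ring out-of-plane
deviation ≤ 0.25 Å; and clash-freedom — non-bonded heavy-atom pairs no
closer than the sum of Bondi van der Waals radii minus a 0.5 Å
tolerance, applied within the ligand (pairs separated by ≥ 4 bonds),
against the protein, and between ligand fragments. Force-field
energy-ratio inspection is intentionally not part of the default flag;
externally computed validity flags can be imported when exact parity
with the external checking suite matters, because that suite's exact
check set and version can differ between studies. The enabled checks
and tolerances appear in every report.

The interligand clash rate of a multiligand dataset is the fraction of
targets whose prediction contains at least one fragment–fragment vdW
clash.

## Benchmark aggregation

Success rates are percentages per run; the default denominator is all
manifest targets, so excluded predictions count as failures (the
conservative convention — reporting over scored-only targets is
selectable and recorded). Mean ± s.d. across runs uses the sample
(n − 1) convention by default, population s.d. selectable; a single
run reports s.d. 0. Reports are a per-target CSV and an aggregate JSON
carrying the package version, full config provenance, the seed, and
the fingerprint bin-order statement.

## Synthetic test surface

The fixtures module builds an ideal poly-alanine α-helix (φ = −57°,
ψ = −47°, ω = 180°, standard bond lengths and angles, assembled by
internal-coordinate chaining) and places distance-geometry-embedded
ligands against its face, pushed outward until no protein–ligand pair
is closer than 3.4 Å, which guarantees a non-empty 10 Å binding site
and a clash-free reference. Perturbations are exact rigid motions plus
optional Gaussian jitter, so ground-truth values are known in closed
form (a pure translation of magnitude d must score RMSD = d exactly;
jitter of s.d. σ on many atoms must score ≈ √3·σ by the χ distribution).
Mock methods add a per-ligand rigid offset of magnitude
error_scale × (0.5 + |N(0,1)|) — zero error always succeeds, 25 Å error
never does — plus one random global rigid motion of the whole complex
that a correct pocket alignment must undo exactly. Generation is
byte-deterministic under a fixed seed.

What this surface does *not* emulate: real side-chain chemistry (the
scaffold is poly-alanine, so fingerprints on fixtures are
hydrophobic/backbone-dominated), induced fit and conformational change,
crystallographic artefacts, and ligand strain. Passing these tests
demonstrates that the scoring machinery is numerically correct and
self-consistent, not that any particular docking method is good; tests
of interaction typing against richer chemistry use purpose-built
geometries (constructed H-bond, π-stack and salt-bridge examples)
rather than the helix fixtures.

The default problem sizes (10–target mock benchmarks, 3 methods,
3 runs; 200 histogram pairs and 50 toys for oracle sweeps) keep the
whole verification suite in the seconds range while exercising every
code path; all are parameters, not constants.

## Numerical notes

- Kabsch: SVD with determinant correction; degenerate (rank < 2) point
  sets raise instead of returning an arbitrary rotation.
- lDDT: strict `<` at both the inclusion radius and the thresholds,
  matching the step-function definition.
- EMD: exact closed form, no iterative solver; the linear-programming
  transport oracle exists only in the test suite.
- Ties: alt-locs (first occurrence), equal-identity chain assignments
  (pocket-fit RMSD), identical fragment copies (minimum symmetry-
  corrected RMSD), all deterministic.
- Seeds: every stochastic component (embedding, jitter, mock methods)
  takes an explicit seed; derived seeds stay below 2³¹.

## Known limitations

- Validity bond/angle ideals come from one embedded conformer of the
  template; for highly flexible rings the ±25% / ±25° envelopes are
  generous rather than conformer-aware.
- Hydrogen-bond detection is distance-only when explicit hydrogens are
  absent, which over-counts borderline geometries relative to tools
  that place hydrogens.
- The interface-lDDT contact radius and threshold pooling follow the
  plain lDDT definition; assessors that used a tighter interface radius
  will produce systematically lower scores (the radius is a config
  field for exactly this reason).
- Sequence-identity chain pairing assumes globally alignable chains; it
  does not handle circular permutations or chimeric constructs.
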