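# poselens

Evaluation toolkit for protein–ligand docking and cofolding predictions.

Blind-docking and cofolding methods (conventional docking, diffusion
docking, all-atom cofolding networks) are usually compared on how often
their top-ranked ligand pose lands within 2 Å of the crystallized pose.
That single number hides two other questions a medicinal chemist cares
about: is the predicted molecule *chemically sane*, and does it make the
*right interactions* with the right amino acids? `poselens` implements
the full scoring stack needed to answer all three at benchmark scale:

- **Pocket-focused alignment.** The binding site is every residue with a
  heavy atom within 10 Å of any crystallized ligand heavy atom; the
  predicted complex is superposed onto the reference by a Kabsch fit on
  those residues (chain correspondence by sequence alignment, with
  Hungarian/exhaustive tie-breaking for homo-oligomers). Ligands are
  never refit independently, so placement errors survive the alignment.
- **Symmetry-corrected RMSD.** For a pose with heavy-atom positions x̂ᵢ
  against crystal positions xᵢ,

  ```
  r.m.s.d. = sqrt( (1/n) Σᵢ ‖x̂ᵢ − xᵢ‖² )
  ```

  minimized over all graph automorphisms of the ligand template, so a
  benzene rotated 60° in place scores 0 Å. Success criteria:
  r.m.s.d. ≤ 2 Å (structural accuracy), heavy-atom centroid distance
  ≤ 1 Å (pocket identification), and r.m.s.d. ≤ 2 Å *and* PB-Valid
  (structurally accurate and chemically sane).
- **lDDT and lDDT-PLI.** The superposition-free local distance
  difference test (inclusion radius R₀ = 15 Å, tolerance thresholds
  0.5/1/2/4 Å, same-residue pairs excluded), and its interface variant
  restricted to protein–ligand cross pairs for multiligand targets.
- **PB-Valid.** A documented, reproducible subset of pose-busting
  sanity checks: graph sanitization, bond lengths within ±25% of
  template-idealized values, angles within ±25°, aromatic ring
  flatness ≤ 0.25 Å, and van-der-Waals clash tests within the ligand,
  against the protein, and between ligand fragments.
- **PLIF-EMD / PLIF-WM.** Interactions are detected geometrically
  (hydrogen bonds, hydrophobic contacts, salt bridges, π-stacking,
  π-cation, halogen bonds, metal coordination) and counted as
  fingerprint tuples ⟨ligand type, amino-acid type, interaction type⟩.
  The predicted histogram **u** is compared with the native histogram
  **v** by the 1-Wasserstein distance on their unified support
  (PLIF-EMD), and per-method distances are min–max normalized across
  the methods being compared into a 0–1 matching score,

  ```
  PLIF-WM = 1 − (EMD − EMD_min) / (EMD_max − EMD_min)
  ```

  so the method with the most native-like interaction profile scores 1.
- **Benchmark aggregation.** Per-target scores roll up into per-method
  success rates reported as mean ± s.d. across independent runs, with
  excluded (unparseable or template-mismatched) predictions counted as
  failures by default and every threshold echoed into the report.

A deterministic fixtures module generates toy complexes — an ideal
poly-alanine helix with distance-geometry-embedded ligands — plus
controlled perturbations and mock "methods" of known error scale, so
the whole stack is testable without downloading a single structure.

## Worked example

Generate a 4-target toy benchmark with three mock predictors (perfect,
1.5 Å error scale, 25 Å error scale) and score it:

```bash
poselens fixtures make --seed 7 --out toydemo --targets 4 --runs 3
poselens score --manifest toydemo/manifest.yaml \
    --predictions toydemo/predictions \
    --methods exact,noisy,bad --runs 3 --out toydemo/report --seed 7
```

which prints

```
bad: rmsd<=2 & valid 0.0% +/- 0.0%, PLIF-WM None
exact: rmsd<=2 & valid 100.0% +/- 0.0%, PLIF-WM 1.000
noisy: rmsd<=2 & valid 66.7% +/- 14.4%, PLIF-WM 1.000
```

The perfect predictor recovers every pose (100% at r.m.s.d. ≤ 2 Å and
PB-Valid); the 1.5 Å-error predictor lands about two thirds of its
poses, with run-to-run spread reported as the sample s.d.; the 25 Å
predictor never finds the pocket, and because its poses make no
protein contacts at all, its interaction fingerprint is empty and its
PLIF-WM is reported as missing rather than faked. `toydemo/report/`
then contains `per_target_metrics.csv` (one row per target × method ×
run, with RMSD, centroid RMSD, interface lDDT, validity flags and
per-target PLIF-EMD) and `summary.json` (the aggregate table plus the
full threshold provenance and seed).

The same pipeline runs on real data: point the manifest at reference
PDB/mmCIF + SDF files with template SMILES and ligand roles, and lay
predictions out as `<dataset>/<method>/run_<k>/<target>_protein.pdb`
with `<target>_ligands.sdf` beside it.

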