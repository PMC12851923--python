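"""Benchmark orchestration: evaluate prediction sets against a manifest
and aggregate per-target scores into per-method tables.

The evaluation pipeline per target and prediction is: load → chain and
residue correspondence → pocket-focused alignment → primary-ligand
extraction (or multiligand assignment) → symmetry-corrected RMSD and
centroid RMSD → validity checks → interface lDDT → interaction
fingerprints and their Wasserstein distance to the native fingerprint.
Unparseable or template-mismatched predictions become excluded rows
with a machine-readable reason; they never abort a run.

Success rates are reported per run and summarized as mean ± s.d. across
runs. By default excluded predictions count as failures over the full
manifest denominator (the conservative reading); a scored-only
denominator is selectable. The per-method Wasserstein matching score is
min–max normalized across exactly the methods present in the run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import ComplexRecord, Manifest, TemplateMismatchError
from .lddt import LddtConfig, UndefinedScoreError, lddt_pli
from .plif import InteractionConfig, complex_fingerprint
from .plif_score import EmptyHistogramError, plif_emd, plif_wm, pool_emds
from .pocket_align import (
    BindingSite,
    CorrespondenceError,
    DegenerateAlignmentError,
    EmptySiteError,
    align_to_pocket,
    build_correspondence,
    select_binding_site,
)
from .pose_metrics import (
    DEFAULT_AUTOMORPHISM_CAP,
    ExtractionError,
    centroid_rmsd,
    ligand_rmsd,
)
from .structio import load_complex, read_ligands, read_protein
from .validity import ValidityConfig, check_pose_validity, has_interligand_clash

CRITERIA = ("centroid_le_1", "rmsd_le_2", "rmsd_le_2_and_pb_valid")


@dataclass(frozen=True)
class EvalConfig:
    site_cutoff: float = 10.0
    min_chain_identity: float = 0.30
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP
    lddt: LddtConfig = field(default_factory=lambda: LddtConfig(interface_only=True))
    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    denominator: str = "all"  # "all" counts exclusions as failures; or "scored"
    sd_convention: str = "sample"  # "sample" (n-1) or "population"
    emd_pooling: str = "mean"  # per-method EMD: "mean" of per-target, or "pooled"
    drop_empty_fingerprints: bool = True

    def __post_init__(self) -> None:
        if self.denominator not in ("all", "scored"):
            raise ValueError("denominator must be 'all' or 'scored'")
        if self.sd_convention not in ("sample", "population"):
            raise ValueError("sd_convention must be 'sample' or 'population'")
        if self.emd_pooling not in ("mean", "pooled"):
            raise ValueError("emd_pooling must be 'mean' or 'pooled'")

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MetricRow:
    target_id: str
    method: str
    run: int
    status: str = "scored"  # or "excluded:<reason>"
    rmsd: float = math.nan
    centroid_rmsd: float = math.nan
    pb_valid: bool = False
    lddt_pli: Optional[float] = None
    plif_emd: Optional[float] = None
    pocket_fit_rmsd: float = math.nan
    interligand_clash: Optional[bool] = None  # None for single-ligand targets
    symmetry_fallback: bool = False

    @property
    def scored(self) -> bool:
        return self.status == "scored"

    @property
    def rmsd_le_2(self) -> bool:
        return self.scored and self.rmsd <= 2.0

    @property
    def centroid_le_1(self) -> bool:
        return self.scored and self.centroid_rmsd <= 1.0

    @property
    def success(self) -> bool:
        return self.rmsd_le_2 and self.pb_valid

    def as_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "method": self.method,
            "run": self.run,
            "status": self.status,
            "rmsd": self.rmsd,
            "centroid_rmsd": self.centroid_rmsd,
            "rmsd_le_2": self.rmsd_le_2,
            "centroid_le_1": self.centroid_le_1,
            "pb_valid": self.pb_valid,
            "rmsd_le_2_and_pb_valid": self.success,
            "lddt_pli": self.lddt_pli,
            "plif_emd": self.plif_emd,
            "pocket_fit_rmsd": self.pocket_fit_rmsd,
            "interligand_clash": self.interligand_clash,
            "symmetry_fallback": self.symmetry_fallback,
        }


@dataclass
class MethodAggregate:
    rates: dict[str, tuple[float, float]]  # criterion -> (mean %, sd %)
    plif_emd: Optional[float]
    plif_wm: Optional[float] = None
    mean_lddt_pli: Optional[float] = None
    interligand_clash_rate: Optional[float] = None
    n_excluded: int = 0


@dataclass
class BenchmarkTable:
    methods: dict[str, MethodAggregate]
    n_targets: int
    n_runs: int
    denominator: str
    sd_convention: str


# ---------------------------------------------------------------------------
# reference preparation
# ---------------------------------------------------------------------------

@dataclass
class _ReferenceContext:
    record: ComplexRecord
    site: BindingSite
    native_fingerprint: object  # PlifHistogram


def _prepare_references(manifest: Manifest, cfg: EvalConfig) -> dict[str, _ReferenceContext]:
    contexts = {}
    for entry in manifest.entries:
        record = load_complex(entry, manifest.dataset)  # missing files: hard error
        site = select_binding_site(record, cfg.site_cutoff)
        native = complex_fingerprint(
            record.protein, record.ligands, cfg.interactions, key_by="template"
        )
        contexts[entry.target_id] = _ReferenceContext(record, site, native)
    return contexts


# ---------------------------------------------------------------------------
# single-prediction scoring
# ---------------------------------------------------------------------------

def score_prediction(
    predicted: ComplexRecord,
    ref_ctx: _ReferenceContext,
    cfg: EvalConfig,
    method: str = "",
    run: int = 1,
) -> MetricRow:
    """Score one predicted complex against its reference context."""
    reference = ref_ctx.record
    row = MetricRow(target_id=reference.target_id, method=method, run=run)
    try:
        corr = build_correspondence(
            predicted, reference, cfg.min_chain_identity, site=ref_ctx.site
        )
        aligned, fit_rmsd = align_to_pocket(predicted, reference, ref_ctx.site, corr)
        row.pocket_fit_rmsd = fit_rmsd

        ref_primary = reference.primary_ligand
        if ref_primary is not None:
            from .pose_metrics import extract_primary

            pose, _ = extract_primary(aligned, reference, cfg.automorphism_cap)
            row.rmsd, row.symmetry_fallback = ligand_rmsd(
                pose, ref_primary, cfg.automorphism_cap
            )
            row.centroid_rmsd = centroid_rmsd(pose, ref_primary)
            reports = check_pose_validity(aligned, cfg.validity)
            row.pb_valid = reports[pose.ligand_id].pb_valid
        else:
            # multiligand target: score the assigned fragments jointly
            from .pose_metrics import assign_fragments

            pairs = assign_fragments(aligned.ligands, reference.ligands)
            if not pairs:
                row.status = "excluded:no_fragment_assignment"
                return row
            rmsds, fallbacks = [], []
            for i, j in pairs:
                r, fb = ligand_rmsd(
                    aligned.ligands[i], reference.ligands[j], cfg.automorphism_cap
                )
                rmsds.append(r)
                fallbacks.append(fb)
            row.rmsd = float(np.mean(rmsds))
            row.symmetry_fallback = any(fallbacks)
            pred_cent = np.mean([aligned.ligands[i].centroid() for i, _ in pairs], axis=0)
            ref_cent = np.mean([reference.ligands[j].centroid() for _, j in pairs], axis=0)
            row.centroid_rmsd = float(np.linalg.norm(pred_cent - ref_cent))
            reports = check_pose_validity(aligned, cfg.validity)
            row.pb_valid = all(r.pb_valid for r in reports.values())

        row.interligand_clash = (
            has_interligand_clash(aligned.ligands, cfg.validity)
            if len(aligned.ligands) >= 2 else None
        )

        try:
            row.lddt_pli = lddt_pli(aligned, reference, corr, cfg.lddt)
        except UndefinedScoreError:
            row.lddt_pli = None

        pred_fp = complex_fingerprint(
            aligned.protein, aligned.ligands, cfg.interactions, key_by="template"
        )
        try:
            if pred_fp or not cfg.drop_empty_fingerprints:
                row.plif_emd = plif_emd(pred_fp, ref_ctx.native_fingerprint)
            else:
                row.plif_emd = None
        except EmptyHistogramError:
            row.plif_emd = None
    except TemplateMismatchError:
        row.status = "excluded:template_mismatch"
    except ExtractionError:
        row.status = "excluded:extraction_error"
    except CorrespondenceError:
        row.status = "excluded:correspondence_error"
    except (DegenerateAlignmentError, EmptySiteError):
        row.status = "excluded:degenerate_alignment"
    return row


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def evaluate_dataset(
    manifest: Manifest,
    predictions_root: Path | str,
    methods: Sequence[str],
    n_runs: int,
    cfg: EvalConfig = EvalConfig(),
) -> list[MetricRow]:
    """Evaluate every method/run/target found under ``predictions_root``.

    Predictions are discovered at
    ``<root>/<dataset>/<method>/run_<k>/<target>_protein.pdb`` with the
    ligands beside it as ``<target>_ligands.sdf``. Missing or broken
    predictions yield excluded rows; missing *reference* files raise.
    """
    root = Path(predictions_root)
    contexts = _prepare_references(manifest, cfg)
    rows: list[MetricRow] = []
    for method in methods:
        for run in range(1, n_runs + 1):
            run_dir = root / manifest.dataset / method / f"run_{run}"
            for entry in manifest.entries:
                ctx = contexts[entry.target_id]
                ppath = run_dir / f"{entry.target_id}_protein.pdb"
                lpath = run_dir / f"{entry.target_id}_ligands.sdf"
                if not ppath.is_file() or not lpath.is_file():
                    rows.append(MetricRow(
                        entry.target_id, method, run, status="excluded:missing_prediction"
                    ))
                    continue
                try:
                    protein = read_protein(ppath)
                    ids = list(entry.ligand_ids) or None
                    ligands = read_ligands(
                        lpath, entry.ligand_smiles, ids, entry.ligand_roles
                    )
                    predicted = ComplexRecord(
                        target_id=entry.target_id,
                        protein=protein,
                        ligands=ligands,
                        primary_ligand_id=ctx.record.primary_ligand_id,
                        dataset=manifest.dataset,
                    )
                except TemplateMismatchError:
                    rows.append(MetricRow(
                        entry.target_id, method, run, status="excluded:template_mismatch"
                    ))
                    continue
                except (IOError, ValueError):
                    rows.append(MetricRow(
                        entry.target_id, method, run, status="excluded:parse_error"
                    ))
                    continue
                rows.append(score_prediction(predicted, ctx, cfg, method, run))
    return rows


def evaluate_records(
    predictions: dict[str, dict[int, list[ComplexRecord]]],
    references: Sequence[ComplexRecord],
    cfg: EvalConfig = EvalConfig(),
) -> list[MetricRow]:
    """In-memory variant of :func:`evaluate_dataset` for already-loaded
    prediction records (used by the fixtures pipeline and tests)."""
    contexts = {}
    for record in references:
        site = select_binding_site(record, cfg.site_cutoff)
        native = complex_fingerprint(
            record.protein, record.ligands, cfg.interactions, key_by="template"
        )
        contexts[record.target_id] = _ReferenceContext(record, site, native)
    rows = []
    for method, runs in predictions.items():
        for run, records in runs.items():
            for predicted in records:
                rows.append(
                    score_prediction(predicted, contexts[predicted.target_id], cfg, method, run)
                )
    return rows


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _criterion_flag(row: MetricRow, criterion: str) -> bool:
    if criterion == "centroid_le_1":
        return row.centroid_le_1
    if criterion == "rmsd_le_2":
        return row.rmsd_le_2
    if criterion == "rmsd_le_2_and_pb_valid":
        return row.success
    raise KeyError(criterion)


def _mean_sd(values: Sequence[float], convention: str) -> tuple[float, float]:
    arr = np.asarray(values, float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, 0.0
    ddof = 1 if convention == "sample" else 0
    return mean, float(arr.std(ddof=ddof))


def aggregate(
    rows: Sequence[MetricRow],
    n_targets: Optional[int] = None,
    cfg: EvalConfig = EvalConfig(),
) -> BenchmarkTable:
    """Per-method success rates (mean ± s.d. over runs) and PLIF scores."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to aggregate")
    methods = sorted({r.method for r in rows})
    runs = sorted({r.run for r in rows})
    if n_targets is None:
        n_targets = len({r.target_id for r in rows})
    if n_targets == 0:
        raise ValueError("zero targets")

    table: dict[str, MethodAggregate] = {}
    for method in methods:
        m_rows = [r for r in rows if r.method == method]
        rates: dict[str, tuple[float, float]] = {}
        for criterion in CRITERIA:
            per_run = []
            for run in runs:
                run_rows = [r for r in m_rows if r.run == run]
                denom = (
                    n_targets if cfg.denominator == "all"
                    else sum(r.scored for r in run_rows)
                )
                hits = sum(_criterion_flag(r, criterion) for r in run_rows)
                per_run.append(100.0 * hits / denom if denom else 0.0)
            rates[criterion] = _mean_sd(per_run, cfg.sd_convention)

        emds = [r.plif_emd for r in m_rows if r.scored]
        method_emd = pool_emds(emds)
        lddts = [r.lddt_pli for r in m_rows if r.scored and r.lddt_pli is not None]
        multi = [
            r for r in m_rows if r.scored and r.interligand_clash is not None
        ]  # multiligand targets only
        clash_rate = (
            float(np.mean([r.interligand_clash for r in multi])) if multi else None
        )
        table[method] = MethodAggregate(
            rates=rates,
            plif_emd=method_emd,
            mean_lddt_pli=float(np.mean(lddts)) if lddts else None,
            interligand_clash_rate=clash_rate,
            n_excluded=sum(not r.scored for r in m_rows),
        )

    emd_by_method = {m: table[m].plif_emd for m in methods}
    if any(e is not None for e in emd_by_method.values()):
        wm = plif_wm(emd_by_method)
        for method in methods:
            table[method].plif_wm = wm[method]

    return BenchmarkTable(
        methods=table,
        n_targets=n_targets,
        n_runs=len(runs),
        denominator=cfg.denominator,
        sd_convention=cfg.sd_convention,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

class UnsupportedFormatError(ValueError):
    pass


def rows_to_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


def table_to_dict(table: BenchmarkTable) -> dict:
    return {
        "n_targets": table.n_targets,
        "n_runs": table.n_runs,
        "denominator": table.denominator,
        "sd_convention": table.sd_convention,
        "methods": {
            m: {
                "rates": {
                    c: {"mean": mu, "sd": sd} for c, (mu, sd) in agg.rates.items()
                },
                "plif_emd": agg.plif_emd,
                "plif_wm": agg.plif_wm,
                "mean_lddt_pli": agg.mean_lddt_pli,
                "interligand_clash_rate": agg.interligand_clash_rate,
                "n_excluded": agg.n_excluded,
            }
            for m, agg in sorted(table.methods.items())
        },
    }


def report(
    table: BenchmarkTable,
    rows: Sequence[MetricRow],
    out_dir: Path | str,
    cfg: EvalConfig = EvalConfig(),
    fmt: str = "csv+json",
    seed: Optional[int] = None,
    timestamp: bool = True,
) -> dict[str, Path]:
    """Write the per-target CSV and the aggregate JSON with provenance."""
    if fmt not in ("csv", "json", "csv+json"):
        raise UnsupportedFormatError(f"unsupported report format: {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "csv" in fmt:
        csv_path = out_dir / "per_target_metrics.csv"
        rows_to_frame(rows).to_csv(csv_path, index=False)
        written["csv"] = csv_path
    if "json" in fmt:
        payload = {
            "poselens_version": __version__,
            "summary": table_to_dict(table),
            "config": cfg.provenance(),
            "seed": seed,
            "bin_order": "lexicographic on (ligand type, residue type, interaction type)",
        }
        if timestamp:
            payload["timestamp"] = datetime.now(timezone.utc).isoformat()
        json_path = out_dir / "summary.json"
        json_path.write_text(json.dumps(payload, indent=2, sort_keys=False))
        written["json"] = json_path
    return written
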