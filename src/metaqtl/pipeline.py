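"""Configuration-driven orchestration of the full meta-QTL analysis.

Stage order: harmonize -> CI recalibration -> consensus-map merge ->
projection -> per-chromosome mixture meta-analysis -> physical anchoring ->
GWAS validation -> breeder's / high-confidence screening -> candidate-gene
mining.  Every stage persists its output as TSV in the configured output
directory, and the run ends with a summary of counts and CI statistics plus
an effective-config echo for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import genes as genes_mod
from . import meta as meta_mod
from . import projection as proj_mod
from . import qtl_data
from . import screening as screen_mod
from .qtl_data import QTLRecord
from .screening import ScreeningThresholds

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "score_recovery"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and tunables of one pipeline run."""

    qtl_table: str = ""
    maps_table: str = ""
    marker_physical: str = ""
    mta_table: str = ""
    gene_annotation: str = ""
    ortholog_table: str = ""
    trait_vocabulary: str = ""   # empty = packaged default
    outdir: str = "metaqtl_out"

    seed: int = 0
    k_max: int = 20
    em_restarts: int = 10
    em_max_iter: int = 500
    em_tol: float = 1e-8
    membership: str = "soft"
    max_interval: int = 1
    use_reported_ci: bool = False
    recalc_imputed_ci: bool = False  # imputed-PVE records keep reported CIs
    require_trait_match: bool = False

    breeders_ci_cM: float = 2.0
    breeders_pve: float = 10.0
    breeders_min_qtl: int = 4
    hc_ci_cM: float = 1.0
    hc_span_mb: float = 20.0
    hc_min_qtl: int = 5
    direct_region_mb: float = 2.0
    peak_flank_mb: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k_max", "em_restarts", "em_max_iter", "max_interval",
            "breeders_min_qtl", "hc_min_qtl",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "em_tol", "breeders_ci_cM", "breeders_pve", "hc_ci_cM",
            "hc_span_mb", "direct_region_mb", "peak_flank_mb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.membership not in ("soft", "hard"):
            raise ValueError("membership must be 'soft' or 'hard'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> ScreeningThresholds:
        return ScreeningThresholds(
            breeders_ci_cM=self.breeders_ci_cM,
            breeders_pve=self.breeders_pve,
            breeders_min_qtl=self.breeders_min_qtl,
            hc_ci_cM=self.hc_ci_cM,
            hc_span_mb=self.hc_span_mb,
            hc_min_qtl=self.hc_min_qtl,
            direct_region_mb=self.direct_region_mb,
            peak_flank_mb=self.peak_flank_mb,
            require_trait_match=self.require_trait_match,
        )

    def meta_config(self) -> meta_mod.MetaConfig:
        return meta_mod.MetaConfig(
            k_max=self.k_max,
            restarts=self.em_restarts,
            max_iter=self.em_max_iter,
            tol=self.em_tol,
            seed=self.seed,
            membership=self.membership,  # type: ignore[arg-type]
        )


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the summary."""

    config: PipelineConfig
    records: list[QTLRecord]
    consensus: cons.ConsensusMap
    projected: list[proj_mod.ProjectedQTL]
    chromosome_results: list[meta_mod.ChromosomeResult]
    screened: list[screen_mod.ScreenedMQTL]
    candidates: pd.DataFrame
    summary: dict[str, Any]

    @property
    def mqtls(self) -> list[meta_mod.MQTL]:
        return [m for r in self.chromosome_results for m in r.mqtls]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- harmonize + impute + CI recalibration
    vocab = (
        qtl_data.TraitVocabulary.from_tsv(config.trait_vocabulary)
        if config.trait_vocabulary
        else qtl_data.default_trait_vocabulary()
    )
    report = qtl_data.read_qtl_table(config.qtl_table, vocab)
    if not report.records:
        raise RuntimeError("harmonize stage: no usable QTL records in input")
    records = [qtl_data.impute_missing(r) for r in report.records]
    if not config.use_reported_ci:
        records = [
            qtl_data.apply_ci_recalculation(
                r, skip_imputed=not config.recalc_imputed_ci
            )
            for r in records
        ]
    qtl_data.write_qtl_table(records, outdir / "harmonized_qtl.tsv")

    # ---- consensus map
    maps = cons.read_genetic_maps(config.maps_table)
    consensus = cons.merge_all_chromosomes(maps, config.max_interval)
    consensus.write(outdir / "consensus_map.tsv", outdir / "removed_constraints.tsv")
    cons.map_summary(consensus).to_csv(outdir / "map_summary.tsv", sep="\t", index=False)

    # ---- projection
    study_maps = {m.map_id: m for m in maps}
    projected = proj_mod.project_all(records, study_maps, consensus)
    proj_mod.write_projected(projected, outdir / "projected_qtl.tsv")

    # ---- meta-analysis per chromosome
    usable = [p for p in projected if p.projectable]
    chrom_results = run_meta_stage(projected, config.meta_config())
    mqtls = [m for r in chrom_results for m in r.mqtls]
    meta_mod.mqtl_to_frame(mqtls).to_csv(
        outdir / "mqtl.tsv", sep="\t", index=False, float_format="%.17g"
    )
    criteria_frames = []
    for res in chrom_results:
        tab = res.criteria.reset_index()
        tab.insert(0, "chrom", res.chromosome)
        criteria_frames.append(tab)
    pd.concat(criteria_frames, ignore_index=True).to_csv(
        outdir / "criteria.tsv", sep="\t", index=False
    )

    # ---- anchoring, validation, screening
    physical = qtl_data.read_marker_physical(config.marker_physical)
    screened = screen_mod.anchor_all(mqtls, consensus, physical)
    mtas = screen_mod.read_mta_table(config.mta_table) if config.mta_table else []
    screen_mod.validate_gwas(
        screened, mtas, require_trait_match=config.require_trait_match
    )
    thresholds = config.thresholds()
    breeders = screen_mod.screen_breeders(screened, thresholds)
    hc = screen_mod.screen_hc(screened, thresholds)
    screen_mod.screened_to_frame(screened).to_csv(
        outdir / "screened_mqtl.tsv", sep="\t", index=False
    )
    screen_mod.mining_regions_to_bed(hc, outdir / "mining_regions.bed")

    # ---- candidate genes
    if config.gene_annotation and config.ortholog_table:
        annotation = genes_mod.read_gene_annotation(config.gene_annotation)
        orthologs = genes_mod.read_ortholog_table(config.ortholog_table)
        candidates = genes_mod.ortholog_candidates(hc, annotation, orthologs)
    else:
        candidates = pd.DataFrame()
    candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)

    # ---- summary
    unintegrated = [p for r in chrom_results for p in r.unassigned]
    integrated = [p for m in mqtls for p in m.members]
    mean_initial_ci = (
        float(np.mean([p.proj_ci_width for p in usable])) if usable else np.nan
    )
    mean_mqtl_ci = float(np.mean([m.ci_width for m in mqtls])) if mqtls else np.nan
    summary: dict[str, Any] = {
        "n_qtl_in": report.n_rows,
        "n_trait_excluded": report.n_excluded,
        "n_records": len(records),
        "n_projected": len(usable),
        "n_unprojectable": len(projected) - len(usable),
        "n_integrated": len(integrated),
        "n_unintegrated": len(unintegrated),
        "n_mqtl": len(mqtls),
        "n_markers_consensus": int(len(consensus.entries)),
        "n_removed_constraints": len(consensus.removed_constraints),
        "mean_initial_ci_cM": mean_initial_ci,
        "mean_mqtl_ci_cM": mean_mqtl_ci,
        "fold_narrowing": (
            mean_initial_ci / mean_mqtl_ci if mqtls and mean_mqtl_ci > 0 else np.nan
        ),
        "n_validated": sum(s.is_validated for s in screened),
        "n_breeders": len(breeders),
        "n_hc": len(hc),
        "n_candidate_genes": (
            int(candidates["barley_gene_id"].nunique()) if len(candidates) else 0
        ),
        "n_candidate_rows": int(len(candidates)),
        "qtl_per_class": _count_by(records, lambda r: r.trait_class),
        "qtl_per_chromosome": _count_by(records, lambda r: r.chromosome),
        "mqtl_per_chromosome": _count_by(mqtls, lambda m: m.chromosome),
        "k_selected": {r.chromosome: r.k_selected for r in chrom_results},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    return PipelineResult(
        config=config,
        records=records,
        consensus=consensus,
        projected=projected,
        chromosome_results=chrom_results,
        screened=screened,
        candidates=candidates,
        summary=summary,
    )


def run_meta_stage(
    projected: list[proj_mod.ProjectedQTL], meta_config: meta_mod.MetaConfig
) -> list[meta_mod.ChromosomeResult]:
    """Per-chromosome mixture meta-analysis of all projectable QTL."""
    usable = [p for p in projected if p.projectable]
    results = []
    for chrom in sorted({p.chromosome for p in usable}):
        on_chrom = [p for p in usable if p.chromosome == chrom]
        results.append(meta_mod.run_chromosome(on_chrom, meta_config))
    return results


def rebuild_mqtls(
    mqtl_table: str | Path, projected: list[proj_mod.ProjectedQTL]
) -> list[meta_mod.MQTL]:
    """Reconstruct MQTL objects from a persisted MQTL table and the
    projected-QTL table its members reference — lets the screening and gene
    stages rerun from intermediates."""
    by_id = {p.record.qtl_id: p for p in projected}
    df = pd.read_csv(
        mqtl_table, sep="\t", float_precision="round_trip",
        dtype={"name": str, "chrom": str},
    )
    out = []
    for r in df.itertuples(index=False):
        members = [by_id[q] for q in str(r.member_qtl_ids).split(";") if q in by_id]
        out.append(
            meta_mod.MQTL(
                name=str(r.name),
                chromosome=str(r.chrom),
                position=float(r.pos_cM),
                ci_lo=float(r.ci_lo),
                ci_hi=float(r.ci_hi),
                members=members,
                mean_lod=float(r.mean_lod),
                mean_pve=float(r.mean_pve),
            )
        )
    return out


def _count_by(items, key) -> dict[str, int]:
    out: dict[str, int] = {}
    for it in items:
        k = key(it)
        out[k] = out.get(k, 0) + 1
    return dict(sorted(out.items()))


def score_recovery(
    true_mqtl: pd.DataFrame, result: PipelineResult
) -> dict[str, float]:
    """Score a run against known truth (synthetic data).

    Per chromosome: whether the selected K equals the number of true MQTL;
    per true MQTL: the distance to the nearest estimated MQTL.  Returns the
    fraction of chromosomes with the correct K, the mean absolute position
    error (cM), and the CI-narrowing ratio of the run.
    """
    k_hits, k_total = 0, 0
    errors: list[float] = []
    est_by_chrom: dict[str, list[float]] = {}
    for r in result.chromosome_results:
        est_by_chrom[r.chromosome] = [m.position for m in r.mqtls]
        true_k = int((true_mqtl["chrom"] == r.chromosome).sum())
        k_total += 1
        if r.k_selected == true_k:
            k_hits += 1
    for t in true_mqtl.itertuples(index=False):
        est = est_by_chrom.get(str(t.chrom), [])
        if est:
            errors.append(min(abs(e - float(t.pos_cM)) for e in est))
    return {
        "k_accuracy": k_hits / k_total if k_total else float("nan"),
        "n_chromosomes": float(k_total),
        "mean_abs_position_error_cM": float(np.mean(errors)) if errors else float("nan"),
        "fold_narrowing": float(result.summary["fold_narrowing"]),
    }
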