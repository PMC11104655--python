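"""Synthetic meta-QTL study generator with known ground truth.

Real meta-QTL inputs are tables curated from dozens of publications.  This
module generates statistically structured stand-ins for all of them — a true
genome (markers with a monotone cM<->bp correspondence), per-study linkage
maps, an initial-QTL table, GWAS marker-trait associations, a gene
annotation and an ortholog table — from a single seed, so that every
pipeline stage is testable offline and parameter recovery can be scored
against known truth.

What the generator emulates:

* mapping-population types in the proportions of published barley yield
  studies (10 BC : 27 DH : 43 RIL) with sizes uniform in the printed ranges
  (BC 28-301, DH 72-312, RIL 35-300);
* QTL positions scattered around true MQTL with a per-record dispersion
  tied to the CI the record reports (the CI formula's width / 3.92), so the
  meta-analysis noise model is realistic;
* reported CIs equal to the population-size/PVE formula value times a
  lognormal distortion, so the CI-recalibration stage has real work to do;
* LOD and PVE distributions with the bulk of their mass at LOD 2-4 and
  PVE 3-12%, and configurable missingness;
* suppressed pericentromeric recombination: mid-chromosome cM advances
  slowly in bp terms, so QTL cluster sub-telomerically in physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .consensus import GeneticMap
from .genes import GeneAnnotation, GeneModel, ORTHOLOG_COLUMNS
from .qtl_data import (
    QTLRecord,
    TraitVocabulary,
    default_trait_vocabulary,
    recalc_ci,
    write_qtl_table,
    write_marker_physical,
)
from .screening import MTARecord, write_mta_table

__all__ = ["SyntheticConfig", "TruthSet", "simulate_truth", "simulate_studies",
           "simulate_mtas", "simulate_annotation", "simulate_all"]

MB = 1_000_000


@dataclass
class SyntheticConfig:
    """All knobs of the generator, with study-realistic defaults."""

    # genome
    n_chromosomes: int = 5
    chromosome_length_cM: float = 150.0
    chromosome_length_mb: float = 600.0
    n_markers_per_chrom: int = 120
    recomb_suppression: float = 0.5  # 0 = linear cM<->bp, ->1 = strong pericentromeric plateau

    # truth
    n_true_mqtl_per_chrom: int = 3
    min_separation_cM: float = 25.0

    # studies
    n_studies: int = 20
    n_qtl: int = 400
    pop_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"BC": 10, "DH": 27, "RIL": 43}
    )
    pop_size_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"BC": (28, 301), "DH": (72, 312), "RIL": (35, 300)}
    )
    study_marker_fraction: float = 0.5
    # component maps in the emulated study are high-quality consensus maps
    # whose residual disagreement is an order of magnitude below QTL
    # positional uncertainty; the default keeps that ratio at this package's
    # CI scale (median CI-implied sd ~0.07 cM)
    map_jitter_sd_cM: float = 0.005

    # QTL attribute distributions: lognormals fitted to the printed
    # frequency bins (PVE: ~46% of mass in 3-12%; LOD: ~65% in 2-4),
    # clipped to the observed extremes
    pve_median: float = 9.0
    pve_sigma: float = 1.1
    pve_range: tuple[float, float] = (0.26, 91.32)
    lod_median: float = 3.0
    lod_sigma: float = 0.35
    lod_range: tuple[float, float] = (1.02, 70.47)
    missing_rate: float = 0.02  # LOD/PVE unreported for a few records
    ci_distortion_sigma: float = 0.15

    # GWAS MTAs
    n_mtas: int = 120
    n_gwas_studies: int = 8
    mta_fp_rate: float = 0.3
    mta_window_mb: float = 1.0

    # annotation
    n_genes: int = 500
    gene_length_range_bp: tuple[int, int] = (2_000, 10_000)
    causal_fraction: float = 0.7
    n_decoy_orthologs: int = 30

    @property
    def chromosomes(self) -> list[str]:
        return [f"{i + 1}H" for i in range(self.n_chromosomes)]


@dataclass
class TruthSet:
    """Everything the generator knows: inputs plus the hidden truth."""

    config: SyntheticConfig
    seed: int
    truth_map: GeneticMap                      # the true marker map (cM)
    marker_physical: pd.DataFrame              # marker, chrom, bp
    true_mqtl: pd.DataFrame                    # mqtl_id, chrom, pos_cM, bp
    study_maps: dict[str, GeneticMap] = field(default_factory=dict)
    qtl_records: list[QTLRecord] = field(default_factory=list)
    qtl_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    mtas: list[MTARecord] = field(default_factory=list)
    mta_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    orthologs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(
            GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end),
                      getattr(r, "description", ""))
            for r in self.gene_table.itertuples(index=False)
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input table in the schema the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "qtl": outdir / "qtl_table.tsv",
            "maps": outdir / "study_maps.tsv",
            "physical": outdir / "marker_physical.tsv",
            "mta": outdir / "mta_table.tsv",
            "genes": outdir / "gene_annotation.tsv",
            "orthologs": outdir / "orthologs.tsv",
            "truth_mqtl": outdir / "truth_mqtl.tsv",
            "truth_qtl": outdir / "truth_qtl.tsv",
        }
        write_qtl_table(self.qtl_records, paths["qtl"])
        frames = []
        for map_id, gmap in sorted(self.study_maps.items()):
            df = gmap.entries.copy()
            df.insert(0, "map_id", map_id)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(paths["maps"], sep="\t", index=False)
        write_marker_physical(self.marker_physical, paths["physical"])
        write_mta_table(self.mtas, paths["mta"])
        self.gene_table.to_csv(paths["genes"], sep="\t", index=False)
        self.orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
        self.true_mqtl.to_csv(paths["truth_mqtl"], sep="\t", index=False)
        self.qtl_truth.to_csv(paths["truth_qtl"], sep="\t", index=False)
        return paths


def _cm_to_bp_fraction(u: np.ndarray, suppression: float) -> np.ndarray:
    """Monotone map of cM fraction to bp fraction.

    With suppression s in [0, 1), the exponent p = 1 - s < 1 makes a small
    mid-chromosome cM step cover a large bp distance (pericentromeric
    recombination suppression); s = 0 is the identity.
    """
    p = 1.0 - suppression
    t = 2.0 * np.asarray(u, dtype=float) - 1.0
    return 0.5 * (1.0 + np.sign(t) * np.abs(t) ** p)


def simulate_truth(config: SyntheticConfig, seed: int) -> TruthSet:
    """Generate the true genome: markers, cM<->bp map, true MQTL positions.

    True MQTL per chromosome are uniform over the feasible set of positions
    with pairwise separation >= ``min_separation_cM`` (error if infeasible).
    """
    rng = np.random.default_rng(seed)
    L = config.chromosome_length_cM
    K = config.n_true_mqtl_per_chrom
    sep = config.min_separation_cM
    if K > 1 and (K - 1) * sep > L:
        raise ValueError(
            f"cannot place {K} MQTL with separation {sep} cM on a {L} cM chromosome"
        )

    marker_rows, phys_rows, mqtl_rows = [], [], []
    for chrom in config.chromosomes:
        pos = np.sort(rng.uniform(0.0, L, size=config.n_markers_per_chrom))
        pos[0] = 0.0  # anchor the chromosome start
        names = [f"M{chrom}_{i:04d}" for i in range(len(pos))]
        bp = np.maximum(
            1,
            np.round(
                _cm_to_bp_fraction(pos / L, config.recomb_suppression)
                * config.chromosome_length_mb
                * MB
            ).astype(np.int64),
        )
        bp = np.maximum.accumulate(bp)  # guard rounding-induced ties only
        for n, p, b in zip(names, pos, bp):
            marker_rows.append({"marker": n, "chrom": chrom, "pos_cM": float(p)})
            phys_rows.append({"marker": n, "chrom": chrom, "bp": int(b)})
        if K > 0:
            slack = rng.uniform(0.0, L - (K - 1) * sep, size=K)
            mpos = np.sort(slack) + sep * np.arange(K)
            mbp = np.round(
                _cm_to_bp_fraction(mpos / L, config.recomb_suppression)
                * config.chromosome_length_mb
                * MB
            ).astype(np.int64)
            for i, (p, b) in enumerate(zip(mpos, mbp), start=1):
                mqtl_rows.append(
                    {
                        "mqtl_id": f"T{chrom}-{i}",
                        "chrom": chrom,
                        "pos_cM": float(p),
                        "bp": int(max(b, 1)),
                    }
                )

    truth_map = GeneticMap(
        "truth", pd.DataFrame(marker_rows)[["marker", "chrom", "pos_cM"]]
    )
    return TruthSet(
        config=config,
        seed=seed,
        truth_map=truth_map,
        marker_physical=pd.DataFrame(phys_rows, columns=["marker", "chrom", "bp"]),
        true_mqtl=pd.DataFrame(
            mqtl_rows, columns=["mqtl_id", "chrom", "pos_cM", "bp"]
        ),
    )


def _affine_transfer(pos: float, src: np.ndarray, dst: np.ndarray) -> float:
    """Piecewise-linear transfer of one coordinate between marker frames,
    extrapolating with the terminal interval beyond the marker span."""
    if pos <= src[0]:
        a, b = 0, 1
    elif pos >= src[-1]:
        a, b = len(src) - 2, len(src) - 1
    else:
        b = int(np.searchsorted(src, pos))
        a = b - 1
    if src[b] == src[a]:
        return float(dst[a])
    return float(dst[a] + (pos - src[a]) * (dst[b] - dst[a]) / (src[b] - src[a]))


def _lognormal(rng, median: float, sigma: float, lo: float, hi: float, size: int):
    return np.clip(rng.lognormal(np.log(median), sigma, size=size), lo, hi)


def simulate_studies(
    truth: TruthSet,
    seed: int,
    vocabulary: TraitVocabulary | None = None,
) -> TruthSet:
    """Draw study maps and the initial-QTL table around the true MQTL.

    Each study gets a population type (study-realistic proportions), a size
    uniform in that type's range, and a marker-subsample map with Gaussian
    positional jitter.  Each QTL picks a true MQTL uniformly; its reported
    position is expressed in *its own study map's* coordinates — the true
    position is first transferred onto the study map by interpolation
    between the study's bracketing markers (as a real QTL coordinate is
    tied to the study's own markers), then scattered by Normal(0, tau^2)
    with tau = formula CI width / 3.92 from the record's own n and PVE.
    The reported CI is the formula width times a lognormal distortion
    factor.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    vocabulary = vocabulary or default_trait_vocabulary()
    raw_names = vocabulary.raw_names
    L = cfg.chromosome_length_cM

    types = list(cfg.pop_type_weights)
    w = np.array([cfg.pop_type_weights[t] for t in types], dtype=float)
    w /= w.sum()

    study_ids = [f"S{j + 1:02d}" for j in range(cfg.n_studies)]
    study_type = {s: types[rng.choice(len(types), p=w)] for s in study_ids}
    study_size = {
        s: int(rng.integers(*cfg.pop_size_ranges[study_type[s]], endpoint=True))
        for s in study_ids
    }

    # study maps: marker subsample + jitter
    study_maps: dict[str, GeneticMap] = {}
    for s in study_ids:
        frames = []
        for chrom in cfg.chromosomes:
            sub = truth.truth_map.chromosome(chrom)
            n = len(sub)
            keep = max(2, int(round(cfg.study_marker_fraction * n)))
            idx = np.sort(rng.choice(n, size=keep, replace=False))
            pos = sub["pos_cM"].to_numpy()[idx] + rng.normal(
                0.0, cfg.map_jitter_sd_cM, size=keep
            )
            frames.append(
                pd.DataFrame(
                    {
                        "marker": sub["marker"].to_numpy()[idx],
                        "chrom": chrom,
                        "pos_cM": np.clip(pos, 0.0, None),
                    }
                )
            )
        study_maps[s] = GeneticMap(s, pd.concat(frames, ignore_index=True))

    tm = truth.true_mqtl
    if tm.empty:
        truth.study_maps = study_maps
        truth.qtl_records = []
        truth.qtl_truth = pd.DataFrame(
            columns=["qtl_id", "study_id", "true_mqtl_id", "true_pos_cM", "tau_cM"]
        )
        return truth

    # per-study interpolators from true coordinates onto the jittered map
    study_interp: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for s in study_ids:
        study_interp[s] = {}
        for chrom in cfg.chromosomes:
            sub = study_maps[s].chromosome(chrom)
            true_pos = truth.truth_map.positions(chrom)
            tp = np.array([true_pos[m] for m in sub["marker"]])
            jp = sub["pos_cM"].to_numpy()
            order = np.argsort(tp)
            study_interp[s][chrom] = (tp[order], jp[order])

    pves = _lognormal(rng, cfg.pve_median, cfg.pve_sigma, *cfg.pve_range, cfg.n_qtl)
    lods = _lognormal(rng, cfg.lod_median, cfg.lod_sigma, *cfg.lod_range, cfg.n_qtl)
    records: list[QTLRecord] = []
    truth_rows = []
    for i in range(cfg.n_qtl):
        s = study_ids[i % cfg.n_studies]
        t = tm.iloc[int(rng.integers(len(tm)))]
        n, ptype = study_size[s], study_type[s]
        pve, lod = float(pves[i]), float(lods[i])
        tau = recalc_ci(ptype, n, pve) / 3.92
        tp, jp = study_interp[s][str(t.chrom)]
        study_coord = _affine_transfer(float(t.pos_cM), tp, jp)
        pos = float(np.clip(rng.normal(study_coord, tau), 0.0, None))
        width = recalc_ci(ptype, n, pve) * float(
            rng.lognormal(0.0, cfg.ci_distortion_sigma)
        )
        smap = study_maps[s].positions(t.chrom)
        below = [m for m, p in smap.items() if p <= pos]
        above = [m for m, p in smap.items() if p > pos]
        flank_l = max(below, key=lambda m: smap[m]) if below else ""
        flank_r = min(above, key=lambda m: smap[m]) if above else ""
        missing_lod = rng.random() < cfg.missing_rate
        missing_pve = rng.random() < cfg.missing_rate
        trait_raw = raw_names[int(rng.integers(len(raw_names)))]
        records.append(
            QTLRecord(
                qtl_id=f"Q{i + 1:04d}",
                study_id=s,
                population_type=ptype,
                population_size=n,
                trait_raw=trait_raw,
                trait_class=vocabulary.lookup(trait_raw),
                chromosome=str(t.chrom),
                position=pos,
                ci_lo=pos - width / 2.0,
                ci_hi=pos + width / 2.0,
                lod=None if missing_lod else lod,
                pve=None if missing_pve else pve,
                flank_left=flank_l,
                flank_right=flank_r,
            )
        )
        truth_rows.append(
            {
                "qtl_id": f"Q{i + 1:04d}",
                "study_id": s,
                "true_mqtl_id": t.mqtl_id,
                "true_pos_cM": float(t.pos_cM),
                "tau_cM": tau,
            }
        )
    truth.study_maps = study_maps
    truth.qtl_records = records
    truth.qtl_truth = pd.DataFrame(truth_rows)
    return truth


def simulate_mtas(truth: TruthSet, seed: int) -> TruthSet:
    """GWAS MTAs: true positives near true MQTL bp, uniform false positives."""
    cfg = truth.config
    rng = np.random.default_rng(seed)
    if cfg.n_gwas_studies <= 0 or cfg.n_mtas <= 0:
        truth.mtas = []
        truth.mta_truth = pd.DataFrame(columns=["marker", "true_mqtl_id"])
        return truth
    genome_bp = int(cfg.chromosome_length_mb * MB)
    w = int(cfg.mta_window_mb * MB)
    tm = truth.true_mqtl
    mtas, rows = [], []
    classes = ["GMT", "GN", "SRT", "GW", "GY", "GPT", "PH"]
    for i in range(cfg.n_mtas):
        is_fp = (rng.random() < cfg.mta_fp_rate) or tm.empty
        name = f"MTA{i + 1:04d}"
        if is_fp:
            chrom = cfg.chromosomes[int(rng.integers(cfg.n_chromosomes))]
            bp = int(rng.integers(1, genome_bp, endpoint=True))
            link = ""
        else:
            t = tm.iloc[int(rng.integers(len(tm)))]
            chrom = str(t.chrom)
            bp = int(np.clip(t.bp + rng.integers(-w, w, endpoint=True), 1, genome_bp))
            link = str(t.mqtl_id)
        mtas.append(
            MTARecord(
                gwas_study_id=f"GWAS{i % cfg.n_gwas_studies + 1:02d}",
                marker=name,
                chromosome=chrom,
                bp=bp,
                trait_class=classes[int(rng.integers(len(classes)))],
            )
        )
        rows.append({"marker": name, "true_mqtl_id": link})
    truth.mtas = mtas
    truth.mta_truth = pd.DataFrame(rows)
    return truth


def simulate_annotation(truth: TruthSet, seed: int) -> TruthSet:
    """Gene models uniform over the genome plus causal genes and orthologs.

    A ``causal_fraction`` of true MQTL receive a gene within +/-1 Mb of
    their bp position together with an ortholog entry; the rest of the
    ortholog table is decoys pointing at randomly chosen background genes.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genome_bp = int(cfg.chromosome_length_mb * MB)
    gene_rows = []
    for i in range(cfg.n_genes):
        chrom = cfg.chromosomes[int(rng.integers(cfg.n_chromosomes))]
        start = int(rng.integers(1, genome_bp))
        length = int(rng.integers(*cfg.gene_length_range_bp, endpoint=True))
        gene_rows.append(
            {
                "gene_id": f"HVGENE{i + 1:05d}",
                "chrom": chrom,
                "start": start,
                "end": min(start + length, genome_bp),
                "description": "hypothetical protein",
            }
        )

    ortho_rows = []
    species_pool = ["rice", "maize"]
    trait_pool = [
        "grain weight",
        "tiller formation, plant height",
        "inflorescence development",
        "flowering time",
        "spikelet development",
    ]
    n_causal = 0
    for j, t in enumerate(truth.true_mqtl.itertuples(index=False)):
        if rng.random() >= cfg.causal_fraction:
            continue
        n_causal += 1
        start = int(np.clip(t.bp + rng.integers(-MB, MB), 1, genome_bp))
        length = int(rng.integers(*cfg.gene_length_range_bp, endpoint=True))
        gid = f"HVCAUSAL{j + 1:03d}"
        gene_rows.append(
            {
                "gene_id": gid,
                "chrom": str(t.chrom),
                "start": start,
                "end": min(start + length, genome_bp),
                "description": f"causal gene for {t.mqtl_id}",
            }
        )
        sp = species_pool[int(rng.integers(2))]
        ortho_rows.append(
            {
                "barley_gene_id": gid,
                "source_species": sp,
                "source_gene_id": f"{'LOC_Os' if sp == 'rice' else 'Zm'}{j + 1:05d}",
                "source_gene_name": f"yield{j + 1}",
                "regulated_traits": trait_pool[int(rng.integers(len(trait_pool)))],
                "description": "yield-associated ortholog",
            }
        )
    background = [g["gene_id"] for g in gene_rows if g["gene_id"].startswith("HVGENE")]
    for d in range(cfg.n_decoy_orthologs):
        gid = background[int(rng.integers(len(background)))]
        sp = species_pool[int(rng.integers(2))]
        ortho_rows.append(
            {
                "barley_gene_id": gid,
                "source_species": sp,
                "source_gene_id": f"{'LOC_Os' if sp == 'rice' else 'Zm'}D{d + 1:04d}",
                "source_gene_name": f"decoy{d + 1}",
                "regulated_traits": trait_pool[int(rng.integers(len(trait_pool)))],
                "description": "decoy ortholog",
            }
        )
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "description"]
    ).sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
    ortho_df = pd.DataFrame(ortho_rows, columns=ORTHOLOG_COLUMNS)
    ortho_df = ortho_df.drop_duplicates(["barley_gene_id", "source_gene_id"]).reset_index(
        drop=True
    )
    truth.gene_table = gene_df
    truth.orthologs = ortho_df
    return truth


def simulate_all(config: SyntheticConfig | None = None, seed: int = 0) -> TruthSet:
    """Generate a complete synthetic study from one seed."""
    config = config or SyntheticConfig()
    truth = simulate_truth(config, seed)
    truth = simulate_studies(truth, seed + 1)
    truth = simulate_mtas(truth, seed + 2)
    truth = simulate_annotation(truth, seed + 3)
    return truth
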