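"""Candidate-gene mining inside high-confidence MQTL regions.

Gene models from the reference annotation that overlap an hcMQTL mining
region (any overlap counts, boundaries inclusive) are intersected with a
table of barley orthologs of yield-associated genes from related cereals;
genes with an ortholog entry become candidate genes, reported once per
(region, barley gene, source gene) with the traits the source gene
regulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .screening import GenomicInterval, ScreenedMQTL

__all__ = [
    "GeneModel",
    "GeneAnnotation",
    "read_gene_annotation",
    "read_ortholog_table",
    "genes_in_region",
    "ortholog_candidates",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene-level annotation feature (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


class GeneAnnotation:
    """Interval-indexed gene annotation supporting overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chromosome, IntervalTree())
            # half-open tree coordinates; +1 keeps inclusive gene ends
            tree.addi(g.start_bp, g.end_bp + 1, g)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, region: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(region.chromosome)
        if tree is None:
            return []
        hits = tree.overlap(region.start_bp, region.end_bp + 1)
        return sorted(
            (iv.data for iv in hits), key=lambda g: (g.start_bp, g.end_bp, g.gene_id)
        )


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene models from GFF3 (``gene`` features only) or a TSV table.

    The TSV schema is gene_id, chrom, start, end[, description].
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return GeneAnnotation(_parse_gff3_genes(path))
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = {"gene_id", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = [
        GeneModel(
            gene_id=str(r.gene_id).strip(),
            chromosome=str(r.chrom).strip(),
            start_bp=int(r.start),
            end_bp=int(r.end),
            description="" if not hasattr(r, "description") or pd.isna(r.description)
            else str(r.description),
        )
        for r in df.itertuples(index=False)
    ]
    return GeneAnnotation(genes)


def _parse_gff3_genes(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", attrs.get("Name", "")),
                    chromosome=fields[0],
                    start_bp=int(fields[3]),
                    end_bp=int(fields[4]),
                    description=attrs.get("description", ""),
                )
            )
    return genes


ORTHOLOG_COLUMNS = [
    "barley_gene_id",
    "source_species",
    "source_gene_id",
    "source_gene_name",
    "regulated_traits",
    "description",
]


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ORTHOLOG_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ORTHOLOG_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    if df.duplicated(["barley_gene_id", "source_gene_id"]).any():
        df = df.drop_duplicates(["barley_gene_id", "source_gene_id"])
    return df[ORTHOLOG_COLUMNS]


def genes_in_region(
    region: GenomicInterval, annotation: GeneAnnotation
) -> list[GeneModel]:
    """Genes overlapping the region by any amount, sorted by start."""
    return annotation.overlapping(region)


def ortholog_candidates(
    screened_hc: Sequence[ScreenedMQTL],
    annotation: GeneAnnotation,
    orthologs: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate-gene report: region genes joined with the ortholog table.

    One row per (hcMQTL, barley gene, source gene); a gene shared by two
    mining regions appears once per region.  Duplicate rows arising from the
    same source gene listed under several species collapse to one with the
    species concatenated.
    """
    rows = []
    by_barley = orthologs.groupby("barley_gene_id", sort=False)
    for s in screened_hc:
        if s.mining_region is None:
            continue
        for g in genes_in_region(s.mining_region, annotation):
            if g.gene_id not in by_barley.groups:
                continue
            for _, o in by_barley.get_group(g.gene_id).iterrows():
                rows.append(
                    {
                        "mqtl": s.name,
                        "chrom": g.chromosome,
                        "barley_gene_id": g.gene_id,
                        "gene_start_bp": g.start_bp,
                        "gene_end_bp": g.end_bp,
                        "source_species": o["source_species"],
                        "source_gene_id": o["source_gene_id"],
                        "source_gene_name": o["source_gene_name"],
                        "regulated_traits": o["regulated_traits"],
                        "description": o["description"] or g.description,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "mqtl",
            "chrom",
            "barley_gene_id",
            "gene_start_bp",
            "gene_end_bp",
            "source_species",
            "source_gene_id",
            "source_gene_name",
            "regulated_traits",
            "description",
        ],
    )
    if df.empty:
        return df
    # same (region, barley gene, source gene) via several species -> one row
    agg = {c: "first" for c in df.columns}
    agg["source_species"] = lambda s: ";".join(sorted(set(s)))
    df = (
        df.groupby(["mqtl", "barley_gene_id", "source_gene_id"], as_index=False)
        .agg(agg)
        .sort_values(["mqtl", "gene_start_bp", "barley_gene_id", "source_gene_id"])
        .reset_index(drop=True)
    )
    return df[
        [
            "mqtl",
            "chrom",
            "barley_gene_id",
            "gene_start_bp",
            "gene_end_bp",
            "source_species",
            "source_gene_id",
            "source_gene_name",
            "regulated_traits",
            "description",
        ]
    ]
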