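"""Physical anchoring, GWAS validation and screening of meta-QTL.

An MQTL lives in genetic (cM) coordinates; downstream use needs physical
(bp) coordinates.  Each MQTL is anchored by locating the consensus markers
flanking its genetic CI that have known physical positions; the physical
interval is the min/max of those anchors' bp coordinates (1-based,
inclusive at both ends throughout).

Validation compares MQTL intervals with marker-trait associations (MTAs)
from independent GWAS: an MQTL overlapping at least one MTA is
GWAS-validated.  Two screens then follow:

* **breeder's MQTL** — genetic CI < 2 cM, mean PVE > 10%, and at least 4
  member QTL from at least 4 distinct studies, among the GWAS-validated
  MQTL; candidates for marker-assisted selection.
* **high-confidence MQTL (hcMQTL)** — genetic CI < 1 cM, physical span
  < 20 Mb, and at least 5 member QTL; used for candidate-gene mining.  The
  mining region is the whole physical interval when it spans < 2 Mb,
  otherwise peak +/- 1 Mb, the peak being the physical interpolation of the
  MQTL's genetic position between its anchor markers.

All inequalities are strict exactly as written (a CI of exactly 2 cM is not
a breeder's MQTL; a span of exactly 20 Mb is not high-confidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusMap
from .meta import MQTL

__all__ = [
    "GenomicInterval",
    "MTARecord",
    "ScreenedMQTL",
    "ScreeningThresholds",
    "anchor_physical",
    "anchor_all",
    "validate_gwas",
    "screen_breeders",
    "screen_hc",
    "read_mta_table",
    "screened_to_frame",
    "mining_regions_to_bed",
]

MB = 1_000_000


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive physical interval."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chromosome: str, bp: int) -> bool:
        return (
            chromosome == self.chromosome and self.start_bp <= bp <= self.end_bp
        )


@dataclass(frozen=True)
class MTARecord:
    """One GWAS marker-trait association at a physical position."""

    gwas_study_id: str
    marker: str
    chromosome: str
    bp: int
    trait_class: str = ""

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError("bp is 1-based")


@dataclass
class ScreenedMQTL:
    """An MQTL carried through anchoring, validation and screening."""

    mqtl: MQTL
    physical: GenomicInterval | None = None
    anchor_note: str = ""
    peak_bp: int | None = None
    n_gwas_hits: int = 0
    n_gwas_studies: int = 0
    is_validated: bool = False
    is_breeders: bool = False
    is_hc: bool = False
    mining_region: GenomicInterval | None = None

    @property
    def name(self) -> str:
        return self.mqtl.name


@dataclass
class ScreeningThresholds:
    """Screening cut-offs (strict inequalities as documented)."""

    breeders_ci_cM: float = 2.0      # genetic CI width strictly below
    breeders_pve: float = 10.0       # mean PVE strictly above (percent)
    breeders_min_qtl: int = 4        # members and distinct studies, at least
    hc_ci_cM: float = 1.0            # genetic CI width strictly below
    hc_span_mb: float = 20.0         # physical span strictly below
    hc_min_qtl: int = 5              # members, at least
    direct_region_mb: float = 2.0    # whole interval mined when span below
    peak_flank_mb: float = 1.0       # else peak +/- this
    require_trait_match: bool = False  # MTA trait must match an MQTL trait


def _physical_lookup(marker_physical: pd.DataFrame) -> dict[tuple[str, str], int]:
    return {
        (str(m).strip(), str(c).strip()): int(b)
        for m, c, b in zip(
            marker_physical["marker"],
            marker_physical["chrom"],
            marker_physical["bp"],
        )
    }


def anchor_physical(
    mqtl: MQTL,
    consensus: ConsensusMap,
    marker_physical: pd.DataFrame,
) -> ScreenedMQTL:
    """Anchor one MQTL's genetic CI to a physical interval.

    The anchors are the closest consensus markers with known bp at or
    outside each CI endpoint (falling back to the closest anchorable marker
    when the CI reaches past the mapped ends).  The interval is min/max of
    the two anchors' bp, and the peak is the linear cM->bp interpolation of
    the MQTL position between them.
    """
    phys = _physical_lookup(marker_physical)
    sub = consensus.entries[consensus.entries["chrom"] == mqtl.chromosome]
    anchorable = [
        (float(p), phys[(m, mqtl.chromosome)])
        for m, p in zip(sub["marker"], sub["pos_cM"])
        if (m, mqtl.chromosome) in phys
    ]
    if len(anchorable) < 2:
        return ScreenedMQTL(
            mqtl, None, anchor_note="fewer than 2 anchorable markers on chromosome"
        )
    anchorable.sort()
    cms = np.array([a[0] for a in anchorable])
    bps = np.array([a[1] for a in anchorable], dtype=float)

    lo_idx = np.searchsorted(cms, mqtl.ci_lo, side="right") - 1
    hi_idx = np.searchsorted(cms, mqtl.ci_hi, side="left")
    lo_idx = int(np.clip(lo_idx, 0, len(cms) - 1))
    hi_idx = int(np.clip(hi_idx, 0, len(cms) - 1))
    if lo_idx == hi_idx:  # CI narrower than local marker spacing
        hi_idx = min(lo_idx + 1, len(cms) - 1)
        if hi_idx == lo_idx:
            lo_idx -= 1
    b1, b2 = bps[lo_idx], bps[hi_idx]
    interval = GenomicInterval(
        mqtl.chromosome, int(min(b1, b2)), int(max(b1, b2))
    )
    # peak: interpolate the MQTL genetic position between the anchors
    c1, c2 = cms[lo_idx], cms[hi_idx]
    if c2 > c1:
        frac = np.clip((mqtl.position - c1) / (c2 - c1), 0.0, 1.0)
        peak = int(round(b1 + frac * (b2 - b1)))
    else:
        peak = int(round((b1 + b2) / 2))
    peak = int(np.clip(peak, interval.start_bp, interval.end_bp))
    return ScreenedMQTL(mqtl, interval, peak_bp=peak)


def anchor_all(
    mqtls: Sequence[MQTL],
    consensus: ConsensusMap,
    marker_physical: pd.DataFrame,
) -> list[ScreenedMQTL]:
    return [anchor_physical(m, consensus, marker_physical) for m in mqtls]


def validate_gwas(
    screened: Sequence[ScreenedMQTL],
    mtas: Sequence[MTARecord],
    *,
    require_trait_match: bool = False,
) -> list[ScreenedMQTL]:
    """Count MTA hits per MQTL; an MQTL with >= 1 hit is GWAS-validated.

    A hit is same chromosome with interval-start <= bp <= interval-end
    (inclusive at both ends).  ``n_gwas_studies`` counts distinct GWAS
    studies among the hits.  MQTL without a physical interval cannot be
    validated and keep zero counts.
    """
    for s in screened:
        if s.physical is None:
            s.n_gwas_hits = 0
            s.n_gwas_studies = 0
            s.is_validated = False
            continue
        traits = set(s.mqtl.trait_classes)
        hits = [
            m
            for m in mtas
            if s.physical.contains(m.chromosome, m.bp)
            and (not require_trait_match or not m.trait_class or m.trait_class in traits)
        ]
        s.n_gwas_hits = len(hits)
        s.n_gwas_studies = len({m.gwas_study_id for m in hits})
        s.is_validated = bool(hits)
    return list(screened)


def screen_breeders(
    screened: Sequence[ScreenedMQTL],
    thresholds: ScreeningThresholds | None = None,
) -> list[ScreenedMQTL]:
    """Flag and return the breeder's MQTL subset (validated MQTL only)."""
    t = thresholds or ScreeningThresholds()
    out = []
    for s in screened:
        m = s.mqtl
        s.is_breeders = (
            s.is_validated
            and m.ci_width < t.breeders_ci_cM
            and not np.isnan(m.mean_pve)
            and m.mean_pve > t.breeders_pve
            and m.n_qtl >= t.breeders_min_qtl
            and m.n_studies >= t.breeders_min_qtl
        )
        if s.is_breeders:
            out.append(s)
    return out


def screen_hc(
    screened: Sequence[ScreenedMQTL],
    thresholds: ScreeningThresholds | None = None,
) -> list[ScreenedMQTL]:
    """Flag the high-confidence subset and attach gene-mining regions."""
    t = thresholds or ScreeningThresholds()
    out = []
    for s in screened:
        m = s.mqtl
        s.is_hc = (
            s.physical is not None
            and m.ci_width < t.hc_ci_cM
            and s.physical.span_bp < t.hc_span_mb * MB
            and m.n_qtl >= t.hc_min_qtl
        )
        if not s.is_hc:
            s.mining_region = None
            continue
        assert s.physical is not None
        if s.physical.span_bp < t.direct_region_mb * MB:
            s.mining_region = s.physical
        else:
            peak = s.peak_bp if s.peak_bp is not None else (
                (s.physical.start_bp + s.physical.end_bp) // 2
            )
            flank = int(t.peak_flank_mb * MB)
            s.mining_region = GenomicInterval(
                m.chromosome, max(1, peak - flank), peak + flank
            )
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# I/O

MTA_COLUMNS = ["gwas_study_id", "marker", "chrom", "bp", "trait"]


def read_mta_table(path: str | Path) -> list[MTARecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gwas_study_id": str, "marker": str, "chrom": str})
    missing = set(MTA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MTARecord(
            gwas_study_id=str(r.gwas_study_id).strip(),
            marker=str(r.marker).strip(),
            chromosome=str(r.chrom).strip(),
            bp=int(r.bp),
            trait_class="" if pd.isna(r.trait) else str(r.trait).strip(),
        )
        for r in df.itertuples(index=False)
    ]


def write_mta_table(mtas: Iterable[MTARecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gwas_study_id": m.gwas_study_id,
                "marker": m.marker,
                "chrom": m.chromosome,
                "bp": m.bp,
                "trait": m.trait_class,
            }
            for m in mtas
        ],
        columns=MTA_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def screened_to_frame(screened: Sequence[ScreenedMQTL]) -> pd.DataFrame:
    rows = []
    for s in screened:
        m = s.mqtl
        rows.append(
            {
                "name": m.name,
                "chrom": m.chromosome,
                "pos_cM": m.position,
                "ci_lo": m.ci_lo,
                "ci_hi": m.ci_hi,
                "ci_width_cM": m.ci_width,
                "n_qtl": m.n_qtl,
                "n_studies": m.n_studies,
                "mean_lod": m.mean_lod,
                "mean_pve": m.mean_pve,
                "phys_start_bp": s.physical.start_bp if s.physical else np.nan,
                "phys_end_bp": s.physical.end_bp if s.physical else np.nan,
                "phys_span_mb": s.physical.span_bp / MB if s.physical else np.nan,
                "peak_bp": s.peak_bp if s.peak_bp is not None else np.nan,
                "n_gwas_hits": s.n_gwas_hits,
                "n_gwas_studies": s.n_gwas_studies,
                "is_validated": s.is_validated,
                "is_breeders": s.is_breeders,
                "is_hc": s.is_hc,
                "mining_start_bp": s.mining_region.start_bp if s.mining_region else np.nan,
                "mining_end_bp": s.mining_region.end_bp if s.mining_region else np.nan,
                "anchor_note": s.anchor_note,
            }
        )
    return pd.DataFrame(rows)


def mining_regions_to_bed(screened: Sequence[ScreenedMQTL], path: str | Path) -> None:
    """Export mining regions as BED (0-based half-open conversion)."""
    with open(path, "w") as fh:
        for s in screened:
            if s.mining_region is None:
                continue
            r = s.mining_region
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{s.name}\n")
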