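"""Projection of initial QTL onto the consensus map.

Each QTL is reported on its source study's linkage map.  To compare QTL
across studies, positions and CI endpoints are transferred to the consensus
map by homothetic (proportional) interpolation between *anchor markers* —
the closest markers bracketing the QTL that exist on both the source map and
the consensus.  Within one anchor interval the transformation is affine, so
the CI width scales by the local ratio of consensus to source interval
lengths.

A QTL whose source chromosome shares fewer than two markers with the
consensus cannot be placed; it is carried through flagged ``projectable =
False`` with an explicit reason and excluded from meta-analysis.  When a
study has no published map, the QTL's flanking markers are used directly:
they are assumed to delimit the reported CI, so the source-side anchor
coordinates are the CI endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusMap, GeneticMap
from .qtl_data import QTLRecord

__all__ = [
    "ProjectedQTL",
    "find_anchor_interval",
    "project_position",
    "project_qtl",
    "project_all",
    "projected_to_frame",
]


@dataclass
class ProjectedQTL:
    """A QTL with coordinates on the consensus map (when projectable)."""

    record: QTLRecord
    projectable: bool
    reason: str = ""
    proj_position: float = np.nan
    proj_ci_lo: float = np.nan
    proj_ci_hi: float = np.nan
    anchor_left: str = ""
    anchor_right: str = ""
    extrapolated: bool = False

    @property
    def chromosome(self) -> str:
        return self.record.chromosome

    @property
    def proj_ci_width(self) -> float:
        return self.proj_ci_hi - self.proj_ci_lo

    @property
    def sd(self) -> float:
        """Position standard deviation implied by the projected 95% CI."""
        return self.proj_ci_width / 3.92


def find_anchor_interval(
    qtl: QTLRecord,
    source_positions: Mapping[str, float],
    consensus_positions: Mapping[str, float],
) -> tuple[str, str, bool]:
    """Closest markers left/right of the QTL shared by source and consensus.

    Returns ``(left, right, extrapolated)``.  When the QTL lies outside the
    span of shared markers the two nearest shared markers are returned with
    ``extrapolated = True``.  Fewer than two shared markers raises
    ``ValueError`` (the QTL is unprojectable).
    """
    shared = sorted(
        set(source_positions) & set(consensus_positions),
        key=lambda m: (source_positions[m], m),
    )
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} marker(s) shared with the consensus on "
            f"chromosome {qtl.chromosome}"
        )
    pos = qtl.position
    lefts = [m for m in shared if source_positions[m] <= pos]
    rights = [m for m in shared if source_positions[m] >= pos]
    if lefts and rights:
        left, right = lefts[-1], rights[0]
        if left == right:  # QTL exactly on a shared marker: bracket it
            i = shared.index(left)
            if i + 1 < len(shared):
                right = shared[i + 1]
            else:
                left = shared[i - 1]
        return left, right, False
    # outside the shared span: extrapolate from the terminal interval
    if rights:
        return shared[0], shared[1], True
    return shared[-2], shared[-1], True


def project_position(
    pos: float, a_src: float, b_src: float, a_cons: float, b_cons: float
) -> float:
    """Affine transfer of one coordinate between anchor pairs."""
    if a_src == b_src:
        raise ValueError("zero-length source anchor interval")
    return a_cons + (pos - a_src) * (b_cons - a_cons) / (b_src - a_src)


def project_qtl(
    qtl: QTLRecord,
    source_map: GeneticMap | None,
    consensus: ConsensusMap,
) -> ProjectedQTL:
    """Project one QTL's position and CI endpoints onto the consensus.

    Position and both CI endpoints use the same anchor pair, so the CI width
    scales by the local consensus/source ratio.  Extrapolated coordinates are
    clamped to the chromosome bounds (never negative, never past the end).
    """
    chrom = qtl.chromosome
    cons_pos = consensus.positions(chrom)
    if not cons_pos:
        return ProjectedQTL(qtl, False, reason=f"chromosome {chrom} not on consensus")

    if source_map is not None:
        src_pos = source_map.positions(chrom)
        try:
            left, right, extrap = find_anchor_interval(qtl, src_pos, cons_pos)
        except ValueError as exc:
            return ProjectedQTL(qtl, False, reason=str(exc))
        a_src, b_src = src_pos[left], src_pos[right]
    else:
        # direct anchoring: flanking markers taken to delimit the reported CI
        left, right = qtl.flank_left, qtl.flank_right
        if not (left and right and left in cons_pos and right in cons_pos):
            return ProjectedQTL(
                qtl, False, reason="no source map and flanking markers not on consensus"
            )
        a_src, b_src = qtl.ci_lo, qtl.ci_hi
        extrap = False
    if a_src == b_src:
        return ProjectedQTL(qtl, False, reason="zero-length source anchor interval")

    a_cons, b_cons = cons_pos[left], cons_pos[right]
    lo, mid, hi = sorted(
        project_position(v, a_src, b_src, a_cons, b_cons)
        for v in (qtl.ci_lo, qtl.position, qtl.ci_hi)
    )
    chrom_end = consensus.chromosome_length(chrom)
    lo = float(np.clip(lo, 0.0, chrom_end))
    mid = float(np.clip(mid, 0.0, chrom_end))
    hi = float(np.clip(hi, 0.0, chrom_end))
    return ProjectedQTL(
        qtl,
        True,
        proj_position=mid,
        proj_ci_lo=lo,
        proj_ci_hi=hi,
        anchor_left=left,
        anchor_right=right,
        extrapolated=extrap,
    )


def project_all(
    records: Sequence[QTLRecord],
    study_maps: Mapping[str, GeneticMap],
    consensus: ConsensusMap,
) -> list[ProjectedQTL]:
    """Project every record; study maps looked up by ``study_id``."""
    return [
        project_qtl(rec, study_maps.get(rec.study_id), consensus) for rec in records
    ]


def projected_to_frame(projected: Iterable[ProjectedQTL]) -> pd.DataFrame:
    """Projected table: the full input schema plus proj_*/anchor columns."""
    rows = []
    for p in projected:
        r = p.record
        rows.append(
            {
                "qtl_id": r.qtl_id,
                "study_id": r.study_id,
                "pop_type": r.population_type,
                "pop_size": r.population_size,
                "trait": r.trait_raw,
                "trait_class": r.trait_class,
                "chrom": r.chromosome,
                "pos_cM": r.position,
                "ci_lo_cM": r.ci_lo,
                "ci_hi_cM": r.ci_hi,
                "lod": r.lod,
                "pve": r.pve,
                "lod_imputed": r.lod_imputed,
                "pve_imputed": r.pve_imputed,
                "flank_left": r.flank_left,
                "flank_right": r.flank_right,
                "proj_pos_cM": p.proj_position,
                "proj_ci_lo": p.proj_ci_lo,
                "proj_ci_hi": p.proj_ci_hi,
                "anchor_left": p.anchor_left,
                "anchor_right": p.anchor_right,
                "projectable": p.projectable,
                "extrapolated": p.extrapolated,
                "reason": p.reason,
            }
        )
    return pd.DataFrame(rows)


def write_projected(projected: Iterable[ProjectedQTL], path: str | Path) -> None:
    projected_to_frame(projected).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_projected(path: str | Path) -> list[ProjectedQTL]:
    """Rebuild ProjectedQTL records from a persisted projected-QTL table."""
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"qtl_id": str, "study_id": str, "chrom": str, "trait": str},
    )
    out: list[ProjectedQTL] = []
    for r in df.itertuples(index=False):
        rec = QTLRecord(
            qtl_id=str(r.qtl_id),
            study_id=str(r.study_id),
            population_type=str(r.pop_type),
            population_size=int(r.pop_size),
            trait_raw=str(r.trait),
            trait_class=str(r.trait_class),
            chromosome=str(r.chrom),
            position=float(r.pos_cM),
            ci_lo=float(r.ci_lo_cM),
            ci_hi=float(r.ci_hi_cM),
            lod=None if pd.isna(r.lod) else float(r.lod),
            pve=None if pd.isna(r.pve) else float(r.pve),
            lod_imputed=bool(r.lod_imputed),
            pve_imputed=bool(r.pve_imputed),
            flank_left="" if pd.isna(r.flank_left) else str(r.flank_left),
            flank_right="" if pd.isna(r.flank_right) else str(r.flank_right),
        )
        out.append(
            ProjectedQTL(
                rec,
                bool(r.projectable),
                reason="" if pd.isna(r.reason) else str(r.reason),
                proj_position=float(r.proj_pos_cM),
                proj_ci_lo=float(r.proj_ci_lo),
                proj_ci_hi=float(r.proj_ci_hi),
                anchor_left="" if pd.isna(r.anchor_left) else str(r.anchor_left),
                anchor_right="" if pd.isna(r.anchor_right) else str(r.anchor_right),
                extrapolated=bool(r.extrapolated),
            )
        )
    return out
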