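"""Domain types and tabular I/O for initial QTL data.

An *initial QTL* is one quantitative-trait-locus report harvested from a
primary mapping study: a genetic position with a confidence interval (CI) on
the study's own linkage map, a LOD score, the percentage of phenotypic
variance explained (PVE), the mapping-population type and size, and the raw
trait name.  Before meta-analysis the raw trait names are harmonized into 11
canonical yield-trait classes, missing LOD/PVE values are imputed, and each
CI is recalibrated from population size and PVE so that interval widths are
comparable across studies.

The CI recalibration uses the empirical relation ``CI = c / (n * PVE)`` with
a population-type-specific constant ``c`` (295-cross-derived constants:
287 for double-haploid, 163 for recombinant-inbred-line, 530 for F2 and
backcross populations).  **PVE is on the percent scale throughout** (10 means
10%); using proportions would inflate every CI a hundred-fold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_CLASSES",
    "POPULATION_TYPES",
    "CI_CONSTANTS",
    "CHROMOSOMES",
    "QTLRecord",
    "TraitVocabulary",
    "UNCLASSIFIED",
    "default_trait_vocabulary",
    "harmonize_trait",
    "recalc_ci",
    "impute_missing",
    "read_qtl_table",
    "write_qtl_table",
    "read_marker_physical",
    "write_marker_physical",
]

#: The 11 canonical yield-trait classes.
TRAIT_CLASSES = (
    "GMT",  # grain morphological traits
    "GN",   # grain number
    "SRT",  # spike-related traits
    "GW",   # grain weight
    "GY",   # grain yield
    "GFRT", # grain filling-related traits
    "GPT",  # growth period traits
    "BY",   # biomass yield
    "PH",   # plant height
    "TN",   # tiller number
    "HI",   # harvest index
)

POPULATION_TYPES = ("BC", "DH", "RIL", "F2")

#: CI = c / (n * PVE%): population-type constant c.
CI_CONSTANTS: Mapping[str, float] = {
    "DH": 287.0,
    "RIL": 163.0,
    "F2": 530.0,
    "BC": 530.0,
}

#: Barley chromosome names.
CHROMOSOMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")

#: Sentinel returned by :func:`harmonize_trait` for unmapped names.
UNCLASSIFIED = "unclassified"

#: Default LOD / PVE for reports that omit them.
DEFAULT_LOD = 3.0
DEFAULT_PVE = 10.0

#: Half-width multiplier of a 95% normal confidence interval.
CI95_Z = 1.959963984540054


@dataclass
class QTLRecord:
    """One initial QTL with study metadata.

    Positions and CI endpoints are centiMorgans on the source study's map;
    ``pve`` is a percentage.  ``lod_imputed``/``pve_imputed`` mark values
    filled in by :func:`impute_missing` rather than reported by the study.
    """

    study_id: str
    population_type: str
    population_size: int
    trait_raw: str
    trait_class: str
    chromosome: str
    position: float
    ci_lo: float
    ci_hi: float
    lod: float | None = None
    pve: float | None = None
    flank_left: str = ""
    flank_right: str = ""
    qtl_id: str = ""
    lod_imputed: bool = False
    pve_imputed: bool = False

    def __post_init__(self) -> None:
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(f"unknown population type {self.population_type!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (self.ci_lo <= self.position <= self.ci_hi):
            raise ValueError(
                f"QTL {self.qtl_id or self.trait_raw}: CI "
                f"[{self.ci_lo}, {self.ci_hi}] does not contain position {self.position}"
            )
        if self.lod is not None and not self.lod > 0:
            raise ValueError("lod must be > 0 when present")
        if self.pve is not None and not (0.0 < self.pve <= 100.0):
            raise ValueError("pve must be in (0, 100] percent when present")

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo


class TraitVocabulary:
    """Mapping from normalized raw trait names to the 11 trait classes.

    Lookup is case-insensitive and whitespace-collapsing.  Every raw name
    maps to exactly one class; unmapped names are reported as
    :data:`UNCLASSIFIED`, never silently dropped.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for raw, cls in mapping.items():
            key = _normalize(raw)
            if cls not in TRAIT_CLASSES:
                raise ValueError(f"unknown trait class {cls!r} for {raw!r}")
            if key in self._map and self._map[key] != cls:
                raise ValueError(f"conflicting classes for trait name {raw!r}")
            self._map[key] = cls

    def __contains__(self, raw_name: str) -> bool:
        return _normalize(raw_name) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, raw_name: str) -> str:
        return self._map.get(_normalize(raw_name), UNCLASSIFIED)

    @property
    def raw_names(self) -> list[str]:
        return sorted(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitVocabulary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"raw_name", "trait_class"}
        if not required.issubset(df.columns):
            raise ValueError(f"trait vocabulary needs columns {sorted(required)}")
        return cls(dict(zip(df["raw_name"], df["trait_class"])))


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def default_trait_vocabulary() -> TraitVocabulary:
    """The packaged vocabulary seeded with every recognised trait synonym."""
    with resources.as_file(
        resources.files("metaqtl.data") / "trait_vocabulary.tsv"
    ) as p:
        return TraitVocabulary.from_tsv(p)


def harmonize_trait(raw_name: str, vocabulary: TraitVocabulary) -> str:
    """Map a raw trait name to one of the 11 classes.

    Returns :data:`UNCLASSIFIED` for empty or unmapped names; callers decide
    whether that is fatal.
    """
    if not raw_name or not raw_name.strip():
        return UNCLASSIFIED
    return vocabulary.lookup(raw_name)


def recalc_ci(population_type: str, population_size: int, pve_percent: float) -> float:
    """Recalibrated 95% CI width (cM) from population size and PVE.

    ``CI = c / (n * PVE)`` with c = 287 (DH), 163 (RIL), 530 (F2 and BC);
    PVE on the percent scale.
    """
    if population_type not in CI_CONSTANTS:
        raise ValueError(f"unknown population type {population_type!r}")
    if population_size < 2:
        raise ValueError("population_size must be >= 2")
    if not pve_percent > 0:
        raise ValueError("pve_percent must be > 0")
    return CI_CONSTANTS[population_type] / (population_size * pve_percent)


def impute_missing(record: QTLRecord) -> QTLRecord:
    """Fill missing LOD with 3 and missing PVE with 10%, flagging each."""
    out = record
    if out.lod is None:
        out = replace(out, lod=DEFAULT_LOD, lod_imputed=True)
    if out.pve is None:
        out = replace(out, pve=DEFAULT_PVE, pve_imputed=True)
    return out


def apply_ci_recalculation(record: QTLRecord, *, skip_imputed: bool = True) -> QTLRecord:
    """Replace the reported CI with the recalibrated one, centred on the peak.

    By default a record whose PVE was *imputed* keeps its reported CI: the
    formula would turn the imputation default into a fabricated precision,
    while the study's reported interval is a measurement.  Pass
    ``skip_imputed=False`` to recalculate unconditionally.
    """
    if record.pve is None:
        raise ValueError("PVE required for CI recalculation; impute first")
    if skip_imputed and record.pve_imputed:
        return record
    width = recalc_ci(record.population_type, record.population_size, record.pve)
    return replace(
        record, ci_lo=record.position - width / 2.0, ci_hi=record.position + width / 2.0
    )


# ---------------------------------------------------------------------------
# Tabular I/O

QTL_COLUMNS = [
    "qtl_id",
    "study_id",
    "pop_type",
    "pop_size",
    "trait",
    "chrom",
    "pos_cM",
    "ci_lo_cM",
    "ci_hi_cM",
    "lod",
    "pve",
    "flank_left",
    "flank_right",
]

_REQUIRED_QTL_COLUMNS = set(QTL_COLUMNS) - {"qtl_id"}


@dataclass
class QTLTableReport:
    """Per-file parse report: accepted records plus rejected-row diagnostics."""

    records: list[QTLRecord]
    n_rows: int = 0
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def read_qtl_table(
    path: str | Path,
    vocabulary: TraitVocabulary | None = None,
    *,
    strict: bool = False,
) -> QTLTableReport:
    """Read a delimited QTL table and harmonize trait names.

    Rows whose trait cannot be mapped onto the 11 classes are excluded and
    reported with their line number (or raise when ``strict``).  A missing
    required column and a non-numeric position are always errors.
    """
    vocabulary = vocabulary or default_trait_vocabulary()
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = _REQUIRED_QTL_COLUMNS - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")

    records: list[QTLRecord] = []
    excluded: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = row._asdict()
        trait_raw = str(row["trait"]).strip()
        trait_class = harmonize_trait(trait_raw, vocabulary)
        if trait_class == UNCLASSIFIED:
            msg = f"line {i}: unmapped trait {trait_raw!r}"
            if strict:
                raise ValueError(f"{path}: {msg}")
            excluded.append((i, msg))
            continue
        try:
            rec = QTLRecord(
                qtl_id=_opt_str(row.get("qtl_id")) or f"Q{i - 1}",
                study_id=str(row["study_id"]).strip(),
                population_type=str(row["pop_type"]).strip().upper(),
                population_size=int(float(row["pop_size"])),
                trait_raw=trait_raw,
                trait_class=trait_class,
                chromosome=str(row["chrom"]).strip(),
                position=float(row["pos_cM"]),
                ci_lo=float(row["ci_lo_cM"]),
                ci_hi=float(row["ci_hi_cM"]),
                lod=_opt_float(row.get("lod")),
                pve=_opt_float(row.get("pve")),
                flank_left=_opt_str(row.get("flank_left")),
                flank_right=_opt_str(row.get("flank_right")),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    return QTLTableReport(records=records, n_rows=len(df), excluded=excluded)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "na", ""):
        return None
    return float(s)


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip()


def qtl_records_to_frame(records: Iterable[QTLRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "qtl_id": r.qtl_id,
                "study_id": r.study_id,
                "pop_type": r.population_type,
                "pop_size": r.population_size,
                "trait": r.trait_raw,
                "chrom": r.chromosome,
                "pos_cM": r.position,
                "ci_lo_cM": r.ci_lo,
                "ci_hi_cM": r.ci_hi,
                "lod": r.lod,
                "pve": r.pve,
                "flank_left": r.flank_left,
                "flank_right": r.flank_right,
            }
        )
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


def write_qtl_table(records: Iterable[QTLRecord], path: str | Path) -> None:
    """Write records as TSV; ``repr``-precision floats so a read round-trips."""
    df = qtl_records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# --- marker physical positions ---------------------------------------------


def read_marker_physical(path: str | Path) -> pd.DataFrame:
    """Read a marker physical-position table (marker, chrom, bp; 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    required = {"marker", "chrom", "bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    df["marker"] = df["marker"].str.strip()
    df["bp"] = df["bp"].astype(np.int64)
    if (df["bp"] < 1).any():
        raise ValueError(f"{path}: bp coordinates are 1-based (>= 1)")
    if df.duplicated(["marker", "chrom"]).any():
        raise ValueError(f"{path}: duplicate (marker, chrom) entries")
    return df


def write_marker_physical(df: pd.DataFrame, path: str | Path) -> None:
    df[["marker", "chrom", "bp"]].to_csv(path, sep="\t", index=False)
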