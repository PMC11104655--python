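"""Consensus genetic-map construction.

Several component linkage maps of the same chromosome rarely agree: shared
markers sit at different centiMorgan coordinates and occasionally in
different orders.  The merge implemented here finds consensus coordinates
``x`` that minimize the average absolute error between the consensus and
every component map, subject to the marker-order constraints the component
maps impose:

    minimize   sum over retained constraints |(x_b - x_a) - d_ab|
    subject to x_b >= x_a                    for every retained constraint,

where each constraint says "map m places marker b a distance d_ab after
marker a".  This is a linear program (absolute values split into slack
pairs) solved with HiGHS via :func:`scipy.optimize.linprog`.

When two maps order a pair of markers oppositely the constraint graph has a
cycle.  A minimal feedback-arc set is NP-hard, so conflicts are broken
greedily: the edge participating in the most cycles is removed (ties:
weakest multi-map support, then lexicographic) and the search repeats until
the graph is acyclic.  Every removed constraint is logged with its source
map.

Flat optima of the L1 objective are resolved deterministically by a
tiny-weight pull of each marker toward the centroid of its per-map
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

__all__ = [
    "GeneticMap",
    "ConsensusMap",
    "OrderGraph",
    "read_genetic_maps",
    "build_order_graph",
    "resolve_conflicts",
    "merge_maps",
    "merge_all_chromosomes",
    "consensus_objective",
    "map_summary",
]

#: Weight of the centroid tie-break term in the merge LP.
TIEBREAK_EPS = 1e-6

MAP_COLUMNS = ["map_id", "marker", "chrom", "pos_cM"]


@dataclass
class GeneticMap:
    """One component linkage map: ordered marker positions per chromosome."""

    map_id: str
    entries: pd.DataFrame  # columns marker, chrom, pos_cM

    def __post_init__(self) -> None:
        df = self.entries.copy()
        df["marker"] = df["marker"].astype(str).str.strip()
        df["chrom"] = df["chrom"].astype(str).str.strip()
        if df.duplicated(["marker", "chrom"]).any():
            dups = df[df.duplicated(["marker", "chrom"])]["marker"].tolist()
            raise ValueError(f"map {self.map_id}: duplicate markers {dups[:5]}")
        df = df.sort_values(["chrom", "pos_cM", "marker"], kind="stable")
        self.entries = df.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.entries["chrom"].unique())

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.entries[self.entries["chrom"] == chrom]

    def positions(self, chrom: str) -> dict[str, float]:
        sub = self.chromosome(chrom)
        return dict(zip(sub["marker"], sub["pos_cM"]))


@dataclass
class ConsensusMap:
    """Merged map with per-marker provenance and the dropped constraints."""

    entries: pd.DataFrame  # marker, chrom, pos_cM, maps (';'-joined provenance)
    removed_constraints: list[tuple[str, str, str]] = field(default_factory=list)
    excluded_markers: list[tuple[str, str]] = field(default_factory=list)
    objective: float = 0.0

    def positions(self, chrom: str) -> dict[str, float]:
        sub = self.entries[self.entries["chrom"] == chrom]
        return dict(zip(sub["marker"], sub["pos_cM"]))

    def chromosome_length(self, chrom: str) -> float:
        sub = self.entries[self.entries["chrom"] == chrom]
        if sub.empty:
            return 0.0
        return float(sub["pos_cM"].max())

    def as_genetic_map(self, map_id: str = "consensus") -> GeneticMap:
        return GeneticMap(map_id, self.entries[["marker", "chrom", "pos_cM"]].copy())

    def write(self, path: str | Path, removed_path: str | Path | None = None) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.17g")
        if removed_path is not None:
            pd.DataFrame(
                self.removed_constraints, columns=["map_id", "marker_a", "marker_b"]
            ).to_csv(removed_path, sep="\t", index=False)


@dataclass
class OrderGraph:
    """Directed marker-order constraints of one chromosome.

    Edge (a, b) carries ``support``: list of (map_id, distance cM) pairs, one
    per component map that places b after a within ``max_interval`` shared
    steps.
    """

    chromosome: str
    graph: nx.DiGraph

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


def read_consensus(path: str | Path) -> ConsensusMap:
    """Read a persisted consensus map (marker, chrom, pos_cM[, maps])."""
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"marker": str, "chrom": str, "maps": str},
    )
    missing = {"marker", "chrom", "pos_cM"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "maps" not in df.columns:
        df["maps"] = ""
    return ConsensusMap(df[["marker", "chrom", "pos_cM", "maps"]])


def read_genetic_maps(path: str | Path) -> list[GeneticMap]:
    """Read component maps from one TSV (map_id, marker, chrom, pos_cM)."""
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"map_id": str, "marker": str, "chrom": str},
    )
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneticMap(map_id, sub[["marker", "chrom", "pos_cM"]].copy())
        for map_id, sub in df.groupby("map_id", sort=True)
    ]


def _conflicting_chromosome_markers(maps: Sequence[GeneticMap]) -> set[str]:
    """Markers assigned to different chromosomes in different maps."""
    assignment: dict[str, str] = {}
    conflicted: set[str] = set()
    for m in maps:
        for marker, chrom in zip(m.entries["marker"], m.entries["chrom"]):
            if assignment.setdefault(marker, chrom) != chrom:
                conflicted.add(marker)
    return conflicted


def build_order_graph(
    maps: Sequence[GeneticMap],
    chromosome: str,
    max_interval: int = 1,
    *,
    exclude: set[str] | None = None,
) -> OrderGraph:
    """Extract order constraints for one chromosome from all component maps.

    For each map, an edge a -> b (with the map's cM distance) is added for
    every marker pair separated by at most ``max_interval`` positions in that
    map's order; ``max_interval=1`` keeps consecutive pairs only.
    """
    if max_interval < 1:
        raise ValueError("max_interval must be >= 1")
    exclude = exclude or set()
    g = nx.DiGraph(chromosome=chromosome)
    seen = False
    for m in maps:
        sub = m.chromosome(chromosome)
        markers = [mk for mk in sub["marker"] if mk not in exclude]
        pos = dict(zip(sub["marker"], sub["pos_cM"]))
        if markers:
            seen = True
        g.add_nodes_from(markers)
        for i, a in enumerate(markers):
            for j in range(i + 1, min(i + 1 + max_interval, len(markers))):
                b = markers[j]
                d = float(pos[b] - pos[a])
                if g.has_edge(a, b):
                    g[a][b]["support"].append((m.map_id, d))
                else:
                    g.add_edge(a, b, support=[(m.map_id, d)])
    if not seen:
        raise ValueError(f"chromosome {chromosome!r} absent from all maps")
    return OrderGraph(chromosome, g)


def _cycles_capped(g: nx.DiGraph, cap: int = 5000) -> list[list[str]]:
    cycles = []
    for cyc in nx.simple_cycles(g):
        cycles.append(cyc)
        if len(cycles) >= cap:
            break
    return cycles


def resolve_conflicts(
    order_graph: OrderGraph,
) -> tuple[OrderGraph, list[tuple[str, str, str]]]:
    """Remove order constraints until the graph is acyclic.

    Greedy heuristic: among all edges on currently known simple cycles,
    remove the one on the most cycles; ties go to the edge with the fewest
    supporting maps, then lexicographically smallest (determinism).  Exact
    minimality is not guaranteed (feedback arc set is NP-hard) but holds on
    small instances, which the test suite verifies by brute force.
    """
    g = order_graph.graph.copy()
    removed: list[tuple[str, str, str]] = []
    while not nx.is_directed_acyclic_graph(g):
        cycles = _cycles_capped(g)
        counts: dict[tuple[str, str], int] = {}
        for cyc in cycles:
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        edge = min(
            counts,
            key=lambda e: (-counts[e], len(g[e[0]][e[1]]["support"]), e),
        )
        for map_id, _d in g[edge[0]][edge[1]]["support"]:
            removed.append((map_id, edge[0], edge[1]))
        g.remove_edge(*edge)
    return OrderGraph(order_graph.chromosome, g), removed


def _solve_merge_lp(
    g: nx.DiGraph, centroid: dict[str, float]
) -> tuple[dict[str, float], float]:
    """L1-optimal consensus coordinates for one acyclic constraint graph.

    Variables: one free coordinate per marker, plus slack pairs (u, v) for
    every per-map distance term and for every centroid tie-break term.
    """
    markers = sorted(g.nodes)
    idx = {m: i for i, m in enumerate(markers)}
    n = len(markers)
    terms = [
        (idx[a], idx[b], d)
        for a, b in sorted(g.edges)
        for _map_id, d in g[a][b]["support"]
    ]
    t = len(terms)

    # column layout: [x (n, free)] [u,v per term (2t)] [p,q per marker (2n)]
    ncol = n + 2 * t + 2 * n
    cost = np.zeros(ncol)
    cost[n : n + 2 * t] = 1.0
    cost[n + 2 * t :] = TIEBREAK_EPS

    rows, cols, vals, rhs = [], [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    r = 0
    for k, (ia, ib, d) in enumerate(terms):  # x_b - x_a - u_k + v_k = d
        add(r, ib, 1.0)
        add(r, ia, -1.0)
        add(r, n + 2 * k, -1.0)
        add(r, n + 2 * k + 1, 1.0)
        rhs.append(d)
        r += 1
    for i, m in enumerate(markers):  # x_i - p_i + q_i = centroid_i
        add(r, i, 1.0)
        add(r, n + 2 * t + 2 * i, -1.0)
        add(r, n + 2 * t + 2 * i + 1, 1.0)
        rhs.append(centroid[m])
        r += 1
    a_eq = coo_matrix((vals, (rows, cols)), shape=(r, ncol))

    # order constraints x_a - x_b <= 0 for every retained edge
    rows, cols, vals = [], [], []
    edges = sorted(g.edges)
    for k, (a, b) in enumerate(edges):
        rows.extend([k, k])
        cols.extend([idx[a], idx[b]])
        vals.extend([1.0, -1.0])
    a_ub = coo_matrix((vals, (rows, cols)), shape=(len(edges), ncol))

    bounds = [(None, None)] * n + [(0, None)] * (2 * t + 2 * n)
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=np.zeros(len(edges)),
        A_eq=a_eq,
        b_eq=np.array(rhs),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(
            f"consensus LP failed ({res.message}); "
            f"{n} markers, {t} distance terms, {len(edges)} order constraints"
        )
    x = res.x[:n]
    objective = float(np.abs([x[ib] - x[ia] - d for ia, ib, d in terms]).sum())
    return dict(zip(markers, x)), objective


def merge_maps(
    maps: Sequence[GeneticMap],
    chromosome: str,
    max_interval: int = 1,
) -> ConsensusMap:
    """Merge the component maps of one chromosome into a consensus map.

    Positions are shifted so the chromosome starts at 0; marker order is a
    linear extension of every retained constraint (position ties broken by
    the topological order of the constraint graph).
    """
    conflicted = _conflicting_chromosome_markers(maps)
    excluded = [
        (mk, "assigned to different chromosomes in different maps")
        for mk in sorted(conflicted)
    ]
    og = build_order_graph(maps, chromosome, max_interval, exclude=conflicted)
    dag, removed = resolve_conflicts(og)

    map_pos = {m.map_id: m.positions(chromosome) for m in maps}
    centroid: dict[str, float] = {}
    for mk in dag.graph.nodes:
        vals = [pos[mk] for pos in map_pos.values() if mk in pos]
        centroid[mk] = float(np.mean(vals))

    positions, objective = _solve_merge_lp(dag.graph, centroid)
    if positions:
        shift = min(positions.values())
        positions = {m: p - shift for m, p in positions.items()}

    topo = {m: i for i, m in enumerate(nx.lexicographical_topological_sort(dag.graph))}
    markers = sorted(positions, key=lambda m: (positions[m], topo[m]))
    provenance = {
        mk: ";".join(sorted(mid for mid, pos in map_pos.items() if mk in pos))
        for mk in markers
    }
    entries = pd.DataFrame(
        {
            "marker": markers,
            "chrom": chromosome,
            "pos_cM": [positions[m] for m in markers],
            "maps": [provenance[m] for m in markers],
        }
    )
    return ConsensusMap(entries, removed, excluded, objective)


def merge_all_chromosomes(
    maps: Sequence[GeneticMap], max_interval: int = 1
) -> ConsensusMap:
    """Merge every chromosome present in any component map, independently."""
    chroms = sorted({c for m in maps for c in m.chromosomes})
    parts, removed, excluded, objective = [], [], [], 0.0
    for chrom in chroms:
        cm = merge_maps(maps, chrom, max_interval)
        parts.append(cm.entries)
        removed.extend(cm.removed_constraints)
        excluded.extend(cm.excluded_markers)
        objective += cm.objective
    entries = pd.concat(parts, ignore_index=True)
    return ConsensusMap(entries, removed, sorted(set(excluded)), objective)


def consensus_objective(
    maps: Sequence[GeneticMap],
    chromosome: str,
    positions: dict[str, float],
    max_interval: int = 1,
) -> float:
    """Sum of absolute errors of candidate coordinates against retained
    constraints — lets any candidate solution be scored against the LP's."""
    og = build_order_graph(
        maps, chromosome, max_interval, exclude=_conflicting_chromosome_markers(maps)
    )
    dag, _ = resolve_conflicts(og)
    total = 0.0
    for a, b in dag.graph.edges:
        for _map_id, d in dag.graph[a][b]["support"]:
            total += abs(positions[b] - positions[a] - d)
    return total


def map_summary(consensus: ConsensusMap) -> pd.DataFrame:
    """Per-chromosome marker counts, lengths, densities and gap statistics.

    The final ``total`` row sums counts/lengths and recomputes the derived
    columns from the totals.
    """
    rows = []
    for chrom, sub in consensus.entries.groupby("chrom", sort=True):
        pos = np.sort(sub["pos_cM"].to_numpy())
        length = float(pos[-1] - pos[0]) if len(pos) else 0.0
        gaps = np.diff(pos)
        rows.append(
            {
                "chrom": chrom,
                "n_markers": len(pos),
                "length_cM": length,
                "markers_per_cM": len(pos) / length if length > 0 else np.nan,
                "mean_gap_cM": float(gaps.mean()) if len(gaps) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    total_len = df["length_cM"].sum()
    n_total = int(df["n_markers"].sum())
    total = {
        "chrom": "total",
        "n_markers": n_total,
        "length_cM": total_len,
        "markers_per_cM": n_total / total_len if total_len > 0 else np.nan,
        "mean_gap_cM": total_len / (n_total - len(df)) if n_total > len(df) else np.nan,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
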