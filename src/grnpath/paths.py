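"""Shortest-path candidate-gene discovery.

Under the guilt-by-association rule, genes lying on shortest beta-weighted
paths between pairs of known disease genes ("seeds") are new disease-gene
candidates. The network view is undirected by default — many seeds are non-TF
targets with no out-edges, and paths between such pairs only exist through
incoming regulations — with antiparallel duplicate edges merged keeping the
smaller beta. Paths are found with Dijkstra's algorithm; among equally short
paths the tie-break is deterministic: fewest hops, then lexicographically
smallest node sequence. Seeds absent from the network are skipped with a
warning, and seed pairs in different components simply yield no path.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .grn import GRN

logger = logging.getLogger("grnpath")

__all__ = [
    "PathResult",
    "PathGeneSet",
    "to_path_graph",
    "seed_pair_paths",
    "extract_path_genes",
    "export_subnetwork",
]


@dataclass
class PathResult:
    """One seed pair's shortest path."""

    source_id: str
    target_id: str
    node_sequence: tuple[str, ...]
    total_beta: float

    @property
    def interior(self) -> tuple[str, ...]:
        return self.node_sequence[1:-1]


@dataclass
class PathGeneSet:
    """Non-seed genes found on shortest paths, with provenance."""

    roles: dict[str, str]
    provenance: dict[str, set]  # gene id -> set of (source, target) seed pairs

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.roles)

    def role_counts(self) -> dict[str, int]:
        counts = {"TF": 0, "miRNA": 0, "gene": 0}
        for role in self.roles.values():
            counts[role] += 1
        return counts


def to_path_graph(grn: GRN, mode: str = "undirected") -> nx.Graph:
    """Build the weighted path graph from a GRN.

    Undirected mode merges antiparallel duplicates keeping the smaller beta;
    directed mode preserves both directions. Node ``role`` attributes are set
    from the GRN. Edge weight attribute: ``beta``.
    """
    if mode not in ("undirected", "directed"):
        raise ValueError("mode must be 'undirected' or 'directed'")
    if not grn.edges:
        raise ValueError("GRN is empty")
    g: nx.Graph = nx.Graph() if mode == "undirected" else nx.DiGraph()
    for node, role in grn.nodes.items():
        g.add_node(node, role=role)
    for e in grn.edges:
        if mode == "undirected" and g.has_edge(e.regulator_id, e.target_id):
            if e.beta < g[e.regulator_id][e.target_id]["beta"]:
                g[e.regulator_id][e.target_id]["beta"] = e.beta
        else:
            g.add_edge(e.regulator_id, e.target_id, beta=e.beta)
    return g


def _dijkstra_best(g: nx.Graph, source: str) -> dict[str, tuple[float, int, tuple[str, ...]]]:
    """Single-source Dijkstra with full deterministic tie-breaking.

    Heap keys are (distance, hops, node_sequence); tuple comparison makes the
    first settlement of each node its lexicographically best shortest path.
    Correct because beta >= 0 keeps the key monotone along any extension.
    """
    settled: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    neighbors = g.neighbors if not g.is_directed() else g.successors
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled[node] = (dist, hops, path)
        for nbr in sorted(neighbors(node)):
            if nbr in settled:
                continue
            heapq.heappush(heap, (dist + g[node][nbr]["beta"], hops + 1, path + (nbr,)))
    return settled


def _co_optimal_paths(g: nx.Graph, source: str, target: str,
                      best: float, tol: float = 1e-12) -> list[tuple[str, ...]]:
    """All simple paths whose total beta is within tol of the optimum."""
    # distance lower bounds from the target prune the search
    rev = g.reverse(copy=False) if g.is_directed() else g
    bound = {n: d for n, (d, _, _) in _dijkstra_best(rev, target).items()}
    out: list[tuple[str, ...]] = []

    def walk(path: list[str], dist: float) -> None:
        node = path[-1]
        if node == target:
            out.append(tuple(path))
            return
        nbrs = g.successors(node) if g.is_directed() else g.neighbors(node)
        for nbr in sorted(nbrs):
            if nbr in path:
                continue
            d = dist + g[node][nbr]["beta"]
            if nbr in bound and d + bound[nbr] <= best + tol:
                walk(path + [nbr], d)

    walk([source], 0.0)
    return out


def seed_pair_paths(
    g: nx.Graph,
    seeds: Sequence[str],
    all_optimal: bool = False,
) -> list[PathResult]:
    """Shortest path for every unordered pair of mapped seeds.

    Seeds missing from the graph are skipped with a warning; pairs in
    different components yield no path (logged). With ``all_optimal=True``,
    every co-optimal path of a pair is returned instead of only the
    tie-broken one.
    """
    mapped = [s for s in seeds if s in g]
    unmapped = [s for s in seeds if s not in g]
    if unmapped:
        logger.warning("seed_pair_paths: %d seeds not in graph: %s",
                       len(unmapped), ", ".join(unmapped))
    if len(mapped) < 2:
        raise ValueError("need >= 2 seeds mapped to the graph")
    mapped_sorted = sorted(set(mapped))
    results: list[PathResult] = []
    n_unreachable = 0
    for i, src in enumerate(mapped_sorted):
        settled = _dijkstra_best(g, src)
        for dst in mapped_sorted[i + 1:]:
            if dst not in settled:
                n_unreachable += 1
                continue
            dist, _, path = settled[dst]
            if all_optimal:
                for p in _co_optimal_paths(g, src, dst, dist):
                    results.append(PathResult(src, dst, p, dist))
            else:
                results.append(PathResult(src, dst, path, dist))
    if n_unreachable:
        logger.info("seed_pair_paths: %d seed pairs had no connecting path", n_unreachable)
    return results


def extract_path_genes(
    paths: Iterable[PathResult],
    seeds: Iterable[str],
    roles: dict[str, str],
) -> PathGeneSet:
    """Interior nodes of all paths, minus seeds — the new candidate genes."""
    seed_set = set(seeds)
    found_roles: dict[str, str] = {}
    provenance: dict[str, set] = {}
    for p in paths:
        for node in p.interior:
            if node in seed_set:
                continue
            found_roles[node] = roles.get(node, "gene")
            provenance.setdefault(node, set()).add((p.source_id, p.target_id))
    return PathGeneSet(found_roles, provenance)


def export_subnetwork(
    paths: Iterable[PathResult],
    seeds: Iterable[str],
    roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Union of all path edges, each once, with node seed/candidate flags.

    Columns: node_a, node_b, beta-free (topology only); node annotation is
    joined in as role/is_seed columns for both endpoints.
    """
    seed_set = set(seeds)
    roles = roles or {}
    edges: set[tuple[str, str]] = set()
    for p in paths:
        for a, b in zip(p.node_sequence, p.node_sequence[1:]):
            edges.add((a, b) if a <= b else (b, a))
    rows = [
        {
            "node_a": a,
            "node_b": b,
            "role_a": roles.get(a, "gene"),
            "role_b": roles.get(b, "gene"),
            "a_is_seed": a in seed_set,
            "b_is_seed": b in seed_set,
        }
        for a, b in sorted(edges)
    ]
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "role_a", "role_b", "a_is_seed", "b_is_seed"])


def write_paths_tsv(paths: Sequence[PathResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "source": p.source_id,
                "target": p.target_id,
                "total_beta": p.total_beta,
                "node_sequence": ",".join(p.node_sequence),
            }
            for p in paths
        ],
        columns=["source", "target", "total_beta", "node_sequence"],
    )
    frame.to_csv(path, sep="\t", index=False)
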