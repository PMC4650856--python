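"""Shortest-path discovery: graph construction, Dijkstra, path genes."""

import itertools

import networkx as nx
import numpy as np
import pytest

from grnpath.grn import GRN, GRNEdge
from grnpath.paths import (export_subnetwork, extract_path_genes, seed_pair_paths,
                           to_path_graph)


def _edge(reg, tgt, alpha, reg_role="TF", tgt_role="gene"):
    return GRNEdge(reg, tgt, reg_role, tgt_role, frozenset({"predicted"}),
                   alpha, 1.0 - abs(alpha))


def _grn(edges):
    return GRN(list(edges), cutoff_tf=0.0, cutoff_mirna=0.0)


def brute_force_shortest(g, source, target):
    """Oracle: minimum total beta over exhaustive simple-path enumeration."""
    best = None
    for path in nx.all_simple_paths(g, source, target):
        total = sum(g[a][b]["beta"] for a, b in zip(path, path[1:]))
        if best is None or total < best - 1e-15:
            best = total
    return best


class TestToPathGraph:
    def test_single_edge_weight_is_beta(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9)]))
        assert g["A"]["B"]["beta"] == pytest.approx(0.1)

    def test_antiparallel_merge_keeps_smaller_beta(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9), _edge("B", "A", 0.7)]),
                          mode="undirected")
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["beta"] == pytest.approx(0.1)

    def test_directed_mode_preserves_both(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9), _edge("B", "A", 0.7)]),
                          mode="directed")
        assert g.number_of_edges() == 2

    def test_empty_grn_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            to_path_graph(_grn([]))


class TestSeedPairPaths:
    def test_chain_path_found(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9), _edge("B", "C", 0.9),
                                _edge("C", "D", 0.9)]))
        [res] = seed_pair_paths(g, ["A", "D"])
        assert res.node_sequence == ("A", "B", "C", "D")
        assert res.total_beta == pytest.approx(0.3)

    def test_cheaper_detour_beats_direct_edge(self):
        # direct A-B beta 0.5; detour A-C-B total 0.3
        g = to_path_graph(_grn([_edge("A", "B", 0.5), _edge("A", "C", 0.85),
                                _edge("C", "B", 0.85)]))
        [res] = seed_pair_paths(g, ["A", "B"])
        assert res.node_sequence == ("A", "C", "B")
        assert res.total_beta == pytest.approx(0.3)
        assert res.total_beta <= g["A"]["B"]["beta"]

    def test_disconnected_seed_yields_no_path(self, caplog):
        g = to_path_graph(_grn([_edge("A", "B", 0.9), _edge("C", "D", 0.9)]))
        with caplog.at_level("INFO", logger="grnpath"):
            results = seed_pair_paths(g, ["A", "B", "C"])
        pairs = {(r.source_id, r.target_id) for r in results}
        assert pairs == {("A", "B")}

    def test_unmapped_seeds_skipped_with_warning(self, caplog):
        g = to_path_graph(_grn([_edge("A", "B", 0.9)]))
        with caplog.at_level("WARNING", logger="grnpath"):
            results = seed_pair_paths(g, ["A", "B", "GHOST"])
        assert len(results) == 1
        assert any("GHOST" in r.message for r in caplog.records)

    def test_fewer_than_two_mapped_seeds_errors(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9)]))
        with pytest.raises(ValueError, match=">= 2 seeds"):
            seed_pair_paths(g, ["A", "GHOST"])

    def test_tie_break_prefers_fewer_hops_then_lexicographic(self):
        # two co-optimal routes A-C-Z and A-B-Z (equal beta): lexicographic
        # picks B; a three-hop route of equal cost must lose to either
        edges = [_edge("A", "B", 0.8), _edge("B", "Z", 0.8),
                 _edge("A", "C", 0.8), _edge("C", "Z", 0.8),
                 _edge("A", "D", 0.9), _edge("D", "E", 0.8), _edge("E", "Z", 0.9)]
        g = to_path_graph(_grn(edges))
        [res] = seed_pair_paths(g, ["A", "Z"])
        assert res.node_sequence == ("A", "B", "Z")

    def test_all_optimal_mode_enumerates_ties(self):
        edges = [_edge("A", "B", 0.8), _edge("B", "Z", 0.8),
                 _edge("A", "C", 0.8), _edge("C", "Z", 0.8)]
        g = to_path_graph(_grn(edges))
        results = seed_pair_paths(g, ["A", "Z"], all_optimal=True)
        assert {r.node_sequence for r in results} == {("A", "B", "Z"), ("A", "C", "Z")}

    def test_zero_weight_edges_allowed(self):
        g = to_path_graph(_grn([_edge("A", "B", 1.0), _edge("B", "C", 1.0)]))
        [res] = seed_pair_paths(g, ["A", "C"])
        assert res.total_beta == pytest.approx(0.0)

    def test_independent_of_seed_order(self):
        rng = np.random.default_rng(0)
        edges = [_edge(f"N{i}", f"N{j}", rng.uniform(0.5, 0.99))
                 for i, j in itertools.combinations(range(6), 2) if rng.random() < 0.6]
        g = to_path_graph(_grn(edges))
        seeds = [f"N{i}" for i in range(6) if f"N{i}" in g]
        fwd = seed_pair_paths(g, seeds)
        rev = seed_pair_paths(g, seeds[::-1])
        key = lambda rs: sorted((r.source_id, r.target_id, r.node_sequence) for r in rs)
        assert key(fwd) == key(rev)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = rng.integers(4, 9)
            g = nx.gnp_random_graph(int(n), 0.5, seed=int(rng.integers(1 << 30)))
            for a, b in g.edges:
                g[a][b]["beta"] = float(rng.uniform(0.0, 1.0))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            seeds = [f"N{i}" for i in range(n) if f"N{i}" in g][:4]
            if len(seeds) < 2:
                continue
            results = {(r.source_id, r.target_id): r.total_beta
                       for r in seed_pair_paths(g, seeds)}
            for a, b in itertools.combinations(sorted(seeds), 2):
                expected = brute_force_shortest(g, a, b)
                if expected is None:
                    assert (a, b) not in results
                else:
                    assert results[(a, b)] == pytest.approx(expected, abs=1e-9)

    def test_total_beta_equals_member_edge_sum(self):
        rng = np.random.default_rng(5)
        edges = [_edge(f"N{i}", f"N{i+1}", rng.uniform(0.5, 0.99)) for i in range(6)]
        g = to_path_graph(_grn(edges))
        [res] = seed_pair_paths(g, ["N0", "N6"])
        member_sum = sum(g[a][b]["beta"]
                         for a, b in zip(res.node_sequence, res.node_sequence[1:]))
        assert res.total_beta == pytest.approx(member_sum, abs=1e-9)


class TestPathGenes:
    def test_interior_minus_seeds(self):
        g = to_path_graph(_grn([_edge("A", "X", 0.9), _edge("X", "B", 0.9)]))
        paths = seed_pair_paths(g, ["A", "B"])
        pg = extract_path_genes(paths, ["A", "B"], {"X": "TF"})
        assert pg.gene_ids == ["X"]
        assert pg.provenance["X"] == {("A", "B")}
        assert pg.role_counts()["TF"] == 1

    def test_direct_edge_contributes_nothing(self):
        g = to_path_graph(_grn([_edge("A", "B", 0.9)]))
        paths = seed_pair_paths(g, ["A", "B"])
        assert extract_path_genes(paths, ["A", "B"], {}).gene_ids == []

    def test_planted_intermediates_recovered(self, dataset):
        from grnpath.grn import build_grn, score_edges
        scored = score_edges(dataset.candidate_edges, dataset.mrna, dataset.mirna)
        net = build_grn(scored, 0.6, 0.6)
        g = to_path_graph(net)
        paths = seed_pair_paths(g, dataset.seeds)
        pg = extract_path_genes(paths, dataset.seeds, net.nodes)
        assert set(dataset.ground_truth.plant_path_intermediates) <= set(pg.gene_ids)

    def test_subnetwork_union_deduplicates_shared_edges(self):
        g = to_path_graph(_grn([_edge("A", "X", 0.9), _edge("X", "B", 0.9),
                                _edge("X", "C", 0.9)]))
        paths = seed_pair_paths(g, ["A", "B", "C"])
        sub = export_subnetwork(paths, ["A", "B", "C"], {"X": "TF"})
        # brute-force union of path edges
        expected = set()
        for p in paths:
            for a, b in zip(p.node_sequence, p.node_sequence[1:]):
                expected.add(tuple(sorted((a, b))))
        assert set(map(tuple, sub[["node_a", "node_b"]].to_numpy())) == expected
        assert len(sub) == len(expected)

    def test_zero_paths_empty_network(self):
        assert export_subnetwork([], ["A"], {}).empty
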