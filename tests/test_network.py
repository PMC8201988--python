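"""Graph construction, PageRank propagation, ranking, and rewiring."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epirank.network import (
    build_graph,
    pagerank_scores,
    promoter_only_ranks,
    rank_genes,
    rewire_degree_preserving,
)
from epirank.regions import PIR, GenomicRegion, Promoter

from conftest import pagerank_power_iteration


def promoter(gene, tss=1000, chrom="chr1"):
    return Promoter(
        region=GenomicRegion(chrom, max(0, tss - 1000), tss + 1000, f"prom_{gene}"),
        gene=gene,
        tss=tss,
    )


def pir(name, start=50_000, chrom="chr1"):
    return PIR(region=GenomicRegion(chrom, start, start + 1000, name))


class TestBuildGraph:
    def test_star(self):
        graph = build_graph(
            [promoter("G1")],
            [pir("p1"), pir("p2", 60_000)],
            [("p1", "prom_G1"), ("p2", "prom_G1")],
            {"prom_G1": 1.0, "p1": 2.0, "p2": 3.0},
        )
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        assert graph.nodes["p2"]["weight"] == 3.0

    def test_duplicate_edges_collapse(self):
        graph = build_graph(
            [promoter("G1")], [pir("p1")],
            [("p1", "prom_G1")] * 3,
            {"prom_G1": 1.0, "p1": 1.0},
        )
        assert graph.number_of_edges() == 1

    def test_pir_targeting_two_promoters(self):
        graph = build_graph(
            [promoter("G1"), promoter("G2", 9000)], [pir("p1")],
            [("p1", "prom_G1"), ("p1", "prom_G2")],
            {"prom_G1": 1.0, "prom_G2": 1.0, "p1": 1.0},
        )
        assert graph.out_degree("p1") == 2

    def test_unknown_edge_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_graph([promoter("G1")], [], [("ghost", "prom_G1")], {"prom_G1": 1.0})

    def test_edge_from_promoter_rejected(self):
        with pytest.raises(ValueError, match="promoter"):
            build_graph(
                [promoter("G1"), promoter("G2", 9000)], [],
                [("prom_G1", "prom_G2")], {"prom_G1": 1.0, "prom_G2": 1.0},
            )

    def test_missing_score_defaults_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            graph = build_graph([promoter("G1")], [], [], {})
        assert graph.nodes["prom_G1"]["weight"] == 0.0


class TestPageRank:
    def test_single_promoter_takes_all_mass(self):
        graph = build_graph([promoter("G1")], [], [], {"prom_G1": 5.0})
        table = pagerank_scores(graph)
        assert table.gene_scores["G1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("damping", [0.1, 0.5, 0.85, 0.99])
    def test_disconnected_promoters_split_by_weight(self, damping):
        graph = build_graph(
            [promoter("G1"), promoter("G2", 9000)], [], [],
            {"prom_G1": 3.0, "prom_G2": 1.0},
        )
        table = pagerank_scores(graph, damping=damping)
        assert table.gene_scores["G1"] == pytest.approx(0.75, abs=1e-9)
        assert table.gene_scores["G2"] == pytest.approx(0.25, abs=1e-9)

    def test_star_promoter_accumulates_more_than_pirs(self):
        graph = build_graph(
            [promoter("G1")], [pir("p1"), pir("p2", 60_000)],
            [("p1", "prom_G1"), ("p2", "prom_G1")],
            {"prom_G1": 1.0, "p1": 1.0, "p2": 1.0},
        )
        table = pagerank_scores(graph)
        ranks = table.node_pagerank
        assert ranks["prom_G1"] > ranks["p1"]
        assert ranks["prom_G1"] > ranks["p2"]

    def test_conservation_and_oracle_on_small_graphs(self):
        """All graphs with <=6 vertices, several weightings: matches the
        dense power-iteration oracle to 1e-9 and sums to 1."""
        rng = np.random.default_rng(0)
        for n_prom, n_pir in [(1, 1), (2, 2), (3, 3), (2, 4), (4, 2)]:
            promoters = [promoter(f"G{i}", 1000 + 10_000 * i) for i in range(n_prom)]
            pirs = [pir(f"p{i}", 200_000 + 10_000 * i) for i in range(n_pir)]
            possible = list(itertools.product(
                [p.id for p in pirs], [p.id for p in promoters]
            ))
            for trial in range(3):
                k = int(rng.integers(0, len(possible) + 1))
                chosen = [possible[i] for i in rng.choice(len(possible), size=k, replace=False)]
                weights = {
                    node.id: float(rng.integers(0, 4))
                    for node in promoters + pirs
                }
                if sum(weights.values()) == 0:
                    weights[promoters[0].id] = 1.0
                graph = build_graph(promoters, pirs, chosen, weights)
                table = pagerank_scores(graph)
                oracle = pagerank_power_iteration(graph)
                assert sum(table.node_pagerank.values()) == pytest.approx(1.0, abs=1e-9)
                for node in graph:
                    assert table.node_pagerank[node] == pytest.approx(
                        oracle[node], abs=1e-9
                    )

    def test_zero_weight_pir_is_neutral(self):
        base = build_graph([promoter("G1")], [], [], {"prom_G1": 2.0})
        with_pir = build_graph(
            [promoter("G1")], [pir("p1")], [("p1", "prom_G1")],
            {"prom_G1": 2.0, "p1": 0.0},
        )
        score = pagerank_scores(base).gene_scores["G1"]
        score_with = pagerank_scores(with_pir).gene_scores["G1"]
        assert score_with == pytest.approx(score, abs=1e-9)

    def test_increasing_pir_weight_helps_its_gene_relative_to_others(self):
        """More weight on an enhancer improves its target gene relative to
        competing genes (absolute PageRank shares all shrink as the
        enhancer vertex itself retains more restart mass)."""

        def score_ratio(weight):
            graph = build_graph(
                [promoter("G1"), promoter("G2", 9000)],
                [pir("p1")], [("p1", "prom_G1")],
                {"prom_G1": 1.0, "prom_G2": 1.0, "p1": weight},
            )
            scores = pagerank_scores(graph).gene_scores
            return scores["G1"] / scores["G2"]

        ratios = [score_ratio(w) for w in (0.0, 0.5, 1.0, 4.0)]
        assert all(b >= a - 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_all_zero_weights_fall_back_to_uniform(self, caplog):
        graph = build_graph(
            [promoter("G1"), promoter("G2", 9000)], [], [],
            {"prom_G1": 0.0, "prom_G2": 0.0},
        )
        with caplog.at_level("WARNING"):
            table = pagerank_scores(graph)
        assert table.gene_scores["G1"] == pytest.approx(0.5)

    def test_bad_damping_rejected(self):
        graph = build_graph([promoter("G1")], [], [], {"prom_G1": 1.0})
        for damping in (0.0, 1.0, -0.5, 1.7):
            with pytest.raises(ValueError):
                pagerank_scores(graph, damping=damping)

    def test_multi_promoter_gene_sums_mass(self):
        promoters = [promoter("G1", 1000), promoter("G1", 9000), promoter("G2", 20_000)]
        # distinct element ids for the two G1 promoters
        promoters[1] = Promoter(
            region=GenomicRegion("chr1", 8000, 10_000, "prom_G1b"), gene="G1", tss=9000
        )
        graph = build_graph(
            promoters, [], [], {"prom_G1": 1.0, "prom_G1b": 1.0, "prom_G2": 2.0}
        )
        table = pagerank_scores(graph)
        assert table.gene_scores["G1"] == pytest.approx(0.5, abs=1e-9)


class TestRanking:
    def test_descending_by_score(self):
        ranked = rank_genes(pd.Series({"A": 0.5, "B": 0.3}))
        assert list(ranked["gene"]) == ["A", "B"]
        assert list(ranked.index) == [1, 2]

    def test_ties_break_lexicographically(self):
        ranked = rank_genes(pd.Series({"B": 0.4, "A": 0.4}))
        assert list(ranked["gene"]) == ["A", "B"]

    def test_order_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.random(50), index=[f"G{i}" for i in range(50)])
        assert list(rank_genes(scores)["gene"]) == list(rank_genes(scores * 7.3)["gene"])

    def test_promoter_only_matches_network_on_edgeless_graph(self):
        """Without enhancers PageRank reduces to the personalization, so
        both rankings agree."""
        promoters = [promoter(f"G{i}", 1000 + 10_000 * i) for i in range(6)]
        scores = {p.id: float(i + 1) for i, p in enumerate(promoters)}
        graph = build_graph(promoters, [], [], scores)
        network_ranks = rank_genes(pagerank_scores(graph).gene_scores)
        baseline = promoter_only_ranks(promoters, scores)
        assert list(network_ranks["gene"]) == list(baseline["gene"])

    def test_single_gene(self):
        ranked = promoter_only_ranks([promoter("G1")], {"prom_G1": 1.0})
        assert list(ranked["gene"]) == ["G1"] and list(ranked.index) == [1]


def random_bipartite(rng, n_prom=5, n_pir=8, p_edge=0.4):
    promoters = [promoter(f"G{i}", 1000 + 10_000 * i) for i in range(n_prom)]
    pirs = [pir(f"p{i}", 200_000 + 10_000 * i) for i in range(n_pir)]
    edges = [
        (p.id, q.id)
        for p in pirs
        for q in promoters
        if rng.random() < p_edge
    ]
    weights = {node.id: float(rng.random()) for node in promoters + pirs}
    return build_graph(promoters, pirs, edges, weights)


class TestRewiring:
    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            graph = random_bipartite(rng)
            rewired = rewire_degree_preserving(graph, seed=trial)
            assert dict(graph.in_degree()) == dict(rewired.in_degree())
            assert dict(graph.out_degree()) == dict(rewired.out_degree())

    def test_same_seed_same_graph(self):
        graph = random_bipartite(np.random.default_rng(3))
        a = rewire_degree_preserving(graph, seed=42)
        b = rewire_degree_preserving(graph, seed=42)
        assert set(a.edges()) == set(b.edges())

    def test_different_seed_usually_differs(self):
        graph = random_bipartite(np.random.default_rng(4), n_prom=8, n_pir=12)
        a = rewire_degree_preserving(graph, seed=1)
        b = rewire_degree_preserving(graph, seed=2)
        assert set(a.edges()) != set(b.edges())

    def test_fewer_than_two_edges_unchanged(self, caplog):
        graph = build_graph(
            [promoter("G1")], [pir("p1")], [("p1", "prom_G1")],
            {"prom_G1": 1.0, "p1": 1.0},
        )
        with caplog.at_level("WARNING"):
            rewired = rewire_degree_preserving(graph)
        assert set(rewired.edges()) == set(graph.edges())

    def test_complete_bipartite_is_rigid(self):
        """K_{2,2} admits only one degree-preserving configuration."""
        promoters = [promoter("G1"), promoter("G2", 9000)]
        pirs = [pir("p1"), pir("p2", 60_000)]
        edges = [(p.id, q.id) for p in pirs for q in promoters]
        graph = build_graph(
            promoters, pirs, edges, {n.id: 1.0 for n in promoters + pirs}
        )
        rewired = rewire_degree_preserving(graph, seed=0)
        assert set(rewired.edges()) == set(graph.edges())

    def test_weights_untouched(self):
        graph = random_bipartite(np.random.default_rng(5))
        rewired = rewire_degree_preserving(graph, seed=0)
        for node in graph:
            assert rewired.nodes[node]["weight"] == graph.nodes[node]["weight"]
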