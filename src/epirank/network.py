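"""Enhancer-promoter graph construction, PageRank propagation, and ranking.

Regulatory elements form a weighted directed graph: PIR (enhancer)
vertices point at the promoter vertices they interact with, and every
vertex carries its differential score as a weight.  Personalized PageRank
with the weight-derived restart vector propagates enhancer scores onto
their target promoters; because edges only run enhancer -> promoter,
promoters are the sinks that accumulate the mass.  The PageRank mass on a
gene's promoter vertices is its meta-gene score, and genes are ranked by
it.  Degree-preserving rewiring of the edge list provides a
connectivity-matched null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneScoreTable:
    """Meta-gene scores plus the underlying per-vertex PageRank values."""

    gene_scores: pd.Series
    node_pagerank: dict


def build_graph(promoters, pirs, edges, scores) -> nx.DiGraph:
    """Assemble the weighted directed enhancer->promoter graph.

    Vertices are element ids tagged ``kind`` ("promoter"/"pir") with a
    nonnegative ``weight`` (the element's dPC score; missing ids get 0
    with a warning) and, for promoters, a ``gene`` attribute.  Isolated
    promoters are retained so genes without enhancers are still ranked.
    """
    graph = nx.DiGraph()
    missing = 0

    def weight_of(element_id):
        nonlocal missing
        try:
            return float(scores[element_id])
        except KeyError:
            missing += 1
            return 0.0

    for prom in promoters:
        graph.add_node(prom.id, kind="promoter", gene=prom.gene, weight=weight_of(prom.id))
    for pir in pirs:
        graph.add_node(pir.id, kind="pir", weight=weight_of(pir.id))
    for pir_id, prom_id in edges:
        if pir_id not in graph or prom_id not in graph:
            raise ValueError(f"edge ({pir_id}, {prom_id}) references an unknown element")
        if graph.nodes[pir_id]["kind"] == "promoter":
            raise ValueError(f"edge may not originate at promoter {pir_id!r}")
        graph.add_edge(pir_id, prom_id)
    if missing:
        logger.warning("%d graph vertices had no score and got weight 0", missing)
    return graph


def pagerank_scores(
    graph: nx.DiGraph, damping: float = 0.85, gene_aggregation: str = "sum"
) -> GeneScoreTable:
    """Personalized PageRank over the element graph, aggregated per gene.

    The restart (personalization) vector is proportional to vertex
    weights; dangling vertices (promoters, which have no out-edges)
    redistribute their mass by the same vector, so the stationary
    distribution is a function of element weights and wiring only.  The
    meta-gene score is the sum (or max) of PageRank over the gene's
    promoter vertices.
    """
    if not 0 < damping < 1:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    if gene_aggregation not in ("sum", "max"):
        raise ValueError(f"unknown gene_aggregation {gene_aggregation!r}")
    if len(graph) == 0:
        raise ValueError("empty graph")
    weights = {node: float(graph.nodes[node].get("weight", 0.0)) for node in graph}
    if any(w < 0 for w in weights.values()):
        raise ValueError("vertex weights must be nonnegative")
    total = sum(weights.values())
    if total <= 0:
        logger.warning("all vertex weights are zero: using uniform personalization")
        weights = {node: 1.0 for node in graph}
    ranks = nx.pagerank(
        graph,
        alpha=damping,
        personalization=weights,
        dangling=None,  # dangling mass follows the personalization vector
        max_iter=10000,
        tol=1e-12 / len(graph),
    )
    per_gene: dict = {}
    for node, data in graph.nodes(data=True):
        if data.get("kind") != "promoter":
            continue
        gene = data["gene"]
        if gene_aggregation == "sum":
            per_gene[gene] = per_gene.get(gene, 0.0) + ranks[node]
        else:
            per_gene[gene] = max(per_gene.get(gene, 0.0), ranks[node])
    gene_scores = pd.Series(per_gene, name="score").sort_index()
    return GeneScoreTable(gene_scores=gene_scores, node_pagerank=ranks)


def rank_genes(gene_scores: pd.Series) -> pd.DataFrame:
    """Rank genes by descending score; ties break lexicographically.

    Returns a DataFrame with columns ``gene`` and ``score`` and index
    ``rank`` running from 1 (highest score).
    """
    if len(gene_scores) == 0:
        raise ValueError("no genes to rank")
    frame = gene_scores.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame.index = pd.RangeIndex(1, len(frame) + 1, name="rank")
    return frame


def promoter_only_ranks(
    promoters, scores, gene_aggregation: str = "sum"
) -> pd.DataFrame:
    """Baseline ranking from promoter element scores alone.

    Discards all enhancer contributions: each gene's score is the sum (or
    max) of its promoter elements' dPC scores.
    """
    if gene_aggregation not in ("sum", "max"):
        raise ValueError(f"unknown gene_aggregation {gene_aggregation!r}")
    per_gene: dict = {}
    missing = 0
    for prom in promoters:
        try:
            value = float(scores[prom.id])
        except KeyError:
            missing += 1
            value = 0.0
        if gene_aggregation == "sum":
            per_gene[prom.gene] = per_gene.get(prom.gene, 0.0) + value
        else:
            per_gene[prom.gene] = max(per_gene.get(prom.gene, 0.0), value)
    if missing:
        logger.warning("%d promoters had no score and contributed 0", missing)
    return rank_genes(pd.Series(per_gene))


def rewire_degree_preserving(
    graph: nx.DiGraph, n_swaps: int | None = None, seed: int = 0
) -> nx.DiGraph:
    """Randomize edges by double-edge swaps, preserving all degrees.

    Repeatedly picks two edges (a -> x) and (b -> y) and replaces them
    with (a -> y) and (b -> x) unless a duplicate edge would result.
    Every PIR keeps its out-degree and every promoter its in-degree
    exactly; vertex attributes (weights, genes) are untouched.  Default
    number of attempted swaps is 10 x |edges|.
    """
    edges = list(graph.edges())
    rewired = graph.copy()
    if len(edges) < 2:
        logger.warning("graph has < 2 edges: returned unchanged")
        return rewired
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, x), (b, y) = edges[i], edges[j]
        if a == b or x == y:
            continue
        if (a, y) in edge_set or (b, x) in edge_set:
            continue
        edge_set.discard((a, x))
        edge_set.discard((b, y))
        edge_set.add((a, y))
        edge_set.add((b, x))
        edges[i], edges[j] = (a, y), (b, x)
    rewired.remove_edges_from(list(rewired.edges()))
    rewired.add_edges_from(edges)
    return rewired
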