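"""End-to-end orchestration: inputs -> element scores -> gene rankings.

The pipeline mirrors the three analysis stages: (1) preprocess regions and
summarize multi-mark signal into the difference matrix D, (2) decompose D
by differential PCA and score every element, (3) propagate scores through
the enhancer-promoter graph with personalized PageRank and rank genes.
A promoter-only baseline ranking (ignoring enhancers) is produced
alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import network, regions, signal
from .dpca import DPCAResult, dpca, element_scores, loadings_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable parameters of the ranking pipeline.

    extension : promoter extension around the TSS, bases
    scale : length-normalization target (per-`scale`-base intensity);
        None disables length normalization
    power : power-transform exponent in (0, 1]
    n_dpcs : number of differential components summed into element scores
    damping : PageRank damping factor
    min_peak_samples : samples with supporting peaks required to retain a PIR
    linkage : "interactions" (anchor overlap) or "nearest" (nearest TSS)
    center : column-center D before the decomposition
    gene_aggregation : combine multiple promoters per gene by "sum" or "max"
    filter_pirs : apply the peak-support filter (requires peak calls)
    """

    extension: int = 1000
    scale: int | None = 1000
    power: float = 0.5
    n_dpcs: int = 2
    damping: float = 0.85
    min_peak_samples: int = 2
    support_marks: tuple = tuple(sorted(regions.DEFAULT_SUPPORT_MARKS))
    linkage: str = "interactions"
    center: bool = False
    gene_aggregation: str = "sum"
    filter_pirs: bool = True


@dataclass
class PipelineResult:
    promoters: list                 # extended
    pirs: list                      # retained
    edges: list
    signal_matrix: signal.ElementSignalMatrix
    diff: pd.DataFrame
    dpca: DPCAResult
    element_scores: pd.Series
    graph: nx.DiGraph
    gene_table: network.GeneScoreTable
    ranking: pd.DataFrame           # network-propagated ranking
    promoter_ranking: pd.DataFrame  # promoter-only baseline


def run_pipeline(
    promoters,
    pirs,
    tracks,
    interactions=None,
    peaks=None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full ranking pipeline on in-memory inputs.

    ``peaks`` maps (sample_id, mark) to peak regions; required unless
    ``params.filter_pirs`` is False.  ``interactions`` is required for
    linkage="interactions" and ignored for linkage="nearest".
    """
    params = params or PipelineParams()
    extended = regions.extend_promoters(promoters, params.extension)
    if params.filter_pirs:
        retained = regions.filter_pirs_by_peaks(
            pirs,
            peaks or {},
            marks=params.support_marks,
            min_samples=params.min_peak_samples,
        )
    else:
        retained = list(pirs)

    if params.linkage == "interactions":
        if interactions is None:
            raise ValueError("linkage='interactions' requires interaction records")
        edges = regions.link_by_interactions(extended, retained, interactions)
    elif params.linkage == "nearest":
        edges = regions.link_by_nearest(extended, retained)
    else:
        raise ValueError(f"unknown linkage {params.linkage!r}")

    elements = list(extended) + list(retained)
    raw = signal.build_signal_matrix(tracks, elements, scale=params.scale)
    normalized = signal.normalize_matrix(raw, power=params.power)
    diff = signal.difference_matrix(normalized)
    decomposition = dpca(diff, center=params.center, k=params.n_dpcs)
    scores = element_scores(decomposition, k=params.n_dpcs)

    graph = network.build_graph(extended, retained, edges, scores)
    gene_table = network.pagerank_scores(
        graph, damping=params.damping, gene_aggregation=params.gene_aggregation
    )
    ranking = network.rank_genes(gene_table.gene_scores)
    promoter_ranking = network.promoter_only_ranks(
        extended, scores, gene_aggregation=params.gene_aggregation
    )
    return PipelineResult(
        promoters=extended,
        pirs=retained,
        edges=edges,
        signal_matrix=normalized,
        diff=diff,
        dpca=decomposition,
        element_scores=scores,
        graph=graph,
        gene_table=gene_table,
        ranking=ranking,
        promoter_ranking=promoter_ranking,
    )


def run_pipeline_on_dataset(dataset, params: PipelineParams | None = None) -> PipelineResult:
    """Run the pipeline on a :class:`~epirank.simulate.SimulatedDataset`."""
    return run_pipeline(
        dataset.promoters,
        dataset.pirs,
        dataset.tracks,
        interactions=dataset.interactions,
        peaks=dataset.peaks,
        params=params,
    )


@dataclass
class RunInputs:
    promoters: list
    pirs: list
    interactions: list
    tracks: list
    peaks: dict


def load_inputs(
    promoters_path,
    pirs_path,
    sample_sheet_path,
    interactions_path=None,
    peaks_sheet_path=None,
    base_dir=None,
) -> RunInputs:
    """Load all pipeline inputs from their on-disk formats.

    Track and peak paths in the sheets are resolved relative to
    ``base_dir`` (default: the sample sheet's directory).
    """
    base = Path(base_dir) if base_dir else Path(sample_sheet_path).parent
    promoters = regions.read_bed(promoters_path, "promoter")
    pirs = regions.read_bed(pirs_path, "pir")
    interactions = (
        regions.read_interactions(interactions_path) if interactions_path else []
    )
    sheet = regions.read_sample_sheet(sample_sheet_path)
    tracks = [
        signal.read_bedgraph(
            base / row.track_path, row.mark, row.sample_id, row.condition
        )
        for row in sheet.itertuples()
    ]
    peaks: dict = {}
    if peaks_sheet_path:
        peak_sheet = pd.read_csv(peaks_sheet_path, sep="\t", dtype=str)
        for row in peak_sheet.itertuples():
            peaks[(row.sample_id, row.mark)] = regions.read_bed(base / row.path, "peak")
    return RunInputs(
        promoters=promoters,
        pirs=pirs,
        interactions=interactions,
        tracks=tracks,
        peaks=peaks,
    )


def write_result(result: PipelineResult, outdir, params: PipelineParams | None = None) -> None:
    """Persist scores, reports, graph, and rankings as tab-separated files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.dpca.B.iloc[:, : result.dpca.k].copy()
    table.insert(0, "score", result.element_scores)
    table.rename_axis("element_id").to_csv(outdir / "element_scores.tsv", sep="\t")
    loadings_report(result.dpca).to_csv(
        outdir / "loadings.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "component": result.dpca.V.index,
            "variance_explained": result.dpca.variance_explained,
        }
    ).to_csv(outdir / "variance_explained.tsv", sep="\t", index=False)
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("source_id\ttarget_id\n")
        for pir_id, prom_id in result.edges:
            fh.write(f"{pir_id}\t{prom_id}\n")
    with open(outdir / "vertices.tsv", "w") as fh:
        fh.write("id\ttype\tgene\tweight\n")
        for node, data in result.graph.nodes(data=True):
            fh.write(
                f"{node}\t{data['kind']}\t{data.get('gene', '')}\t{data['weight']:.10g}\n"
            )
    result.ranking.to_csv(outdir / "ranks_network.tsv", sep="\t")
    result.promoter_ranking.to_csv(outdir / "ranks_promoter.tsv", sep="\t")
    if params is not None:
        with open(outdir / "params.tsv", "w") as fh:
            for key, value in asdict(params).items():
                fh.write(f"{key}\t{value}\n")


def read_ranking(path) -> pd.DataFrame:
    """Read a ranked list written by :func:`write_result`."""
    frame = pd.read_csv(path, sep="\t", index_col="rank")
    if "gene" not in frame.columns:
        raise ValueError(f"{path}: not a ranked gene list (no 'gene' column)")
    return frame
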