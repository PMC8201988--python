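"""Self-contained toy epigenome generator with planted differential signal.

Emulates the inputs of a two-condition differential epigenome study:
promoters on a toy genome, candidate enhancers (PIRs) within 1 Mb of
their gene's TSS, an interaction table linking them, per-sample peak
calls for the enhancer-support filter, and per-sample per-mark signal
tracks in the bedGraph block model.

A designated fraction of genes are "markers": at their promoters and/or
linked enhancers, activating marks are multiplied by the effect size in
condition A and repressive marks divided by it (condition B is left at
baseline).  Baseline intensity is lognormal: each element and mark draws
a latent mean shared by all samples, and every sample observation
multiplies it by lognormal noise with configurable sigma.  Peaks are
emitted wherever a sample's H3K4me1/H3K27ac value exceeds that track's
median over elements, so retained PIRs pass the support filter by
construction.

All outputs are either in-memory objects the pipeline consumes directly
or, via :meth:`SimulatedDataset.write`, the plain-text formats the
readers ingest (BED, bedGraph, tab-separated tables).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import EnrichmentResult, ecdf_curve
from .regions import PIR, GenomicRegion, InteractionRecord, Promoter
from .signal import SignalTrack

logger = logging.getLogger(__name__)

#: The six most commonly profiled histone marks with their regulatory polarity.
DEFAULT_MARKS = (
    ("H3K27ac", "activating"),
    ("H3K4me1", "activating"),
    ("H3K4me3", "activating"),
    ("H3K36me3", "activating"),
    ("H3K27me3", "repressive"),
    ("H3K9me3", "repressive"),
)


@dataclass
class SimulationConfig:
    """Study conditions for the toy epigenome.

    Defaults describe a desk-scale two-condition design: 200 genes on a
    50-Mb chromosome, on average 5 enhancers per gene, 10% marker genes
    with a 4-fold planted shift on both their promoters and enhancers,
    3 samples per condition, and lognormal sample noise with sigma 0.3.
    """

    n_genes: int = 200
    pirs_per_gene_mean: float = 5.0
    marker_fraction: float = 0.1
    marker_mode: str = "both"  # promoter | enhancer | both
    marks: tuple = DEFAULT_MARKS
    effect_size: float = 4.0
    samples_per_condition: int = 3
    noise_sigma: float = 0.3
    genome: Mapping[str, int] = field(default_factory=lambda: {"chr1": 50_000_000})
    pir_length_range: tuple = (500, 2000)
    min_pir_distance: int = 5_000
    max_pir_distance: int = 1_000_000
    promoter_halfwidth: int = 1000
    base_level: float = 10.0      # median per-base baseline intensity
    element_sigma: float = 0.5    # spread of latent element/mark means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.samples_per_condition < 1:
            raise ValueError("n_genes and samples_per_condition must be >= 1")
        if not 0 < self.marker_fraction < 1:
            raise ValueError("marker_fraction must be in (0, 1)")
        if self.marker_mode not in ("promoter", "enhancer", "both"):
            raise ValueError(f"unknown marker_mode {self.marker_mode!r}")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1 (1 plants no signal)")
        if self.noise_sigma <= 0 or self.pirs_per_gene_mean <= 0:
            raise ValueError("noise_sigma and pirs_per_gene_mean must be > 0")


@dataclass
class GroundTruth:
    """Which genes are markers and what was planted where."""

    marker_genes: list
    effects: pd.DataFrame  # element_id, gene, mark, condition_a_multiplier


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    promoters: list          # 1-bp TSS records, pre-extension
    pirs: list
    interactions: list
    peaks: dict              # (sample_id, mark) -> list of GenomicRegion
    tracks: list             # SignalTrack per (sample, mark)
    sample_sheet: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> dict:
        """Write every artifact as the plain-text formats the readers ingest."""
        outdir = Path(outdir)
        (outdir / "tracks").mkdir(parents=True, exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
        paths = {
            "promoters": outdir / "promoters.bed",
            "pirs": outdir / "pirs.bed",
            "interactions": outdir / "interactions.tsv",
            "sample_sheet": outdir / "samples.tsv",
            "peaks_sheet": outdir / "peaks.tsv",
            "markers": outdir / "truth_markers.txt",
            "effects": outdir / "truth_effects.tsv",
        }
        with open(paths["promoters"], "w") as fh:
            for prom in self.promoters:
                r = prom.region
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{prom.gene}\n")
        with open(paths["pirs"], "w") as fh:
            for pir in self.pirs:
                r = pir.region
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
        with open(paths["interactions"], "w") as fh:
            for rec in self.interactions:
                a, b = rec.anchor_a, rec.anchor_b
                fh.write(
                    f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{rec.source}\n"
                )
        peak_rows = []
        for (sample_id, mark), regions in sorted(self.peaks.items()):
            peak_path = outdir / "peaks" / f"{sample_id}_{mark}.bed"
            with open(peak_path, "w") as fh:
                for r in regions:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
            peak_rows.append(
                {"sample_id": sample_id, "mark": mark, "path": f"peaks/{sample_id}_{mark}.bed"}
            )
        pd.DataFrame(peak_rows).to_csv(paths["peaks_sheet"], sep="\t", index=False)
        for track in self.tracks:
            track_path = outdir / "tracks" / f"{track.sample_id}_{track.mark}.bedGraph"
            with open(track_path, "w") as fh:
                for chrom in sorted(track.blocks):
                    starts, ends, values = track.blocks[chrom]
                    for s, e, v in zip(starts, ends, values):
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
        self.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        with open(paths["markers"], "w") as fh:
            fh.write("\n".join(self.truth.marker_genes) + "\n")
        self.truth.effects.to_csv(paths["effects"], sep="\t", index=False)
        return paths


def _place_genes(config: SimulationConfig, rng) -> list:
    """Non-overlapping TSS placement, proportional to chromosome length."""
    chroms = list(config.genome.items())
    total = sum(length for _, length in chroms)
    counts = [int(round(config.n_genes * length / total)) for _, length in chroms]
    while sum(counts) < config.n_genes:
        counts[int(np.argmin(counts))] += 1
    while sum(counts) > config.n_genes:
        counts[int(np.argmax(counts))] -= 1
    placements = []
    gene_index = 0
    for (chrom, length), count in zip(chroms, counts):
        if count == 0:
            continue
        slot = length / (count + 1)
        if slot < 4 * config.promoter_halfwidth:
            raise ValueError(
                f"genome too small: {chrom} ({length} bp) cannot hold {count} genes"
            )
        for i in range(count):
            gene_index += 1
            jitter = rng.uniform(-slot / 4, slot / 4)
            tss = int((i + 1) * slot + jitter)
            tss = min(max(tss, config.promoter_halfwidth), length - config.promoter_halfwidth - 1)
            placements.append((f"G{gene_index:04d}", chrom, tss))
    return placements


class _Occupancy:
    """Sorted non-overlapping interval set per chromosome, for placement."""

    def __init__(self):
        self._by_chrom: dict = {}

    def is_free(self, chrom, start, end) -> bool:
        intervals = self._by_chrom.get(chrom, [])
        idx = bisect_left(intervals, (start, start))
        for neighbor in intervals[max(0, idx - 1): idx + 1]:
            if neighbor[0] < end and start < neighbor[1]:
                return False
        return True

    def add(self, chrom, start, end) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full toy dataset for one seed."""
    rng = np.random.default_rng(config.seed)
    hw = config.promoter_halfwidth
    placements = _place_genes(config, rng)

    occupancy = _Occupancy()
    promoters, element_footprints = [], []
    for gene, chrom, tss in placements:
        region = GenomicRegion(chrom, tss, tss + 1, f"prom_{gene}")
        promoters.append(Promoter(region=region, gene=gene, tss=tss))
        occupancy.add(chrom, tss - hw, tss + hw)
        element_footprints.append((region.id, chrom, tss - hw, tss + hw, gene))

    marker_count = int(round(config.marker_fraction * config.n_genes))
    marker_genes = sorted(
        rng.choice([p[0] for p in placements], size=marker_count, replace=False)
    )
    marker_set = set(marker_genes)

    pirs, interactions = [], []
    pir_gene: dict = {}
    lengths = config.pir_length_range
    skipped = 0
    for gene, chrom, tss in placements:
        chrom_len = config.genome[chrom]
        n_pirs = rng.poisson(config.pirs_per_gene_mean)
        for i in range(n_pirs):
            placed = False
            for _ in range(100):
                length = int(rng.integers(lengths[0], lengths[1] + 1))
                distance = int(rng.integers(config.min_pir_distance, config.max_pir_distance + 1))
                sign = 1 if rng.random() < 0.5 else -1
                start = tss + sign * distance
                start = min(max(start, 0), chrom_len - length - 1)
                if occupancy.is_free(chrom, start, start + length):
                    occupancy.add(chrom, start, start + length)
                    placed = True
                    break
            if not placed:
                skipped += 1
                continue
            pir_id = f"pir_{gene}_{i + 1}"
            region = GenomicRegion(chrom, start, start + length, pir_id)
            pirs.append(PIR(region=region))
            pir_gene[pir_id] = gene
            element_footprints.append((pir_id, chrom, start, start + length, gene))
            anchors = (
                GenomicRegion(chrom, start, start + length, f"{pir_id}_anchor"),
                GenomicRegion(chrom, tss - hw // 2, tss + hw // 2, f"{gene}_anchor"),
            )
            if rng.random() < 0.5:
                anchors = anchors[::-1]
            interactions.append(
                InteractionRecord(anchor_a=anchors[0], anchor_b=anchors[1], source="sim")
            )
    if skipped:
        logger.warning("could not place %d PIRs without overlap; skipped", skipped)

    element_ids = [f[0] for f in element_footprints]
    n_elements = len(element_ids)
    mark_names = [m for m, _ in config.marks]
    polarity = dict(config.marks)

    # latent per-element per-mark baseline intensity, shared across samples
    latent = config.base_level * np.exp(
        rng.normal(0.0, config.element_sigma, size=(n_elements, len(mark_names)))
    )

    # planted condition-A multipliers
    multiplier = np.ones((n_elements, len(mark_names)))
    effect_rows = []
    for row, (element_id, _, _, _, gene) in enumerate(element_footprints):
        if gene not in marker_set:
            continue
        is_promoter = element_id.startswith("prom_")
        planted = (
            (is_promoter and config.marker_mode in ("promoter", "both"))
            or (not is_promoter and config.marker_mode in ("enhancer", "both"))
        )
        if not planted:
            continue
        for col, mark in enumerate(mark_names):
            factor = (
                config.effect_size
                if polarity[mark] == "activating"
                else 1.0 / config.effect_size
            )
            multiplier[row, col] = factor
            effect_rows.append(
                {
                    "element_id": element_id,
                    "gene": gene,
                    "mark": mark,
                    "condition_a_multiplier": factor,
                }
            )
    effects = pd.DataFrame(
        effect_rows,
        columns=["element_id", "gene", "mark", "condition_a_multiplier"],
    )

    footprint_blocks = sorted(
        (chrom, start, end, eid)
        for eid, chrom, start, end, _ in element_footprints
    )
    id_to_row = {eid: row for row, (eid, *_rest) in enumerate(element_footprints)}

    tracks, sheet_rows = [], []
    peaks: dict = {}
    support_marks = {"H3K4me1", "H3K27ac"} & set(mark_names)
    for condition in ("A", "B"):
        for s in range(1, config.samples_per_condition + 1):
            sample_id = f"{condition}{s}"
            noise = np.exp(
                rng.normal(0.0, config.noise_sigma, size=(n_elements, len(mark_names)))
            )
            values = latent * noise
            if condition == "A":
                values = values * multiplier
            for col, mark in enumerate(mark_names):
                blocks = [
                    (chrom, start, end, values[id_to_row[eid], col])
                    for chrom, start, end, eid in footprint_blocks
                ]
                tracks.append(
                    SignalTrack.from_blocks(mark, sample_id, condition, blocks)
                )
                sheet_rows.append(
                    {
                        "track_path": f"tracks/{sample_id}_{mark}.bedGraph",
                        "condition": condition,
                        "mark": mark,
                        "sample_id": sample_id,
                    }
                )
                if mark in support_marks:
                    threshold = np.median(values[:, col])
                    peaks[(sample_id, mark)] = [
                        GenomicRegion(chrom, start, end, f"peak_{sample_id}_{mark}_{eid}")
                        for chrom, start, end, eid in footprint_blocks
                        if values[id_to_row[eid], col] > threshold
                    ]

    return SimulatedDataset(
        config=config,
        promoters=promoters,
        pirs=pirs,
        interactions=interactions,
        peaks=peaks,
        tracks=tracks,
        sample_sheet=pd.DataFrame(sheet_rows),
        truth=GroundTruth(marker_genes=list(marker_genes), effects=effects),
    )


def truth_eval(ranked: pd.DataFrame, truth: GroundTruth) -> EnrichmentResult:
    """AUC of the planted marker genes within a ranking."""
    return ecdf_curve(ranked, truth.marker_genes, name="planted_markers")
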