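"""Genomic region ingestion, preprocessing, and enhancer-promoter linkage.

Promoters and promoter-interacting regions (PIRs) are plain half-open
intervals (BED convention, 0-based).  Promoters carry a gene identifier and
a TSS coordinate; PIRs carry the number of samples in which a peak of an
enhancer-associated mark supports them.  Chromatin-interaction records link
the two: an interaction whose anchors overlap a promoter on one side and a
PIR on the other creates a directed enhancer-to-promoter edge.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Marks whose peaks count as enhancer support for the PIR filter.
DEFAULT_SUPPORT_MARKS = frozenset({"H3K4me1", "H3K27ac"})

_HEADER_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval with a unique identifier."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for region {self.id!r}: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start for region {self.id!r}: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Promoter:
    region: GenomicRegion
    gene: str
    tss: int

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"promoter {self.region.id!r} has an empty gene identifier")

    @property
    def id(self) -> str:
        return self.region.id


@dataclass(frozen=True)
class PIR:
    """Promoter-interacting region, i.e. a candidate enhancer."""

    region: GenomicRegion
    support_count: int = 0

    @property
    def id(self) -> str:
        return self.region.id


@dataclass(frozen=True)
class InteractionRecord:
    anchor_a: GenomicRegion
    anchor_b: GenomicRegion
    source: str = ""


def as_region(element) -> GenomicRegion:
    """Return the GenomicRegion of a region-like object."""
    if isinstance(element, GenomicRegion):
        return element
    return element.region


def _data_lines(path):
    with open(path) as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            yield number, line


def _unique_id(candidate: str, seen: set) -> str:
    out = candidate
    suffix = 2
    while out in seen:
        out = f"{candidate}_{suffix}"
        suffix += 1
    seen.add(out)
    return out


def read_bed(path, kind: str):
    """Read a BED file as promoters, PIRs, or peak regions.

    Parameters
    ----------
    path : path-like
        Tab-separated BED file with at least three columns. Lines starting
        with ``#``, ``track`` or ``browser`` are skipped.
    kind : {"promoter", "pir", "peak"}
        Promoter records require a gene identifier in column 4; the TSS is
        taken as the record midpoint.  For PIRs and peaks, column 4 (when
        present) is used as the element identifier; otherwise identifiers
        are generated as ``chrom:start-end``.
    """
    if kind not in ("promoter", "pir", "peak"):
        raise ValueError(f"unknown BED kind {kind!r}")
    records = []
    seen_ids: set = set()
    for number, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: expected >=3 tab-separated columns at line {number}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer coordinates at line {number}") from exc
        if end <= start:
            raise ValueError(f"{path}: end <= start at line {number}")
        if start < 0:
            raise ValueError(f"{path}: negative start at line {number}")
        name = fields[3].strip() if len(fields) > 3 else ""
        if kind == "promoter":
            if not name:
                raise ValueError(f"{path}: promoter record missing gene id at line {number}")
            region = GenomicRegion(
                chrom, start, end, _unique_id(f"{chrom}:{start}-{end}", seen_ids)
            )
            records.append(Promoter(region=region, gene=name, tss=region.midpoint))
        else:
            region_id = _unique_id(name or f"{chrom}:{start}-{end}", seen_ids)
            region = GenomicRegion(chrom, start, end, region_id)
            records.append(PIR(region=region) if kind == "pir" else region)
    if not records:
        logger.warning("%s: no records found (empty %s file)", path, kind)
    return records


def read_interactions(path) -> list:
    """Read anchor-pair interaction records.

    Expects tab-separated ``chromA startA endA chromB startB endB [source]``
    (BEDPE-compatible).
    """
    records = []
    for number, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}: expected >=6 columns at line {number}")
        try:
            coords = [int(fields[i]) for i in (1, 2, 4, 5)]
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer coordinates at line {number}") from exc
        if coords[1] <= coords[0] or coords[3] <= coords[2]:
            raise ValueError(f"{path}: end <= start at line {number}")
        source = fields[6].strip() if len(fields) > 6 else ""
        records.append(
            InteractionRecord(
                anchor_a=GenomicRegion(
                    fields[0], coords[0], coords[1], f"ixn{number}_a"
                ),
                anchor_b=GenomicRegion(
                    fields[3], coords[2], coords[3], f"ixn{number}_b"
                ),
                source=source,
            )
        )
    if not records:
        logger.warning("%s: no interaction records found", path)
    return records


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the track sample sheet.

    Tab-separated with header columns ``track_path``, ``condition``,
    ``mark``, ``sample_id``.  Conditions must be labelled ``A`` and ``B``
    (A is the condition of interest, e.g. tumor; B the reference).
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"track_path", "condition", "mark", "sample_id"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad = set(sheet["condition"]) - {"A", "B"}
    if bad:
        raise ValueError(
            f"{path}: conditions must be 'A' or 'B', found {sorted(bad)}"
        )
    dupes = sheet.duplicated(subset=["mark", "sample_id", "condition"])
    if dupes.any():
        raise ValueError(f"{path}: duplicate (mark, sample_id, condition) rows")
    counts = sheet.groupby(["mark", "condition"]).size().unstack(fill_value=0)
    if (counts < 1).any().any() or counts.shape[1] < 2:
        raise ValueError(f"{path}: every mark needs >=1 sample in each condition")
    return sheet


def extend_promoters(
    promoters: Sequence[Promoter], extension: int = 1000
) -> list:
    """Extend each promoter to +/- `extension` bases around its TSS.

    The TSS (record midpoint) is the anchor; extended regions are clamped
    at zero.  ``extension=0`` leaves records unchanged.  Identifiers are
    preserved.
    """
    if extension < 0:
        raise ValueError(f"extension must be >= 0, got {extension}")
    if extension == 0:
        return list(promoters)
    out = []
    for prom in promoters:
        anchor = prom.tss
        region = replace(
            prom.region,
            start=max(0, anchor - extension),
            end=anchor + extension,
        )
        out.append(replace(prom, region=region))
    return out


def _build_trees(elements) -> dict:
    trees: dict = {}
    for element in elements:
        region = as_region(element)
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region.id
        )
    return trees


def filter_pirs_by_peaks(
    pirs: Sequence[PIR],
    peaks_by_sample: Mapping,
    marks: Iterable[str] = DEFAULT_SUPPORT_MARKS,
    min_samples: int = 2,
) -> list:
    """Keep PIRs supported by enhancer-mark peaks in enough samples.

    Parameters
    ----------
    peaks_by_sample : mapping of (sample_id, mark) -> sequence of regions
        Peak calls per sample and mark, pooled over both conditions.
    marks : iterable of str
        Marks whose peaks count as support (default H3K4me1/H3K27ac).
    min_samples : int
        A PIR is retained when peaks from at least this many distinct
        samples overlap it by >=1 bp (samples are counted, not peaks).
    """
    if not peaks_by_sample:
        raise ValueError(
            "no peak calls supplied; provide peaks_by_sample or disable "
            "the PIR support filter explicitly"
        )
    marks = set(marks)
    sample_trees: dict = {}
    for (sample_id, mark), peak_list in peaks_by_sample.items():
        if mark not in marks:
            continue
        trees = sample_trees.setdefault(sample_id, {})
        for peak in peak_list:
            region = as_region(peak)
            trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.end
            )
    retained = []
    for pir in pirs:
        region = pir.region
        support = sum(
            1
            for trees in sample_trees.values()
            if region.chrom in trees
            and trees[region.chrom].overlap(region.start, region.end)
        )
        if support >= min_samples:
            retained.append(replace(pir, support_count=support))
    logger.info(
        "PIR support filter: retained %d / %d (min %d supporting samples)",
        len(retained), len(pirs), min_samples,
    )
    return retained


def link_by_interactions(
    promoters: Sequence[Promoter],
    pirs: Sequence[PIR],
    interactions: Sequence[InteractionRecord],
) -> list:
    """Derive (pir_id, promoter_id) edges from interaction anchor overlap.

    An edge is emitted when one anchor overlaps an (extended) promoter and
    the other overlaps a retained PIR, in either anchor orientation.
    Duplicate pairs collapse to a single edge; input order is preserved.
    """
    prom_trees = _build_trees(promoters)
    pir_trees = _build_trees(pirs)

    def hits(trees, anchor):
        tree = trees.get(anchor.chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(anchor.start, anchor.end))

    edges: list = []
    seen: set = set()
    unmatched = 0
    for record in interactions:
        matched = False
        for pir_anchor, prom_anchor in (
            (record.anchor_a, record.anchor_b),
            (record.anchor_b, record.anchor_a),
        ):
            for pir_id in hits(pir_trees, pir_anchor):
                for prom_id in hits(prom_trees, prom_anchor):
                    matched = True
                    if (pir_id, prom_id) not in seen:
                        seen.add((pir_id, prom_id))
                        edges.append((pir_id, prom_id))
        if not matched:
            unmatched += 1
    if unmatched:
        logger.info("dropped %d interaction records matching no promoter/PIR pair", unmatched)
    return edges


def link_by_nearest(
    promoters: Sequence[Promoter], pirs: Sequence[PIR]
) -> list:
    """Assign each PIR to the promoter with the nearest TSS.

    Distance is measured from the PIR midpoint; ties are broken toward the
    lower TSS coordinate (then lexicographically by promoter id).  PIRs on
    chromosomes without a promoter are dropped with a warning.
    """
    by_chrom: dict = {}
    for prom in promoters:
        by_chrom.setdefault(prom.region.chrom, []).append((prom.tss, prom.id))
    for entries in by_chrom.values():
        entries.sort()
    edges = []
    dropped = 0
    for pir in pirs:
        entries = by_chrom.get(pir.region.chrom)
        if not entries:
            dropped += 1
            continue
        mid = pir.region.midpoint
        positions = [tss for tss, _ in entries]
        idx = bisect_left(positions, mid)
        candidates = entries[max(0, idx - 1): idx + 1]
        best = min(candidates, key=lambda entry: (abs(entry[0] - mid), entry[0], entry[1]))
        edges.append((pir.id, best[1]))
    if dropped:
        logger.warning("%d PIRs on chromosomes without promoters were dropped", dropped)
    return edges
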