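"""Signal summarization over regulatory elements and matrix normalization.

Per-sample, per-mark genome-wide signal enters as non-overlapping value
blocks (the bedGraph model).  Each element's signal is the coverage-weighted
sum over overlapping blocks, length-normalized to a 1-kb scale, then
power-transformed and quantile-normalized within each mark across all
samples of both conditions.  The condition mean-difference matrix D
(elements x marks) feeds the differential PCA step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import as_region

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """One sample's genome-wide signal for one mark, as value blocks.

    ``blocks`` maps chromosome -> (starts, ends, values) arrays, sorted by
    start, non-overlapping, with finite non-negative values.
    """

    mark: str
    sample_id: str
    condition: str
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_blocks(cls, mark, sample_id, condition, blocks: Iterable):
        """Build a track from an iterable of (chrom, start, end, value)."""
        per_chrom: dict = {}
        for chrom, start, end, value in blocks:
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        out: dict = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"track {sample_id}/{mark}: block with end <= start on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"track {sample_id}/{mark}: overlapping blocks on {chrom}")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"track {sample_id}/{mark}: non-finite or negative values on {chrom}")
            out[chrom] = (starts, ends, values)
        return cls(mark=mark, sample_id=sample_id, condition=condition, blocks=out)


def read_bedgraph(path, mark: str, sample_id: str, condition: str) -> SignalTrack:
    """Read a 4-column bedGraph file into a SignalTrack."""
    rows = []
    with open(path) as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: expected 4 columns at line {number}")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph line {number}") from exc
    return SignalTrack.from_blocks(mark, sample_id, condition, rows)


def summarize_signal(track: SignalTrack, elements: Sequence) -> np.ndarray:
    """Coverage-weighted signal sum of a track over each element.

    value(e) = sum over blocks b overlapping e of value(b) * overlap_bases,
    which is independent of how a track splits constant coverage into
    blocks.  Elements with no overlapping block (or on chromosomes absent
    from the track) get 0.
    """
    out = np.zeros(len(elements), dtype=float)
    missing_chroms = set()
    for i, element in enumerate(elements):
        region = as_region(element)
        chrom_blocks = track.blocks.get(region.chrom)
        if chrom_blocks is None:
            missing_chroms.add(region.chrom)
            continue
        starts, ends, values = chrom_blocks
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if lo >= hi:
            continue
        overlap = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        out[i] = float(np.dot(values[lo:hi], overlap))
    if missing_chroms:
        logger.warning(
            "track %s/%s: chromosomes %s absent, elements there scored 0",
            track.sample_id, track.mark, sorted(missing_chroms),
        )
    return out


def bin_to_scale(value, element_length, scale: int = 1000):
    """Length-normalize summarized signal to intensity per `scale` bases."""
    element_length = np.asarray(element_length, dtype=float)
    if np.any(element_length <= 0):
        raise ValueError("element_length must be > 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return np.asarray(value, dtype=float) * scale / element_length


def power_transform(matrix, exponent: float = 0.5):
    """Elementwise x**exponent for exponent in (0, 1]; order-preserving."""
    if not 0 < exponent <= 1:
        raise ValueError(f"exponent must be in (0, 1], got {exponent}")
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if np.any(values < 0):
        raise ValueError("power transform requires non-negative input")
    transformed = values ** exponent
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(transformed, index=matrix.index, columns=matrix.columns)
    return transformed


def quantile_normalize_columns(arr) -> np.ndarray:
    """Quantile-normalize columns of a 2-D array to their common reference.

    The reference is the across-column mean of sorted values; tied input
    values receive the mean of the reference values at their tied ranks.
    A single column is returned unchanged with a warning.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    n_rows, n_cols = arr.shape
    if n_cols < 2:
        logger.warning("quantile normalization skipped: only %d column(s)", n_cols)
        return arr.copy()
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_cols):
        column = arr[:, j]
        order = np.argsort(column, kind="stable")
        assigned = np.empty(n_rows)
        assigned[order] = reference
        out[:, j] = pd.Series(assigned).groupby(column).transform("mean").to_numpy()
    return out


@dataclass
class ElementSignalMatrix:
    """Elements x (mark, sample, condition) signal matrix.

    ``data`` has element ids as index and a (mark, sample_id, condition)
    MultiIndex on columns.
    """

    data: pd.DataFrame
    normalized: bool = False

    @property
    def element_ids(self) -> list:
        return list(self.data.index)

    @property
    def marks(self) -> list:
        seen = []
        for mark in self.data.columns.get_level_values("mark"):
            if mark not in seen:
                seen.append(mark)
        return seen


def build_signal_matrix(
    tracks: Sequence[SignalTrack],
    elements: Sequence,
    scale: int | None = 1000,
) -> ElementSignalMatrix:
    """Summarize all tracks over the elements into one raw signal matrix.

    ``scale`` length-normalizes each element to per-`scale`-base intensity;
    pass None to keep raw coverage-weighted sums.
    """
    if not tracks:
        raise ValueError("no signal tracks supplied")
    lengths = np.array([as_region(e).length for e in elements], dtype=float)
    ids = [as_region(e).id for e in elements]
    columns, data = [], []
    for track in tracks:
        values = summarize_signal(track, elements)
        if scale is not None:
            values = bin_to_scale(values, lengths, scale)
        columns.append((track.mark, track.sample_id, track.condition))
        data.append(values)
    frame = pd.DataFrame(
        np.column_stack(data),
        index=ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["mark", "sample_id", "condition"]),
    )
    return ElementSignalMatrix(data=frame, normalized=False)


def quantile_normalize(matrix: ElementSignalMatrix) -> ElementSignalMatrix:
    """Quantile-normalize sample columns within each mark.

    Samples of both conditions are normalized jointly per mark so that
    between-condition differences survive while cross-sample depth and
    dynamic-range differences are removed.
    """
    frame = matrix.data.copy()
    for mark in matrix.marks:
        block = frame.loc[:, frame.columns.get_level_values("mark") == mark]
        frame.loc[:, block.columns] = quantile_normalize_columns(block.to_numpy())
    return ElementSignalMatrix(data=frame, normalized=True)


def normalize_matrix(
    matrix: ElementSignalMatrix, power: float = 0.5
) -> ElementSignalMatrix:
    """Apply the power transform then per-mark quantile normalization."""
    powered = ElementSignalMatrix(
        data=power_transform(matrix.data, power), normalized=False
    )
    return quantile_normalize(powered)


def difference_matrix(matrix: ElementSignalMatrix) -> pd.DataFrame:
    """Condition mean-difference matrix D (elements x marks, A minus B)."""
    if not matrix.normalized:
        logger.warning("computing D from a non-normalized signal matrix")
    frame = matrix.data
    marks = matrix.marks
    out = {}
    for mark in marks:
        block = frame.loc[:, frame.columns.get_level_values("mark") == mark]
        conditions = block.columns.get_level_values("condition")
        a = block.loc[:, conditions == "A"]
        b = block.loc[:, conditions == "B"]
        if a.shape[1] == 0 or b.shape[1] == 0:
            raise ValueError(f"mark {mark!r} is missing samples for one condition")
        out[mark] = a.mean(axis=1) - b.mean(axis=1)
    diff = pd.DataFrame(out, index=frame.index)[marks]
    diff.columns.name = "mark"
    return diff
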