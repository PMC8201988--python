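"""Differential PCA: decompose the condition-difference matrix D.

D (elements x marks, the between-condition mean difference of normalized
signal) is factored as D = B V + E by singular value decomposition, where
the rows of V are loadings of each differential component (dPC) over the
marks and B holds each element's coordinates along the dPCs.  The
per-element score is the sum of absolute coordinates along the first k
components (k = 2 by default), which captures differential signal from
both activating and repressive marks regardless of direction.

No inferential layer (component significance, locus-level testing) is
attached: only the coordinates and loadings are used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DPCAResult:
    """Decomposition D = B V + E with sign-stabilized components.

    B : elements x R coordinates (columns dPC1..dPCR, R = min(G, M))
    V : R x M loadings over marks
    residual : E = D - B_k V_k for the retained k components
    """

    B: pd.DataFrame
    V: pd.DataFrame
    singular_values: np.ndarray
    variance_explained: np.ndarray
    residual: pd.DataFrame
    k: int

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


def dpca(D: pd.DataFrame, center: bool = False, k: int = 2) -> DPCAResult:
    """Singular value decomposition of the difference matrix.

    Parameters
    ----------
    D : DataFrame, elements x marks
        Between-condition mean differences.
    center : bool
        Subtract column means first.  Off by default: rows of D are
        already differences, and overall magnitude (not deviation from
        the mean difference) is the signal.
    k : int
        Number of components retained for the residual and the default
        element score.

    Component signs are stabilized so each loading row's largest-magnitude
    entry is positive; element scores use absolute values and are
    unaffected by this choice.
    """
    values = D.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("difference matrix contains non-finite entries")
    n_elements, n_marks = values.shape
    if n_elements < 2:
        raise ValueError("need at least 2 elements")
    if n_marks < 1:
        raise ValueError("need at least 1 mark")
    if center:
        values = values - values.mean(axis=0, keepdims=True)
    rank = min(n_elements, n_marks)
    if not 1 <= k <= rank:
        raise ValueError(f"k must be in [1, {rank}], got {k}")

    u, s, vt = np.linalg.svd(values, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for r in range(rank):
        pivot = np.argmax(np.abs(vt[r]))
        if vt[r, pivot] < 0:
            vt[r] *= -1.0
            u[:, r] *= -1.0
    b = u * s

    total = float(np.sum(s**2))
    if total > 0:
        variance_explained = s**2 / total
    else:
        logger.warning("all-zero difference matrix: variance explained undefined, reported as zeros")
        variance_explained = np.zeros_like(s)

    comp_index = [f"dPC{r + 1}" for r in range(rank)]
    B = pd.DataFrame(b, index=D.index, columns=comp_index)
    V = pd.DataFrame(vt, index=comp_index, columns=D.columns)
    residual = pd.DataFrame(
        values - b[:, :k] @ vt[:k], index=D.index, columns=D.columns
    )
    return DPCAResult(
        B=B,
        V=V,
        singular_values=s,
        variance_explained=variance_explained,
        residual=residual,
        k=k,
    )


def element_scores(result: DPCAResult, k: int | None = None) -> pd.Series:
    """Per-element score: sum of |coordinates| over the first k dPCs."""
    if k is None:
        k = result.k
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k must be in [1, {result.n_components}], got {k}")
    scores = result.B.iloc[:, :k].abs().sum(axis=1)
    scores.name = "score"
    return scores


def loadings_report(result: DPCAResult) -> pd.DataFrame:
    """Long-format table of per-component mark loadings.

    Useful for inspecting whether activating and repressive marks separate
    onto the first two components.
    """
    rows = []
    for r, component in enumerate(result.V.index):
        for mark in result.V.columns:
            rows.append(
                {
                    "component": component,
                    "mark": mark,
                    "loading": result.V.loc[component, mark],
                    "variance_explained": result.variance_explained[r],
                }
            )
    return pd.DataFrame(rows)
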