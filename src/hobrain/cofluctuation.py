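"""Signed k-order co-fluctuation time series.

For a z-scored panel ``z_0 ... z_{N-1}`` and a strictly increasing tuple of
``k + 1`` regions, the raw product series is ``p(t) = prod_m z_m(t)``; the
standardized magnitude is ``xi(t) = (p(t) - mu[p]) / sigma[p]`` and the signed
weight is

    w(t) = parity_sign(z values at t) * |xi(t)|

where the parity sign is +1 when the tuple's instantaneous values are
sign-concordant (all positive or all negative) and -1 when signs are mixed.
The remapping marks perfectly coherent group co-fluctuations as positive
irrespective of the shared sign.

For k = 1 the raw product series is the classic edge time series, whose time
mean equals the Pearson correlation of the two rows; edge functional
connectivity (eFC) is the correlation matrix among those edge series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import DegenerateSignalError, DimensionError
from .panel import TimeSeriesPanel

__all__ = [
    "CofluctuationSet",
    "parity_sign",
    "parity_signs",
    "cofluctuation_series",
    "efc_matrix",
    "tuple_indices",
]


def tuple_indices(n_regions: int, k: int) -> np.ndarray:
    """All strictly increasing (k+1)-tuples of region indices, lexicographic.

    Returns an int array of shape ``(C(N, k+1), k+1)``.
    """
    return np.array(list(combinations(range(n_regions), k + 1)), dtype=np.int64)


@dataclass
class CofluctuationSet:
    """Dense order-``k`` co-fluctuation series for every (k+1)-tuple of regions.

    Attributes
    ----------
    k : int
        Interaction order (1 = edges, 2 = triangles).
    tuples : ndarray, shape (M, k+1)
        Strictly increasing region tuples in lexicographic order.
    weights : ndarray, shape (M, T)
        Parity-signed standardized weights ``w(t)``.
    raw : ndarray, shape (M, T)
        Raw (pre-standardization, unsigned-remap) product series ``p(t)``.
    """

    k: int
    n_regions: int
    tuples: np.ndarray
    weights: np.ndarray
    raw: np.ndarray

    def __post_init__(self) -> None:
        m_expect = comb(self.n_regions, self.k + 1)
        if self.tuples.shape != (m_expect, self.k + 1):
            raise DimensionError(
                f"dense order-{self.k} set over N={self.n_regions} requires "
                f"{m_expect} tuples, got {self.tuples.shape[0]}"
            )
        if self.weights.shape != self.raw.shape or self.weights.shape[0] != m_expect:
            raise DimensionError("weights/raw arrays inconsistent with tuple count")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.raw))):
            raise DimensionError("non-finite co-fluctuation values")

    @property
    def n_frames(self) -> int:
        return self.weights.shape[1]

    def index_of(self, tup: tuple[int, ...]) -> int:
        """Position of a region tuple in the dense lexicographic ordering."""
        hit = np.flatnonzero((self.tuples == np.asarray(tup)).all(axis=1))
        if hit.size != 1:
            raise KeyError(f"tuple {tup} not in dense order-{self.k} set")
        return int(hit[0])

    def series(self, tup: tuple[int, ...]) -> np.ndarray:
        return self.weights[self.index_of(tup)]


def parity_sign(z_values) -> int:
    """Concordance parity of one frame's tuple of z-values: +1 unless signs are mixed.

    Zeros break concordance only in the presence of both a positive and a
    negative entry; an all-zero or zero-padded same-sign frame counts as
    concordant.
    """
    v = np.asarray(z_values, dtype=np.float64)
    if v.size < 2:
        raise DimensionError("parity needs at least 2 values")
    return -1 if (np.any(v > 0) and np.any(v < 0)) else 1


def parity_signs(z_block: np.ndarray) -> np.ndarray:
    """Vectorized parity over frames for a ``(k+1) x T`` block (or stacked blocks).

    For input of shape ``(..., k+1, T)`` returns ``(..., T)`` of +-1.
    """
    pos = (z_block > 0).any(axis=-2)
    neg = (z_block < 0).any(axis=-2)
    return np.where(pos & neg, -1.0, 1.0)


def cofluctuation_series(zpanel: TimeSeriesPanel, k: int) -> CofluctuationSet:
    """Dense signed k-order co-fluctuation weights for every (k+1)-tuple.

    Parameters
    ----------
    zpanel : TimeSeriesPanel
        Must already be z-scored (population ddof-0 moments).
    k : int
        1 for edges, 2 for triangles.  Higher orders are accepted but
        combinatorially expensive.

    Raises
    ------
    DegenerateSignalError
        If some tuple's raw product series is constant over time.
    """
    if k < 1:
        raise DimensionError("order k must be >= 1")
    if not zpanel.is_zscored(tol=1e-8):
        raise DimensionError("cofluctuation_series expects a z-scored panel")
    z = zpanel.values
    tups = tuple_indices(zpanel.n_regions, k)
    if tups.shape[0] == 0:
        raise DimensionError(f"N={zpanel.n_regions} has no order-{k} tuples")

    # raw products p(t), vectorized over tuples
    raw = z[tups[:, 0]].copy()
    for col in range(1, k + 1):
        raw *= z[tups[:, col]]

    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0.0)
    if degenerate.size:
        bad = tuple(int(i) for i in tups[degenerate[0]])
        raise DegenerateSignalError(
            f"constant raw product series for tuple {bad} "
            f"({degenerate.size} degenerate tuple(s) in total)"
        )
    xi = (raw - mu) / sd
    signs = parity_signs(z[tups])  # (M, T)
    weights = signs * np.abs(xi)
    return CofluctuationSet(k=k, n_regions=zpanel.n_regions, tuples=tups,
                            weights=weights, raw=raw)


def efc_matrix(edge_set: CofluctuationSet, use: str = "raw",
               max_regions: int = 60) -> np.ndarray:
    """Edge functional connectivity: Pearson correlations among all edge series.

    Parameters
    ----------
    edge_set : CofluctuationSet with ``k == 1``.
    use : {"raw", "signed"}
        ``"raw"`` (default) correlates the classic edge time series (raw
        products of z-scored node pairs); ``"signed"`` correlates the
        parity-signed standardized weights instead.
    max_regions : int
        Guard on N: the result is ``C(N,2) x C(N,2)`` and grows quartically.

    Returns
    -------
    ndarray, shape (C(N,2), C(N,2)), symmetric with unit diagonal.
    """
    if edge_set.k != 1:
        raise DimensionError("efc_matrix requires an order-1 (edge) set")
    if edge_set.n_regions > max_regions:
        raise DimensionError(
            f"N={edge_set.n_regions} exceeds the eFC cap ({max_regions}); "
            "raise max_regions explicitly if this is intended"
        )
    series = edge_set.raw if use == "raw" else edge_set.weights
    if use not in ("raw", "signed"):
        raise ValueError("use must be 'raw' or 'signed'")
    sd = series.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        bad = tuple(int(i) for i in edge_set.tuples[flat[0]])
        raise DegenerateSignalError(f"constant edge series for tuple {bad}")
    efc = np.corrcoef(series)
    efc = np.clip((efc + efc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(efc, 1.0)
    return efc
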