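"""Recurrence-plot task decoding.

Per-frame indicator vectors are compared across time with Pearson correlation
(time-time "recurrence plots"), binarized at a percentile of the off-diagonal
distribution, clustered with the Louvain algorithm, and scored against the
ground-truth task-block partition with the element-centric similarity (ECS).

ECS for hard partitions uses the personalized-PageRank affinity with damping
``alpha``: within cluster ``c`` the affinity of element ``i`` to ``j`` is
``(1 - alpha) * delta_ij + alpha / |c|`` and zero outside, and the similarity
of two partitions is the mean over elements of ``1 - L1/(2*alpha)`` between
their affinity rows.  ECS is 1 exactly when the partitions coincide up to a
relabeling, and 0 for maximally dissimilar partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import IndicatorMatrix
from .errors import DegenerateSignalError, DimensionError

__all__ = [
    "RecurrencePlot",
    "Partition",
    "recurrence_plot",
    "binarize_percentile",
    "louvain_partition",
    "element_centric_similarity",
    "task_decoding_score",
]


@dataclass
class RecurrencePlot:
    """Symmetric T x T time-time correlation matrix for one method."""

    values: np.ndarray
    method: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class Partition:
    """Per-frame integer community labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise DimensionError("partition labels must be one-dimensional")

    @property
    def n_elements(self) -> int:
        return int(self.labels.size)

    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)


def recurrence_plot(ind: IndicatorMatrix) -> RecurrencePlot:
    """Pearson correlation between the feature vectors of every pair of frames."""
    x = ind.values
    if x.shape[0] < 2:
        raise DimensionError("need at least 2 features per frame")
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise DegenerateSignalError(
            f"zero-variance frame(s) {flat[:5].tolist()} in {ind.method} indicator")
    rp = np.corrcoef(x.T)
    rp = np.clip((rp + rp.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rp, 1.0)
    return RecurrencePlot(rp, method=ind.method)


def binarize_percentile(rp: RecurrencePlot, q: float = 95.0) -> np.ndarray:
    """Binarize at the q-th percentile of the upper-triangular off-diagonal values.

    Entries greater than or equal to the threshold map to 1 (ties included);
    the diagonal is zeroed (self-similarity is uninformative).
    """
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    iu = np.triu_indices(rp.n_frames, k=1)
    thr = np.percentile(rp.values[iu], q)
    out = (rp.values >= thr).astype(np.int8)
    np.fill_diagonal(out, 0)
    return out


def louvain_partition(binary: np.ndarray, seed: int = 0,
                      n_restarts: int = 10, resolution: float = 1.0) -> Partition:
    """Louvain communities of the binarized recurrence graph, best of restarts.

    Runs the Louvain algorithm ``n_restarts`` times with seeds
    ``seed, seed+1, ...`` and returns the highest-modularity partition.  With
    no edges every frame is its own singleton community.
    """
    parts = _louvain_restarts(binary, seed, n_restarts, resolution)
    best = max(parts, key=lambda pm: pm[1])
    return best[0]


def _louvain_restarts(binary: np.ndarray, seed: int, n_restarts: int,
                      resolution: float) -> list[tuple[Partition, float]]:
    t = binary.shape[0]
    if binary.shape != (t, t) or not np.array_equal(binary, binary.T):
        raise DimensionError("binarized recurrence matrix must be square symmetric")
    g = nx.from_numpy_array(binary.astype(float))
    if g.number_of_edges() == 0:
        p = Partition(np.arange(t))
        return [(p, 0.0)] * max(n_restarts, 1)
    out = []
    for r in range(max(n_restarts, 1)):
        comms = nx.community.louvain_communities(
            g, resolution=resolution, seed=int(seed) + r)
        labels = np.empty(t, dtype=np.int64)
        for c, members in enumerate(comms):
            labels[list(members)] = c
        q = nx.community.modularity(g, comms, resolution=resolution)
        out.append((Partition(labels), float(q)))
    return out


def element_centric_similarity(p1: Partition, p2: Partition,
                               alpha: float = 0.9) -> float:
    """Element-centric similarity between two hard partitions, in [0, 1]."""
    if p1.n_elements != p2.n_elements:
        raise DimensionError("partitions cover different numbers of elements")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    l1, l2 = p1.labels, p2.labels
    n = p1.n_elements
    _, inv1 = np.unique(l1, return_inverse=True)
    _, inv2 = np.unique(l2, return_inverse=True)
    size1 = np.bincount(inv1)[inv1].astype(np.float64)   # |c1(i)| per element
    size2 = np.bincount(inv2)[inv2].astype(np.float64)
    # overlap |c1(i) & c2(i)| per element via joint cluster ids
    joint = inv1 * (inv2.max() + 1) + inv2
    _, jinv = np.unique(joint, return_inverse=True)
    overlap = np.bincount(jinv)[jinv].astype(np.float64)
    corrected_l1 = (overlap * np.abs(1.0 / size1 - 1.0 / size2)
                    + (size1 - overlap) / size1
                    + (size2 - overlap) / size2)
    return float(np.mean(1.0 - corrected_l1 / 2.0))


def task_decoding_score(ind: IndicatorMatrix, truth: Partition,
                        q: float = 95.0, seed: int = 0,
                        n_restarts: int = 10, alpha: float = 0.9) -> float:
    """End-to-end decoding score: recurrence plot -> binarize -> Louvain -> ECS.

    Returns the mean ECS against the ground-truth block partition over the
    Louvain restarts.
    """
    rp = recurrence_plot(ind)
    if rp.n_frames != truth.n_elements:
        raise DimensionError("indicator frames and truth labels disagree")
    binary = binarize_percentile(rp, q=q)
    parts = _louvain_restarts(binary, seed, n_restarts, resolution=1.0)
    scores = [element_centric_similarity(p, truth, alpha=alpha) for p, _ in parts]
    return float(np.mean(scores))
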