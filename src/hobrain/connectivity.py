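"""Indicator matrices, static connectivity features and functional-network masks.

Four "methods" are compared throughout the applications, ordered from
lower-order to higher-order:

* ``BOLD`` — the z-scored region signals themselves (N features per frame);
* ``edges`` — the order-1 signed co-fluctuation weights (C(N,2) features);
* ``triangles`` — the violating-triangle weights, embedded densely over all
  C(N,3) triples (zero where a triple is not violating at that frame);
* ``scaffold`` — the homological-scaffold edge frequencies (C(N,2) features).

Static per-subject features are the Pearson FC upper triangle, the eFC upper
triangle, and the time means of the triangle and scaffold indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .cofluctuation import CofluctuationSet, efc_matrix, tuple_indices
from .errors import DimensionError
from .panel import TimeSeriesPanel, pearson_fc
from .topology import ScanTopology

__all__ = [
    "METHODS",
    "NETWORKS",
    "IndicatorMatrix",
    "StaticConnectivity",
    "NetworkAssignment",
    "indicator_matrix",
    "static_features",
    "network_mask",
    "nodal_strength_cv",
]

METHODS = ("BOLD", "edges", "triangles", "scaffold")
NETWORKS = ("VIS", "SM", "DA", "VA", "L", "FP", "DMN", "SC")


@dataclass
class IndicatorMatrix:
    """Feature x frame activation matrix for one method."""

    method: str
    values: np.ndarray                     # (F, T)
    feature_index: list[tuple[int, ...]]   # node tuple per feature

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.feature_index) != self.values.shape[0]:
            raise DimensionError("feature index does not match matrix rows")


@dataclass
class StaticConnectivity:
    """Per-subject, per-session static feature vector for one method."""

    method: str
    values: np.ndarray
    feature_index: list[tuple[int, ...]]
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        if len(self.feature_index) != self.values.shape[0]:
            raise DimensionError("feature index does not match vector length")


@dataclass
class NetworkAssignment:
    """Region -> functional network labels over the canonical eight systems."""

    labels: list[str]

    def __post_init__(self) -> None:
        bad = sorted({l for l in self.labels if l not in NETWORKS})
        if bad:
            raise ValueError(f"unknown network label(s): {bad}; expected {NETWORKS}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def regions_of(self, network: str) -> np.ndarray:
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return np.flatnonzero(np.asarray(self.labels) == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": range(self.n_regions), "network": self.labels})


# ---------------------------------------------------------------------------


def _pair_index(n: int) -> list[tuple[int, ...]]:
    return [tuple(int(x) for x in p) for p in tuple_indices(n, 1)]


def _triple_index(n: int) -> list[tuple[int, ...]]:
    return [tuple(int(x) for x in p) for p in tuple_indices(n, 2)]


def indicator_matrix(method: str, *,
                     zpanel: TimeSeriesPanel | None = None,
                     edge_set: CofluctuationSet | None = None,
                     scan: ScanTopology | None = None) -> IndicatorMatrix:
    """Assemble the per-frame indicator matrix for one of the four methods.

    ``BOLD`` needs ``zpanel``; ``edges`` needs ``edge_set``; ``triangles`` and
    ``scaffold`` need ``scan`` (a :class:`~hobrain.topology.ScanTopology`).
    """
    if method == "BOLD":
        if zpanel is None:
            raise DimensionError("BOLD indicator requires the z-scored panel")
        n = zpanel.n_regions
        return IndicatorMatrix("BOLD", zpanel.values.copy(),
                               [(i,) for i in range(n)])
    if method == "edges":
        if edge_set is None or edge_set.k != 1:
            raise DimensionError("edges indicator requires the order-1 set")
        return IndicatorMatrix("edges", edge_set.weights.copy(),
                               _pair_index(edge_set.n_regions))
    if method == "triangles":
        if scan is None:
            raise DimensionError("triangles indicator requires scan topology")
        return IndicatorMatrix("triangles", scan.tri_indicator.copy(),
                               _triple_index(scan.n_regions))
    if method == "scaffold":
        if scan is None:
            raise DimensionError("scaffold indicator requires scan topology")
        return IndicatorMatrix("scaffold", scan.scaffold.copy(),
                               _pair_index(scan.n_regions))
    raise ValueError(f"unknown method {method!r}")


def static_features(method: str, *,
                    panel: TimeSeriesPanel | None = None,
                    edge_set: CofluctuationSet | None = None,
                    scan: ScanTopology | None = None,
                    subject: str = "", session: str = "",
                    efc_max_regions: int = 60) -> StaticConnectivity:
    """Per-subject static connectivity vector for one method.

    FC -> upper triangle of the Pearson FC matrix (C(N,2) features);
    eFC -> upper triangle of the edge-by-edge correlation matrix
    (C(C(N,2),2) features, feature index pools the two edges' nodes);
    triangles / scaffold -> time means of the respective indicators.

    The method tags follow the application naming: ``BOLD`` maps to FC and
    ``edges`` maps to eFC.
    """
    if method == "BOLD":
        if panel is None:
            raise DimensionError("FC features require the panel")
        fc = pearson_fc(panel)
        iu = np.triu_indices(panel.n_regions, k=1)
        return StaticConnectivity("BOLD", fc[iu], _pair_index(panel.n_regions),
                                  subject, session)
    if method == "edges":
        if edge_set is None:
            raise DimensionError("eFC features require the order-1 set")
        efc = efc_matrix(edge_set, max_regions=efc_max_regions)
        pairs = _pair_index(edge_set.n_regions)
        iu = np.triu_indices(len(pairs), k=1)
        index = [tuple(sorted(set(pairs[a]) | set(pairs[b])))
                 for a, b in zip(*iu)]
        return StaticConnectivity("edges", efc[iu], index, subject, session)
    if method in ("triangles", "scaffold"):
        if scan is None:
            raise DimensionError(f"{method} features require scan topology")
        if scan.tri_indicator.shape[1] == 0:
            raise DimensionError("zero-length scan")
        if method == "triangles":
            return StaticConnectivity("triangles", scan.tri_indicator.mean(axis=1),
                                      _triple_index(scan.n_regions), subject, session)
        return StaticConnectivity("scaffold", scan.scaffold.mean(axis=1),
                                  _pair_index(scan.n_regions), subject, session)
    raise ValueError(f"unknown method {method!r}")


def network_mask(feature_index: list[tuple[int, ...]],
                 assignment: NetworkAssignment,
                 network: str,
                 mode: str = "at_least_one") -> np.ndarray:
    """Boolean mask over features touching (or contained in) one network.

    ``at_least_one`` selects features whose node set intersects the network;
    ``within`` requires every node of the feature inside it.  eFC features
    carry the pooled node set of both edges, so both modes act on all four
    involved regions.
    """
    if mode not in ("at_least_one", "within"):
        raise ValueError(f"unknown mode {mode!r}")
    members = set(int(r) for r in assignment.regions_of(network))
    out = np.empty(len(feature_index), dtype=bool)
    for f, nodes in enumerate(feature_index):
        for node in nodes:
            if node >= assignment.n_regions:
                raise DimensionError(
                    f"feature node {node} not covered by the network assignment")
        hits = sum(node in members for node in nodes)
        out[f] = (hits == len(nodes)) if mode == "within" else (hits > 0)
    return out


def nodal_strength_cv(triangle_features: np.ndarray,
                      n_regions: int) -> np.ndarray:
    """Coefficient of variation of the triangle nodal strength across subjects.

    ``triangle_features`` is a subjects x C(N,3) matrix of average
    violating-triangle weights (signed, as stored).  A region's strength for a
    subject is the sum over all triples containing it; the cv is the
    across-subject sample standard deviation divided by the mean.  Regions with
    zero mean strength are reported as NaN.
    """
    s, m = triangle_features.shape
    if s < 2:
        raise DimensionError("need at least 2 subjects for a cv")
    if m != comb(n_regions, 3):
        raise DimensionError(f"expected C({n_regions},3)={comb(n_regions, 3)} features")
    tris = tuple_indices(n_regions, 2)
    strength = np.zeros((s, n_regions))
    for col in range(3):
        np.add.at(strength.T, tris[:, col], triangle_features.T)
    mean = strength.mean(axis=0)
    sd = strength.std(axis=0, ddof=1)
    out = np.full(n_regions, np.nan)
    nz = mean != 0
    out[nz] = sd[nz] / mean[nz]
    return out
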