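"""Per-frame weighted simplicial complexes and their persistent homology.

At every time frame the signed edge and triangle co-fluctuation weights are
condensed into a weighted complex ``K^t``.  A descending filtration sweeps the
weights from the strongest (most coherent) simplices downward; triangles that
would enter before one of their own edges break simplicial closure and are
removed into the violation list ``Delta_v`` instead.  On the remaining complex
the one-dimensional homology H1 is tracked over Z/2: each loop is a bar with a
birth weight ``b_g`` (the edge that closed the cycle), a death weight ``d_g``
(the triangle that filled it, or the frame's minimum simplex weight for
essential loops) and a generator — the birth-cycle edge set from the standard
column reduction.

Derived indicators:

* hyper-coherence — fraction of coherent (positive-weight) triangles that are
  violating; a global per-frame score.
* hyper-complexity — sliced Wasserstein distance between the H1 diagram and
  the empty diagram (every bar matched to the diagonal).
* FC/CT/FD cycle classes — bars living entirely in coherent weights (b, d > 0),
  crossing into decoherence (b > 0 >= d), or fully decoherent (b <= 0).
* homological scaffold — edge weights counting how many H1 generators an edge
  belongs to.

Conventions (the persistence literature leaves these open): bars are reported
on the weight scale with ``b_g >= d_g`` and persistence ``pi_g = b_g - d_g >= 0``;
ties in the descending sort are broken by dimension (edges first) and then by
lexicographic tuple order; vertices are present from the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .cofluctuation import CofluctuationSet, tuple_indices
from .errors import DimensionError

__all__ = [
    "WeightedComplexFrame",
    "ViolationList",
    "PersistenceDiagram",
    "CycleClasses",
    "build_frame",
    "find_violations",
    "violation_mask",
    "hyper_coherence_frame",
    "persistence_h1",
    "persistence_h1_sparse",
    "hyper_complexity",
    "exact_wasserstein_empty",
    "classify_cycles",
    "scaffold_frame",
    "triangle_edge_indices",
    "ScanTopology",
    "scan_topology",
]


# ---------------------------------------------------------------------------
# frame containers


@dataclass
class WeightedComplexFrame:
    """One timepoint's weighted complex: all C(N,2) edges and C(N,3) triangles."""

    t: int
    n_regions: int
    edge_tuples: np.ndarray   # (E, 2)
    edge_weights: np.ndarray  # (E,)
    tri_tuples: np.ndarray    # (M, 3)
    tri_weights: np.ndarray   # (M,)

    def __post_init__(self) -> None:
        n = self.n_regions
        if self.edge_weights.shape[0] != comb(n, 2) or self.tri_weights.shape[0] != comb(n, 3):
            raise DimensionError("frame must carry all C(N,2) edges and C(N,3) triangles")


@dataclass
class ViolationList:
    """Triangles whose weight exceeds at least one of their edge weights."""

    t: int
    tuples: np.ndarray    # (V, 3)
    weights: np.ndarray   # (V,)
    mask: np.ndarray      # (C(N,3),) bool over the dense triangle ordering


@dataclass
class PersistenceDiagram:
    """H1 bars of one frame, on the weight scale (birth >= death)."""

    births: np.ndarray
    deaths: np.ndarray
    essential: np.ndarray                      # bool
    generators: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def n_bars(self) -> int:
        return int(self.births.size)

    @property
    def persistence(self) -> np.ndarray:
        return self.births - self.deaths

    @classmethod
    def empty(cls) -> "PersistenceDiagram":
        z = np.zeros(0)
        return cls(z, z.copy(), np.zeros(0, dtype=bool), [])


@dataclass
class CycleClasses:
    """Persistence-weighted shares of full-coherence / transition / decoherence bars."""

    fc: float
    ct: float
    fd: float
    defined: bool

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fc, self.ct, self.fd)


# ---------------------------------------------------------------------------
# construction and violations


def triangle_edge_indices(n_regions: int) -> np.ndarray:
    """For each lexicographic triangle (i,j,k), the dense edge positions of
    (i,j), (i,k), (j,k).  Shape (C(N,3), 3)."""
    pair_pos = {}
    for p, (i, j) in enumerate(map(tuple, tuple_indices(n_regions, 1))):
        pair_pos[(i, j)] = p
    tris = tuple_indices(n_regions, 2)
    out = np.empty((tris.shape[0], 3), dtype=np.int64)
    for m, (i, j, k) in enumerate(map(tuple, tris)):
        out[m] = (pair_pos[(i, j)], pair_pos[(i, k)], pair_pos[(j, k)])
    return out


def build_frame(edge_set: CofluctuationSet, tri_set: CofluctuationSet, t: int) -> WeightedComplexFrame:
    """Snapshot the order-1 and order-2 weights at frame ``t``."""
    if edge_set.k != 1 or tri_set.k != 2:
        raise DimensionError("need an order-1 and an order-2 set")
    if edge_set.n_regions != tri_set.n_regions:
        raise DimensionError("edge and triangle sets cover different N")
    if not (0 <= t < edge_set.n_frames) or edge_set.n_frames != tri_set.n_frames:
        raise IndexError(f"frame {t} out of range for T={edge_set.n_frames}")
    return WeightedComplexFrame(
        t=t,
        n_regions=edge_set.n_regions,
        edge_tuples=edge_set.tuples,
        edge_weights=edge_set.weights[:, t].copy(),
        tri_tuples=tri_set.tuples,
        tri_weights=tri_set.weights[:, t].copy(),
    )


def violation_mask(edge_weights: np.ndarray, tri_weights: np.ndarray,
                   tri_edges: np.ndarray) -> np.ndarray:
    """Boolean mask over dense triangles: weight strictly above the minimum of
    the triangle's three edge weights (simplicial-closure violation).

    Works frame-wise on 1-D weights or on (M, T) stacks.
    """
    min_edge = edge_weights[tri_edges].min(axis=1)
    return tri_weights > min_edge


def find_violations(frame: WeightedComplexFrame,
                    tri_edges: np.ndarray | None = None) -> ViolationList:
    """List the triangles of a frame that violate simplicial closure.

    A triangle (i,j,k) violates when at least one of its edges satisfies
    ``w_ij < w_ijk``; ties (``w_ijk`` equal to the minimum edge weight) do not
    violate, so a retained triangle never precedes its slowest edge in the
    descending filtration.
    """
    if tri_edges is None:
        tri_edges = triangle_edge_indices(frame.n_regions)
    mask = violation_mask(frame.edge_weights, frame.tri_weights, tri_edges)
    return ViolationList(
        t=frame.t,
        tuples=frame.tri_tuples[mask],
        weights=frame.tri_weights[mask],
        mask=mask,
    )


def hyper_coherence_frame(violations: ViolationList, tri_weights: np.ndarray) -> float:
    """Fraction of coherent (w > 0) triangles that are violating, for one frame.

    A frame with no coherent triangle contributes 0.
    """
    coherent = tri_weights > 0
    n_coh = int(coherent.sum())
    if n_coh == 0:
        return 0.0
    return float((violations.mask & coherent).sum() / n_coh)


# ---------------------------------------------------------------------------
# persistence


def _filtration_order(frame: WeightedComplexFrame, keep_tri: np.ndarray):
    """Descending filtration over edges and retained triangles.

    Returns ``(edge_order, items)`` where items is the merged order as a list of
    ``(dim, local_index)`` and edge filtration positions are implied by
    appearance order.  Ties: higher weight first, then edges before triangles,
    then lexicographic tuples (the dense local index is already lexicographic).
    """
    e_w = frame.edge_weights
    t_idx = np.flatnonzero(keep_tri)
    t_w = frame.tri_weights[t_idx]
    w = np.concatenate([e_w, t_w])
    dim = np.concatenate([np.ones(e_w.size), 2 * np.ones(t_w.size)])
    lex = np.concatenate([np.arange(e_w.size), np.arange(t_w.size)])
    order = np.lexsort((lex, dim, -w))
    items = []
    for pos in order:
        if pos < e_w.size:
            items.append((1, int(pos)))
        else:
            items.append((2, int(t_idx[pos - e_w.size])))
    return items


def persistence_h1(frame: WeightedComplexFrame,
                   violations: ViolationList | None = None,
                   tri_edges: np.ndarray | None = None) -> PersistenceDiagram:
    """H1 persistence of one frame's descending filtration, with generators.

    Violating triangles are excluded from the complex.  The reduction is the
    standard Z/2 boundary-column algorithm: a union-find pass classifies edges
    as tree (H0-killing) or cycle-creating, cycle-creating edges record their
    birth cycle (edge + tree path); triangle columns are then reduced against
    each other, pairing each with the youngest cycle-creating edge they fill.
    Unpaired cycle edges yield essential bars whose death is capped at the
    frame's minimum simplex weight.
    """
    if tri_edges is None:
        tri_edges = triangle_edge_indices(frame.n_regions)
    if violations is None:
        violations = find_violations(frame, tri_edges)
    keep = ~violations.mask
    return _reduce_h1(frame, keep, tri_edges)


def persistence_h1_sparse(n_regions: int,
                          edge_tuples: np.ndarray,
                          edge_weights: np.ndarray,
                          tri_tuples: np.ndarray | None = None,
                          tri_weights: np.ndarray | None = None) -> PersistenceDiagram:
    """H1 persistence of an explicit (possibly sparse) weighted complex.

    Same conventions as :func:`persistence_h1` but the caller lists exactly
    the simplices present; closure violations among the listed triangles are
    still removed.  Every triangle's three edges must be listed.
    """
    edge_tuples = np.asarray(edge_tuples, dtype=np.int64).reshape(-1, 2)
    edge_weights = np.asarray(edge_weights, dtype=np.float64)
    if tri_tuples is None or len(tri_tuples) == 0:
        tri_tuples = np.zeros((0, 3), dtype=np.int64)
        tri_weights = np.zeros(0)
    tri_tuples = np.asarray(tri_tuples, dtype=np.int64).reshape(-1, 3)
    tri_weights = np.asarray(tri_weights, dtype=np.float64)
    pair_pos = {tuple(int(x) for x in e): p for p, e in enumerate(edge_tuples)}
    tri_edges = np.empty((tri_tuples.shape[0], 3), dtype=np.int64)
    for m, (i, j, k) in enumerate(map(tuple, tri_tuples)):
        try:
            tri_edges[m] = (pair_pos[(i, j)], pair_pos[(i, k)], pair_pos[(j, k)])
        except KeyError as exc:
            raise DimensionError(f"triangle ({i},{j},{k}) misses edge {exc}") from exc
    frame = WeightedComplexFrame.__new__(WeightedComplexFrame)
    frame.t = 0
    frame.n_regions = n_regions
    frame.edge_tuples = edge_tuples
    frame.edge_weights = edge_weights
    frame.tri_tuples = tri_tuples
    frame.tri_weights = tri_weights
    keep = ~violation_mask(edge_weights, tri_weights, tri_edges) \
        if tri_weights.size else np.zeros(0, dtype=bool)
    return _reduce_h1(frame, keep, tri_edges)


def _reduce_h1(frame: WeightedComplexFrame, keep: np.ndarray,
               tri_edges: np.ndarray) -> PersistenceDiagram:
    items = _filtration_order(frame, keep)

    n = frame.n_regions
    uf_parent = list(range(n))

    def find(a: int) -> int:
        root = a
        while uf_parent[root] != root:
            root = uf_parent[root]
        while uf_parent[a] != root:
            uf_parent[a], a = root, uf_parent[a]
        return root

    # forest adjacency for birth-cycle extraction
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]  # node -> (nbr, edge_filt_pos)

    edge_filt_pos = np.full(frame.edge_weights.size, -1, dtype=np.int64)
    pos_weight: dict[int, float] = {}          # filtration pos -> weight (edges)
    pos_edge_local: dict[int, int] = {}        # filtration pos -> dense edge index
    cycle_reps: dict[int, int] = {}            # creator edge pos -> bitset over edge positions
    pivots: dict[int, int] = {}                # pivot edge pos -> reduced triangle column
    pairs: list[tuple[int, float]] = []        # (creator edge pos, death weight)

    next_pos = 0
    for dim, local in items:
        if dim == 1:
            u, v = (int(x) for x in frame.edge_tuples[local])
            pos = next_pos
            next_pos += 1
            edge_filt_pos[local] = pos
            pos_weight[pos] = float(frame.edge_weights[local])
            pos_edge_local[pos] = local
            ru, rv = find(u), find(v)
            if ru != rv:
                uf_parent[ru] = rv
                adj[u].append((v, pos))
                adj[v].append((u, pos))
            else:
                # cycle creator: birth cycle = edge + tree path u..v (BFS)
                prev = {u: (-1, -1)}
                queue = [u]
                while queue:
                    nxt = []
                    for a in queue:
                        if a == v:
                            nxt = []
                            queue = []
                            break
                        for b, epos in adj[a]:
                            if b not in prev:
                                prev[b] = (a, epos)
                                nxt.append(b)
                    else:
                        queue = nxt
                        continue
                    break
                rep = 1 << pos
                node = v
                while prev[node][0] != -1:
                    node, epos = prev[node]
                    rep ^= 1 << epos
                cycle_reps[pos] = rep
        else:
            # triangle column over its 3 edge filtration positions
            col = 0
            for e_local in tri_edges[local]:
                col ^= 1 << int(edge_filt_pos[e_local])
            while col:
                low = col.bit_length() - 1
                other = pivots.get(low)
                if other is None:
                    break
                col ^= other
            if col:
                low = col.bit_length() - 1
                pivots[low] = col
                pairs.append((low, float(frame.tri_weights[local])))
            # col == 0 would create an H2 class; ignored.

    if not cycle_reps:
        return PersistenceDiagram.empty()

    kept_tri_w = frame.tri_weights[keep]
    min_weight = float(min(frame.edge_weights.min(),
                           kept_tri_w.min() if kept_tri_w.size else np.inf))

    paired = {p: d for p, d in pairs}
    births, deaths, essential, gens = [], [], [], []
    for pos in sorted(cycle_reps):
        births.append(pos_weight[pos])
        if pos in paired:
            deaths.append(paired[pos])
            essential.append(False)
        else:
            deaths.append(min_weight)
            essential.append(True)
        rep = cycle_reps[pos]
        edges = []
        while rep:
            low = rep.bit_length() - 1
            rep ^= 1 << low
            i, j = (int(x) for x in frame.edge_tuples[pos_edge_local[low]])
            edges.append((i, j))
        gens.append(sorted(edges))

    return PersistenceDiagram(
        births=np.asarray(births, dtype=np.float64),
        deaths=np.asarray(deaths, dtype=np.float64),
        essential=np.asarray(essential, dtype=bool),
        generators=gens,
    )


# ---------------------------------------------------------------------------
# diagram functionals


def hyper_complexity(diagram: PersistenceDiagram, n_slices: int = 50) -> float:
    """Sliced Wasserstein distance between the H1 diagram and the empty diagram.

    Every bar is matched to its orthogonal projection on the diagonal; the
    matching cost is sliced over ``n_slices`` directions uniform in
    ``[-pi/2, pi/2)`` and rescaled by ``pi/2`` so that the value converges, as
    the number of slices grows, to the exact diagonal-matching cost
    ``sum |b - d| / sqrt(2)`` (Euclidean ground metric).
    """
    if diagram.n_bars == 0:
        return 0.0
    if n_slices < 1:
        raise ValueError("need at least one slice")
    theta = np.linspace(-np.pi / 2, np.pi / 2, n_slices, endpoint=False)
    gaps = np.abs(diagram.births - diagram.deaths)
    per_dir = 0.5 * np.abs(np.cos(theta) - np.sin(theta))
    return float((np.pi / 2) * per_dir.mean() * gaps.sum())


def exact_wasserstein_empty(diagram: PersistenceDiagram) -> float:
    """Exact W1 cost of matching every bar to the diagonal (Euclidean metric).

    The nearest diagonal point of ``(b, d)`` is its orthogonal projection, at
    distance ``|b - d| / sqrt(2)``; the cost is additive over bars.
    """
    if diagram.n_bars == 0:
        return 0.0
    return float(np.sum(np.abs(diagram.births - diagram.deaths)) / np.sqrt(2.0))


def classify_cycles(diagram: PersistenceDiagram) -> CycleClasses:
    """Persistence-weighted shares of FC / CT / FD bars.

    Full coherence: ``b > 0 and d > 0``; coherence transition: ``b > 0 >= d``;
    full decoherence: ``b <= 0``.  Shares weight each bar by its persistence
    ``b - d`` (falling back to counts when every bar has zero persistence);
    an empty diagram returns zero shares with ``defined=False``.
    """
    if diagram.n_bars == 0:
        return CycleClasses(0.0, 0.0, 0.0, defined=False)
    b, d = diagram.births, diagram.deaths
    w = diagram.persistence
    if w.sum() == 0:
        w = np.ones_like(w)
    fc = (b > 0) & (d > 0)
    fd = b <= 0
    ct = ~(fc | fd)
    tot = float(w.sum())
    return CycleClasses(float(w[fc].sum() / tot), float(w[ct].sum() / tot),
                        float(w[fd].sum() / tot), defined=True)


def scaffold_frame(diagram: PersistenceDiagram, n_regions: int) -> np.ndarray:
    """Frequency homological scaffold: per dense edge, the number of H1
    generators that contain it.  Returns a ``C(N,2)`` integer vector."""
    pair_pos = {tuple(int(x) for x in p): i
                for i, p in enumerate(tuple_indices(n_regions, 1))}
    out = np.zeros(comb(n_regions, 2), dtype=np.int64)
    for gen in diagram.generators:
        for e in gen:
            out[pair_pos[tuple(e)]] += 1
    return out


# ---------------------------------------------------------------------------
# whole-scan pipeline


@dataclass
class ScanTopology:
    """Per-frame topological outputs for a whole scan."""

    n_regions: int
    viol_mask: np.ndarray          # (C(N,3), T) bool
    tri_indicator: np.ndarray      # (C(N,3), T): w_ijk(t) where violating, else 0
    scaffold: np.ndarray           # (C(N,2), T): generator-frequency weights
    hyper_coherence_t: np.ndarray  # (T,)
    hyper_complexity_t: np.ndarray # (T,)
    diagrams: list[PersistenceDiagram]

    @property
    def hyper_coherence(self) -> float:
        """Scan-level score: mean of the per-frame fractions."""
        return float(self.hyper_coherence_t.mean())

    @property
    def hyper_complexity(self) -> float:
        return float(self.hyper_complexity_t.mean())

    def cycle_classes(self) -> CycleClasses:
        """FC/CT/FD shares pooled over every frame's bars."""
        merged = PersistenceDiagram(
            births=np.concatenate([d.births for d in self.diagrams]) if self.diagrams else np.zeros(0),
            deaths=np.concatenate([d.deaths for d in self.diagrams]) if self.diagrams else np.zeros(0),
            essential=np.concatenate([d.essential for d in self.diagrams]) if self.diagrams else np.zeros(0, dtype=bool),
            generators=[],
        )
        return classify_cycles(merged)


def scan_topology(edge_set: CofluctuationSet, tri_set: CofluctuationSet,
                  n_slices: int = 50, keep_diagrams: bool = True) -> ScanTopology:
    """Run violations, persistence and all indicators over every frame of a scan."""
    if edge_set.n_regions != tri_set.n_regions or edge_set.n_frames != tri_set.n_frames:
        raise DimensionError("edge and triangle sets are inconsistent")
    n = edge_set.n_regions
    T = edge_set.n_frames
    tri_edges = triangle_edge_indices(n)

    vmask = violation_mask(edge_set.weights, tri_set.weights, tri_edges)  # (M3, T)
    tri_ind = np.where(vmask, tri_set.weights, 0.0)

    coherent = tri_set.weights > 0
    n_coh = coherent.sum(axis=0)
    n_viol_coh = (vmask & coherent).sum(axis=0)
    hc = np.divide(n_viol_coh, n_coh, out=np.zeros(T, dtype=np.float64),
                   where=n_coh > 0)

    scaff = np.zeros((edge_set.tuples.shape[0], T), dtype=np.float64)
    hx = np.zeros(T)
    diagrams: list[PersistenceDiagram] = []
    for t in range(T):
        frame = WeightedComplexFrame(
            t=t, n_regions=n,
            edge_tuples=edge_set.tuples, edge_weights=edge_set.weights[:, t],
            tri_tuples=tri_set.tuples, tri_weights=tri_set.weights[:, t],
        )
        viol = ViolationList(t=t, tuples=tri_set.tuples[vmask[:, t]],
                             weights=tri_set.weights[vmask[:, t], t],
                             mask=vmask[:, t])
        dgm = persistence_h1(frame, violations=viol, tri_edges=tri_edges)
        scaff[:, t] = _scaffold_from_diagram(dgm, edge_set)
        hx[t] = hyper_complexity(dgm, n_slices=n_slices)
        if keep_diagrams:
            diagrams.append(dgm)

    return ScanTopology(n_regions=n, viol_mask=vmask, tri_indicator=tri_ind,
                        scaffold=scaff, hyper_coherence_t=hc,
                        hyper_complexity_t=hx, diagrams=diagrams)


def _scaffold_from_diagram(dgm: PersistenceDiagram, edge_set: CofluctuationSet) -> np.ndarray:
    out = np.zeros(edge_set.tuples.shape[0], dtype=np.float64)
    if dgm.n_bars == 0:
        return out
    n = edge_set.n_regions
    for gen in dgm.generators:
        for i, j in gen:
            # dense lexicographic position of pair (i, j), i < j
            pos = i * (2 * n - i - 1) // 2 + (j - i - 1)
            out[pos] += 1
    return out
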