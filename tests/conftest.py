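"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from hobrain.topology import (WeightedComplexFrame, find_violations,
                              triangle_edge_indices)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frame(n, edge_w, tri_w, t=0):
    """Dense frame from explicit weight vectors (lexicographic order)."""
    return WeightedComplexFrame(
        t=t, n_regions=n,
        edge_tuples=np.array(list(combinations(range(n), 2)), dtype=np.int64),
        edge_weights=np.asarray(edge_w, dtype=np.float64),
        tri_tuples=np.array(list(combinations(range(n), 3)), dtype=np.int64),
        tri_weights=np.asarray(tri_w, dtype=np.float64),
    )


def random_frame(rng, n):
    return make_frame(n, rng.normal(size=comb(n, 2)), rng.normal(size=comb(n, 3)))


def brute_force_h1(frame):
    """Full boundary-matrix Z/2 reduction, written independently of the
    package's union-find/bitset implementation.

    Returns a sorted list of (birth, death, essential) bars.
    """
    tri_edges = triangle_edge_indices(frame.n_regions)
    keep = ~find_violations(frame, tri_edges).mask
    ew, tw = frame.edge_weights, frame.tri_weights

    order = [(1, e, ew[e]) for e in range(ew.size)]
    order += [(2, int(m), tw[m]) for m in np.flatnonzero(keep)]
    order.sort(key=lambda x: (-x[2], x[0], x[1]))

    cols, index = [], {}
    for i in range(frame.n_regions):
        cols.append(set())
        index[("v", i)] = len(cols) - 1
    for dim, local, _w in order:
        if dim == 1:
            u, v = frame.edge_tuples[local]
            cols.append({index[("v", int(u))], index[("v", int(v))]})
            index[("e", local)] = len(cols) - 1
        else:
            cols.append({index[("e", int(e))] for e in tri_edges[local]})
            index[("t", local)] = len(cols) - 1

    lows, pairs, positives = {}, {}, set()
    for j in range(len(cols)):
        col = set(cols[j])
        while col:
            low = max(col)
            if low in lows:
                col ^= cols[lows[low]]
            else:
                break
        cols[j] = col
        if col:
            lows[max(col)] = j
            pairs[max(col)] = j
        else:
            positives.add(j)

    inv = {v: k for k, v in index.items()}
    kept_tw = tw[keep]
    min_w = min(ew.min(), kept_tw.min() if kept_tw.size else np.inf)
    weight_of = {("e" if d == 1 else "t", l): w for d, l, w in order}
    bars = []
    for j in positives:
        kind, local = inv[j]
        if kind != "e":
            continue
        b = weight_of[("e", local)]
        if j in pairs:
            bars.append((b, weight_of[inv[pairs[j]]], False))
        else:
            bars.append((b, float(min_w), True))
    return sorted(bars)


def bars_of(diagram, digits=12):
    return sorted(zip(np.round(diagram.births, digits).tolist(),
                      np.round(diagram.deaths, digits).tolist(),
                      diagram.essential.tolist()))


def ecs_ppr_oracle(labels1, labels2, alpha=0.9):
    """Element-centric similarity by explicit personalized-PageRank inversion
    on the cluster-induced element graphs (brute force)."""
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    n = labels1.size

    def affinity(labels):
        p = np.zeros((n, n))
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            trans = np.zeros((n, n))
            trans[np.ix_(members, members)] = 1.0 / members.size
            block = np.linalg.inv(np.eye(n) - alpha * trans)
            for i in members:
                e = np.zeros(n)
                e[i] = 1.0
                p[i] = (1 - alpha) * block.T @ e
        return p

    p1, p2 = affinity(labels1), affinity(labels2)
    per_element = 1.0 - np.abs(p1 - p2).sum(axis=1) / (2.0 * alpha)
    return float(per_element.mean())
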