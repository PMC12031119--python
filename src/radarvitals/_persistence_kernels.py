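"""Numba kernels for persistence computations.

These are deliberately free of Python objects: plain arrays in, plain
arrays out.  The public API lives in :mod:`radarvitals.tda`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Sublevel-set H0 of a 1-D series (union-find with elder rule)
# ---------------------------------------------------------------------------


@njit(cache=True)
def sublevel_h0(values):  # pragma: no cover - exercised via tda tests
    """Birth/death pairs of 0-dim sublevel-set persistence of a 1-D series.

    Samples are processed in increasing value order (ties broken by index,
    i.e. left to right).  Each local minimum births a component; at merges
    the component with the larger birth value dies (elder rule).  The
    essential component is closed at the global maximum.  Pairs with zero
    lifespan (plateaus) are dropped.

    Returns an (n_pairs, 2) float64 array of (birth, death).
    """
    n = values.shape[0]
    order = np.argsort(values, kind="mergesort")  # stable: ties left-to-right
    parent = np.full(n, -1, dtype=np.int64)   # -1: not yet in filtration
    birth = np.empty(n, dtype=np.float64)     # birth value of each root
    birth_seq = np.empty(n, dtype=np.int64)   # processing rank, for tie-break
    out = np.empty((n, 2), dtype=np.float64)
    n_pairs = 0

    for rank in range(n):
        i = order[rank]
        v = values[i]
        parent[i] = i
        birth[i] = v
        birth_seq[i] = rank
        for nb in (i - 1, i + 1):
            if nb < 0 or nb >= n or parent[nb] == -1:
                continue
            # find roots with path halving
            a = i
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            b = nb
            while parent[b] != b:
                parent[b] = parent[parent[b]]
                b = parent[b]
            if a == b:
                continue
            # elder rule: the root with the larger (birth, seq) dies now
            if (birth[a] > birth[b]) or (
                birth[a] == birth[b] and birth_seq[a] > birth_seq[b]
            ):
                young, old = a, b
            else:
                young, old = b, a
            if v > birth[young]:
                out[n_pairs, 0] = birth[young]
                out[n_pairs, 1] = v
                n_pairs += 1
            parent[young] = old

    # essential class: global minimum paired with global maximum
    gmin = values[order[0]]
    gmax = values[order[n - 1]]
    if gmax > gmin:
        out[n_pairs, 0] = gmin
        out[n_pairs, 1] = gmax
        n_pairs += 1
    return out[:n_pairs]


# ---------------------------------------------------------------------------
# Vietoris-Rips H0 (single linkage) and H1 (boundary-matrix reduction)
# ---------------------------------------------------------------------------


@njit(cache=True)
def mst_deaths(edge_u, edge_v, edge_len, n_points):  # pragma: no cover
    """Kruskal over edges pre-sorted by length; returns merge lengths.

    The returned array holds the n_points - 1 H0 death values (single
    linkage merge scales) in increasing order.
    """
    parent = np.arange(n_points)
    out = np.empty(n_points - 1, dtype=np.float64)
    k = 0
    for e in range(edge_u.shape[0]):
        a = edge_u[e]
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        b = edge_v[e]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a != b:
            parent[a] = b
            out[k] = edge_len[e]
            k += 1
            if k == n_points - 1:
                break
    return out[:k]


@njit(cache=True)
def reduce_triangles(tri_edges, n_edges):  # pragma: no cover
    """Reduce the dim-2 boundary matrix over GF(2) with bitset columns.

    Parameters
    ----------
    tri_edges:
        (n_tri, 3) int64 array of edge filtration ranks per triangle,
        triangles already sorted by filtration order (diameter).
    n_edges:
        Total number of edges (rows of the boundary matrix).

    Returns
    -------
    (n_edges,) int64 array mapping each edge rank to the index of the
    triangle that kills it, or -1 if unpaired.
    """
    n_words = (n_edges + 63) >> 6
    store = np.zeros((n_edges, n_words), dtype=np.uint64)
    has_col = np.zeros(n_edges, dtype=np.uint8)
    killer = np.full(n_edges, -1, dtype=np.int64)
    work = np.zeros(n_words, dtype=np.uint64)
    one = np.uint64(1)

    for t in range(tri_edges.shape[0]):
        for w in range(n_words):
            work[w] = np.uint64(0)
        pivot = -1
        for s in range(3):
            e = tri_edges[t, s]
            work[e >> 6] ^= one << np.uint64(e & 63)
            if e > pivot:
                pivot = e
        while True:
            if has_col[pivot] == 0:
                for w in range(n_words):
                    store[pivot, w] = work[w]
                has_col[pivot] = 1
                killer[pivot] = t
                break
            for w in range(n_words):
                work[w] ^= store[pivot, w]
            # rescan for the new pivot (highest set bit)
            pivot = -1
            for w in range((n_edges - 1) >> 6, -1, -1):
                v = work[w]
                if v != np.uint64(0):
                    b = 0
                    while v > one:
                        v >>= one
                        b += 1
                    pivot = (w << 6) + b
                    break
            if pivot == -1:
                break  # positive triangle (births an H2 class; ignored)
    return killer


@njit(cache=True)
def enumerate_triangles(dist, edge_rank, threshold):  # pragma: no cover
    """All triangles with diameter <= threshold, sorted by diameter.

    Returns (tri_edges, tri_diam): edge-rank triples and diameters, ordered
    by increasing diameter (stable).
    """
    n = dist.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > threshold:
                continue
            for k in range(j + 1, n):
                if dist[i, k] <= threshold and dist[j, k] <= threshold:
                    count += 1
    tri_edges = np.empty((count, 3), dtype=np.int64)
    tri_diam = np.empty(count, dtype=np.float64)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = dist[i, j]
            if dij > threshold:
                continue
            for k in range(j + 1, n):
                dik = dist[i, k]
                djk = dist[j, k]
                if dik <= threshold and djk <= threshold:
                    d = dij
                    if dik > d:
                        d = dik
                    if djk > d:
                        d = djk
                    tri_edges[idx, 0] = edge_rank[i, j]
                    tri_edges[idx, 1] = edge_rank[i, k]
                    tri_edges[idx, 2] = edge_rank[j, k]
                    tri_diam[idx] = d
                    idx += 1
    order = np.argsort(tri_diam, kind="mergesort")
    return tri_edges[order], tri_diam[order]
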