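"""Topological machinery: time-delay embedding, sublevel-set H0 persistence
of 1-D series, Vietoris-Rips H0/H1 persistence of point clouds, the
birth-lifespan transform and the diagram-spread scale.

Conventions
-----------
* Rips scale is reported in *distance* (diameter) units: an edge enters the
  filtration when the pairwise distance is <= scale.  Mind the factor two
  against radius-based definitions.
* The Rips H0 essential class (infinite death) is excluded from the
  returned pairs; ``max_finite_h0`` statistics therefore refer to the
  largest single-linkage merge scale.
* The sublevel-set H0 essential class is closed at the global maximum of
  the series, so all sublevel pairs are finite.
* Zero-lifespan pairs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._persistence_kernels import (
    enumerate_triangles,
    mst_deaths,
    reduce_triangles,
    sublevel_h0,
)

MAX_RIPS_POINTS = 10_000


@dataclass(frozen=True)
class EmbeddingParams:
    """Uniform time-delay embedding parameters.

    ``tau`` is the delay in samples (default 10, i.e. 0.5 s at 20 Hz) and
    ``m`` the embedding dimension (default 3).
    """

    tau: int = 10
    m: int = 3

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.m < 2:
            raise ValueError("m must be >= 2")


@dataclass(frozen=True)
class PersistenceDiagram:
    """Birth/death pairs of one homology dimension.

    ``pairs`` is an (n, 2) float array.  ``representation`` is either
    ``"birth-death"`` or ``"birth-lifespan"``.
    """

    dim: int
    pairs: np.ndarray
    representation: str = "birth-death"

    def __post_init__(self) -> None:
        pairs = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        if pairs.size == 0:
            pairs = np.empty((0, 2))
        if pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if self.representation not in ("birth-death", "birth-lifespan"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if np.any(pairs[:, 1] < (pairs[:, 0] if self.representation == "birth-death" else 0)):
            raise ValueError("deaths must be >= births (lifespans >= 0)")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def births(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        if self.representation == "birth-death":
            return self.pairs[:, 1]
        return self.pairs[:, 0] + self.pairs[:, 1]

    @property
    def lifespans(self) -> np.ndarray:
        if self.representation == "birth-lifespan":
            return self.pairs[:, 1]
        return self.pairs[:, 1] - self.pairs[:, 0]


def to_birth_lifespan(diagram: PersistenceDiagram) -> PersistenceDiagram:
    """Convert (birth, death) pairs to (birth, death - birth)."""
    if diagram.representation == "birth-lifespan":
        return diagram
    pairs = np.column_stack([diagram.births, diagram.lifespans])
    return PersistenceDiagram(diagram.dim, pairs, "birth-lifespan")


def to_birth_death(diagram: PersistenceDiagram) -> PersistenceDiagram:
    """Inverse of :func:`to_birth_lifespan`."""
    if diagram.representation == "birth-death":
        return diagram
    pairs = np.column_stack([diagram.births, diagram.deaths])
    return PersistenceDiagram(diagram.dim, pairs, "birth-death")


def time_delay_embed(series: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Uniform time-delay embedding of a scalar series.

    Point ``p`` of the output is ``(x(t), x(t - tau), ..., x(t - (m-1) tau))``
    for ``t = (m-1) tau .. len-1``; the cloud has ``len - (m-1) tau`` points.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    span = (params.m - 1) * params.tau
    if len(x) <= span:
        raise ValueError(
            f"series of length {len(x)} too short for tau={params.tau}, "
            f"m={params.m} (needs > {span} samples)"
        )
    cols = [x[span - k * params.tau : len(x) - k * params.tau]
            for k in range(params.m)]
    return np.column_stack(cols)


def sublevel_persistence(series: np.ndarray) -> PersistenceDiagram:
    """H0 persistence of the sublevel-set filtration of a 1-D series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return PersistenceDiagram(0, sublevel_h0(x))


def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def rips_persistence(
    points: np.ndarray,
    maxdim: int = 1,
    *,
    allow_large: bool = False,
) -> dict[int, PersistenceDiagram]:
    """Vietoris-Rips persistence (H0 and optionally H1) of a point cloud.

    H0 deaths are the single-linkage merge scales (MST edge lengths); the
    essential H0 class is not reported.  H1 is computed by GF(2) reduction
    of the triangle boundary matrix, with the filtration truncated at the
    enclosing radius of the cloud (beyond which the complex is a cone and
    H1 is trivial, so no H1 pair is lost).

    Parameters
    ----------
    points:
        (n, d) coordinates.
    maxdim:
        0 or 1.
    allow_large:
        Clouds above 10_000 points are refused unless this flag is set;
        subsample first (see :func:`farthest_point_subsample`).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("point cloud is empty")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point cloud contains non-finite coordinates")
    if maxdim not in (0, 1):
        raise ValueError("maxdim must be 0 or 1")
    n = len(pts)
    if n > MAX_RIPS_POINTS and not allow_large:
        raise ValueError(
            f"{n} points exceed the {MAX_RIPS_POINTS}-point guard; "
            "subsample the cloud or pass allow_large=True"
        )

    if n == 1:
        out = {0: PersistenceDiagram(0, np.empty((0, 2)))}
        if maxdim == 1:
            out[1] = PersistenceDiagram(1, np.empty((0, 2)))
        return out

    dist = _pairwise(pts)
    iu, ju = np.triu_indices(n, k=1)
    lengths = dist[iu, ju]
    order = np.lexsort((ju, iu, lengths))
    edge_u = iu[order].astype(np.int64)
    edge_v = ju[order].astype(np.int64)
    edge_len = lengths[order]

    h0_pairs = np.column_stack([
        np.zeros(n - 1), mst_deaths(edge_u, edge_v, edge_len, n)
    ])
    h0_pairs = h0_pairs[h0_pairs[:, 1] > 0]
    out = {0: PersistenceDiagram(0, h0_pairs)}
    if maxdim == 0:
        return out

    # enclosing radius: beyond it the complex cones off and H1 dies
    threshold = float(np.min(np.max(dist, axis=1)))
    keep = edge_len <= threshold
    n_edges = int(np.sum(keep))
    edge_rank = np.full((n, n), -1, dtype=np.int64)
    ranks = np.cumsum(keep) - 1
    for e in range(len(edge_len)):
        if keep[e]:
            edge_rank[edge_u[e], edge_v[e]] = ranks[e]
            edge_rank[edge_v[e], edge_u[e]] = ranks[e]
    kept_len = edge_len[keep]

    tri_edges, tri_diam = enumerate_triangles(dist, edge_rank, threshold)
    h1 = []
    if len(tri_edges):
        killer = reduce_triangles(tri_edges, n_edges)
        for e in range(n_edges):
            t = killer[e]
            if t >= 0 and tri_diam[t] > kept_len[e]:
                h1.append((kept_len[e], tri_diam[t]))
    out[1] = PersistenceDiagram(1, np.array(h1).reshape(-1, 2))
    return out


def diagram_spread(points: np.ndarray, *, mode: str = "connection") -> float:
    """Data-driven DBSCAN scale from the spread of diagram points.

    ``mode="connection"`` (default) returns the largest finite Rips H0
    death of the 2-D cloud of diagram points, i.e. the single-linkage
    connection scale (the longest minimum-spanning-tree edge).
    ``mode="diameter"`` returns the plain cloud diameter instead.

    Raises ``ValueError`` for fewer than two points ("no spread"); callers
    must fall back to their own scale.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("diagram spread undefined for fewer than 2 points")
    dist = _pairwise(pts)
    if mode == "diameter":
        return float(dist.max())
    if mode != "connection":
        raise ValueError(f"unknown mode {mode!r}")
    iu, ju = np.triu_indices(len(pts), k=1)
    lengths = dist[iu, ju]
    order = np.argsort(lengths, kind="stable")
    deaths = mst_deaths(
        iu[order].astype(np.int64), ju[order].astype(np.int64),
        lengths[order], len(pts),
    )
    return float(deaths[-1]) if len(deaths) else 0.0


def farthest_point_subsample(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point (minmax) subsample of a cloud.

    Starts from the first point; returns the selected rows (all of them if
    the cloud has at most ``k`` points).  Preserves coarse geometry, which
    is what the Rips H1 scale estimate needs.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pts) <= k:
        return pts
    selected = np.empty(k, dtype=int)
    selected[0] = 0
    d = np.linalg.norm(pts - pts[0], axis=1)
    for i in range(1, k):
        selected[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(pts - pts[selected[i]], axis=1))
    return pts[np.sort(selected)]
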