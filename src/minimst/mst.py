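"""Exact Euclidean minimum spanning trees via Prim's algorithm.

A minimum spanning tree (MST) over ``N`` points connects all of them with
``N - 1`` edges of minimal total weight, where each weight is the Euclidean
distance between the two endpoints.  Prim's algorithm grows the tree from a
root point, repeatedly attaching the closest non-tree point; the order in
which points are attached, and which endpoint acted as parent, are recorded
because the detection stage downstream consumes both.

Everything here is deterministic: ties among candidate edges are broken by
the smallest point index, so a fixed root always yields the same edge
sequence.  The MST's *total* weight is root-invariant whenever pairwise
distances are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PointSet",
    "Edge",
    "MstResult",
    "euclidean_distance",
    "build_prim_mst",
    "sort_edges_nondecreasing",
]

#: Edge-weight measures: plain Euclidean, or Euclidean scaled by the
#: global termination threshold ("ted").
EUCLIDEAN = "euclidean"
TED = "ted"


@dataclass
class PointSet:
    """An ``N x n`` numeric dataset with optional ground-truth outlier flags.

    Parameters
    ----------
    coordinates : ndarray of shape (N, n)
        Feature matrix; must be finite (no NaN/inf) with ``N >= 2``,
        ``n >= 1``.
    truth_labels : ndarray of shape (N,), optional
        Binary per-point flags, 1 = outlier, 0 = normal.
    ids : sequence of str, optional
        Per-point identifiers; defaults to the row index on output.
    """

    coordinates: np.ndarray
    truth_labels: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coordinates must be a 2-D array of shape (N, n)")
        if coords.shape[0] < 2:
            raise ValueError(f"need at least 2 points, got N={coords.shape[0]}")
        if coords.shape[1] < 1:
            raise ValueError("need at least one feature")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates contain missing or non-finite values")
        self.coordinates = coords
        if self.truth_labels is not None:
            labels = np.asarray(self.truth_labels, dtype=int)
            if labels.shape != (coords.shape[0],):
                raise ValueError(
                    f"truth_labels length {labels.shape} does not match N={coords.shape[0]}"
                )
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("truth_labels must be binary (0 = normal, 1 = outlier)")
            self.truth_labels = labels
        if self.ids is not None and len(self.ids) != coords.shape[0]:
            raise ValueError("ids length does not match N")

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_features(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class Edge:
    """One tree edge: point indices ``a`` (parent) and ``b`` (child)."""

    a: int
    b: int
    weight: float
    measure: str = EUCLIDEAN

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-loop edge")
        if self.weight < 0:
            raise ValueError("edge weight must be nonnegative")
        if self.measure not in (EUCLIDEAN, TED):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass
class MstResult:
    """A spanning tree: edges in Prim addition order, plus the root used."""

    edges: list[Edge]
    root: int
    total_weight: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.total_weight = float(sum(e.weight for e in self.edges))

    @property
    def n_points(self) -> int:
        return len(self.edges) + 1


def euclidean_distance(x1, x2) -> float:
    """Euclidean distance between two points of equal dimension.

    >>> euclidean_distance([0, 0], [3, 4])
    5.0
    """
    p, q = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(((p - q) ** 2).sum()))


def pairwise_distances(coordinates: np.ndarray) -> np.ndarray:
    """Full N x N Euclidean distance matrix (the package works at desk scale)."""
    return cdist(coordinates, coordinates)


def build_prim_mst(
    points: PointSet | np.ndarray,
    root: int = 0,
    *,
    distances: np.ndarray | None = None,
) -> MstResult:
    """Exact Euclidean MST by Prim's algorithm.

    Edges are returned in the order Prim attached them, each recording the
    in-tree endpoint as the parent ``a`` and the newly added point as the
    child ``b``.  When several candidate edges share the minimal weight the
    smallest candidate index wins, making the sequence deterministic.

    Parameters
    ----------
    points
        A :class:`PointSet` or a raw ``(N, n)`` array, ``N >= 2``.
    root
        Index of the starting point.
    distances
        Optional precomputed ``N x N`` distance matrix (reused by the
        detection loop to avoid recomputing).
    """
    coords = points.coordinates if isinstance(points, PointSet) else np.asarray(points, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("Prim's MST needs at least 2 points")
    if not 0 <= root < n:
        raise ValueError(f"root {root} out of range [0, {n})")

    dist = pairwise_distances(coords) if distances is None else distances
    in_tree = np.zeros(n, dtype=bool)
    in_tree[root] = True
    best = dist[root].copy()
    parent = np.full(n, root, dtype=int)
    best[root] = np.inf

    edges: list[Edge] = []
    for _ in range(n - 1):
        child = int(np.argmin(best))  # ties -> smallest index
        edges.append(Edge(int(parent[child]), child, float(best[child])))
        in_tree[child] = True
        best[child] = np.inf
        improved = (~in_tree) & (dist[child] < best)
        best[improved] = dist[child][improved]
        parent[improved] = child
    return MstResult(edges=edges, root=root)


def sort_edges_nondecreasing(mst: MstResult | list[Edge]) -> list[Edge]:
    """Edges sorted by non-decreasing weight; stable for equal weights."""
    edges = mst.edges if isinstance(mst, MstResult) else list(mst)
    return sorted(edges, key=lambda e: e.weight)
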