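"""The adaptive mini-MST outlier detection (MMOD) procedure.

The method needs no outlier count or contamination fraction.  It works in
two stages:

1. A global Prim MST over the whole dataset yields a *termination
   threshold* ``T_t = mean + spread`` of its edge weights.  Dividing every
   Euclidean distance by ``T_t`` gives the *threshold-scaled distance*
   (ted), a scale-free weight that makes clusters of very different
   densities comparable.

2. The MST edges, sorted by non-decreasing weight, seed small Prim-style
   trees ("mini-MSTs") grown with ted weights over the not-yet-labeled
   points.  Each tree keeps a running record (MEW) of the ted weights it
   accepted; a candidate whose ted exceeds the *adaptive exit condition*
   ``aec = mean + spread`` of the current MEW terminates the tree.  Trees
   with at least ``least_number`` edges become normal clusters; smaller
   trees are outlier clusters.  A sliding window over the sorted global
   edge weights stops the whole loop once the window mean exceeds ``T_t``;
   every point never absorbed by an accepted tree is an outlier.

The ``spread`` term is the population standard deviation by default.  The
printed form of the defining equations reads as a raw sum of squared
deviations (dimensionally a squared distance); that literal reading is
retained as ``deviation_mode="sum_squares"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mst import (
    TED,
    Edge,
    PointSet,
    build_prim_mst,
    pairwise_distances,
    sort_edges_nondecreasing,
)

__all__ = [
    "MmodConfig",
    "MiniMst",
    "DetectionResult",
    "termination_threshold",
    "threshold_scaled_distance",
    "adaptive_exit_condition",
    "compute_least_number",
    "grow_mini_mst",
    "detect",
]


@dataclass
class MmodConfig:
    """Every tunable the method leaves open.

    Parameters
    ----------
    deviation_mode : {"std", "sum_squares"}
        Spread term of both the termination threshold and the adaptive
        exit condition.  ``"std"`` (default) is the population standard
        deviation; ``"sum_squares"`` is the literal raw sum of squared
        deviations.
    mew1_policy : {"first_edge", "fixed"}
        How the first entry of a mini-tree's edge-weight record (MEW) is
        initialized.  ``"first_edge"`` uses the ted weight of the tree's
        first edge.  ``"fixed"`` uses ``mew1_value``; 1.0 is the
        documented choice for continuous 2-D data, where the first-edge
        policy degenerates (see docs/methods.md).
    mew1_value : float
        The fixed MEW initial value; required > 0 when policy is "fixed".
    window_len : int
        Total edges in the stopping window, current edge included.
    least_number_override : int, optional
        Minimum cluster size (in edges).  Default ``None`` applies
        ``round(N / n)``.
    normalize : bool
        Per-feature min-max scaling to [0, 1] before detection.
    drop_duplicates : bool
        Collapse exactly duplicated rows before detection; duplicates
        inherit their representative's label.
    root : int or "random"
        Root of the global Prim MST; "random" draws from ``random_state``.
    size_rule : {"ge", "gt"}
        Whether a tree with exactly ``least_number`` edges counts as a
        normal cluster ("ge", default) or not ("gt").
    random_state : int, optional
        Seed used only when ``root="random"``.
    """

    deviation_mode: str = "std"
    mew1_policy: str = "first_edge"
    mew1_value: float = 1.0
    window_len: int = 6
    least_number_override: int | None = None
    normalize: bool = False
    drop_duplicates: bool = False
    root: int | str = 0
    size_rule: str = "ge"
    random_state: int | None = None

    def __post_init__(self) -> None:
        if self.deviation_mode not in ("std", "sum_squares"):
            raise ValueError(f"unknown deviation_mode {self.deviation_mode!r}")
        if self.mew1_policy not in ("first_edge", "fixed"):
            raise ValueError(f"unknown mew1_policy {self.mew1_policy!r}")
        if self.mew1_policy == "fixed" and not self.mew1_value > 0:
            raise ValueError("mew1_value must be > 0 with mew1_policy='fixed'")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.least_number_override is not None and self.least_number_override < 1:
            raise ValueError("least_number_override must be >= 1")
        if self.size_rule not in ("ge", "gt"):
            raise ValueError(f"unknown size_rule {self.size_rule!r}")


@dataclass
class MiniMst:
    """One mini-MST: a detected candidate cluster.

    ``mew`` holds the ted weight record (one entry per edge; the first
    entry may be the configured fixed value instead of the first edge's
    ted).  ``member_points`` are the absorbed point indices including the
    start point.
    """

    start: int
    edges: list[Edge]
    mew: list[float]
    member_points: list[int]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DetectionResult:
    """Full labeling plus the run's diagnostics.

    ``outlier_mask[i]`` is True iff point ``i`` was flagged;
    ``cluster_id[i]`` is the normal-cluster index, or -1 for outliers.
    """

    outlier_mask: np.ndarray
    cluster_id: np.ndarray
    t_t: float
    least_number: int
    mini_msts: list[MiniMst] = field(default_factory=list)

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.cluster_id[self.cluster_id >= 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def _spread(weights: np.ndarray, mode: str) -> float:
    if mode == "std":
        return float(weights.std())
    if mode == "sum_squares":
        return float(((weights - weights.mean()) ** 2).sum())
    raise ValueError(f"unknown deviation mode {mode!r}")


def termination_threshold(edge_weights: Sequence[float], mode: str = "std") -> float:
    """Global stopping threshold ``T_t``: mean + spread of MST edge weights."""
    w = np.asarray(edge_weights, dtype=float)
    if w.size == 0:
        raise ValueError("need at least one edge weight")
    return float(w.mean() + _spread(w, mode))


def threshold_scaled_distance(x1, x2, t_t: float) -> float:
    """Euclidean distance divided by ``T_t`` (the "ted" measure).

    A common positive scale factor, so the relative ordering of pairs is
    exactly the Euclidean ordering.
    """
    from .mst import euclidean_distance

    if not t_t > 0:
        raise ValueError(f"t_t must be positive, got {t_t}")
    return euclidean_distance(x1, x2) / t_t


def adaptive_exit_condition(mew: Sequence[float], mode: str = "std") -> float:
    """Exit statistic over the current MEW: mean + spread.

    With a single entry the spread term is zero, so the statistic equals
    that entry.
    """
    w = np.asarray(mew, dtype=float)
    if w.size == 0:
        raise ValueError("MEW is empty")
    return float(w.mean() + _spread(w, mode))


def compute_least_number(n_points: int, n_features: int) -> int:
    """Minimum normal-cluster size in edges: round(N / n), at least 1.

    Rounding is half-away-from-zero (spreadsheet ROUND), so 0.5 -> 1.
    """
    return max(1, int(math.floor(n_points / n_features + 0.5)))


def _grow(
    dist: np.ndarray,
    start: int,
    unlabeled: set[int],
    t_t: float,
    config: MmodConfig,
) -> MiniMst:
    """Prim-style growth over ``unlabeled`` using ted weights.

    The caller is responsible for moving the returned members out of
    ``unlabeled``.
    """
    candidates = sorted(unlabeled - {start})
    if not candidates:
        return MiniMst(start=start, edges=[], mew=[], member_points=[start])

    cand = np.array(candidates, dtype=int)
    ted = dist[start][cand] / t_t
    parent = np.full(cand.size, start, dtype=int)

    # Seed with the start point's nearest neighbor.
    j = int(np.argmin(ted))
    first = Edge(start, int(cand[j]), float(ted[j]), measure=TED)
    members = [start, first.b]
    edges = [first]
    mew = [config.mew1_value if config.mew1_policy == "fixed" else first.weight]

    alive = np.ones(cand.size, dtype=bool)
    alive[j] = False
    newer = dist[first.b][cand] / t_t
    improved = alive & (newer < ted)
    ted[improved] = newer[improved]
    parent[improved] = first.b

    while alive.any():
        k = int(np.argmin(np.where(alive, ted, np.inf)))
        # aec is evaluated on the MEW the candidate is about to enter.
        aec = adaptive_exit_condition(mew, config.deviation_mode)
        if ted[k] > aec:
            break
        r = int(cand[k])
        edges.append(Edge(int(parent[k]), r, float(ted[k]), measure=TED))
        members.append(r)
        mew.append(float(ted[k]))
        alive[k] = False
        newer = dist[r][cand] / t_t
        improved = alive & (newer < ted)
        ted[improved] = newer[improved]
        parent[improved] = r
    return MiniMst(start=start, edges=edges, mew=mew, member_points=members)


def grow_mini_mst(
    points: PointSet | np.ndarray,
    start: int,
    labeled: set[int],
    unlabeled: set[int],
    t_t: float,
    config: MmodConfig | None = None,
) -> MiniMst:
    """Grow one mini-MST from ``start`` over the unlabeled points.

    Growth terminates when the closest remaining candidate's ted weight
    exceeds the adaptive exit condition of the current MEW.  With fewer
    than two unlabeled points the degenerate single-point tree (no edges)
    is returned.
    """
    config = config or MmodConfig()
    if not t_t > 0:
        raise ValueError("t_t must be positive")
    if start in labeled or start not in unlabeled:
        raise ValueError(f"start point {start} is not unlabeled")
    coords = points.coordinates if isinstance(points, PointSet) else np.asarray(points, float)
    return _grow(pairwise_distances(coords), start, unlabeled, t_t, config)


def _preprocess(coords: np.ndarray, config: MmodConfig) -> tuple[np.ndarray, np.ndarray]:
    """Returns (working coordinates, inverse map original-row -> working-row)."""
    inverse = np.arange(coords.shape[0])
    if config.drop_duplicates:
        uniq, first_idx, inv = np.unique(coords, axis=0, return_index=True, return_inverse=True)
        # np.unique sorts rows; re-order to first occurrence so the root
        # index and tie-breaks stay tied to the input order.
        order = np.argsort(first_idx)
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        coords = uniq[order]
        inverse = rank[inv.ravel()]
    if config.normalize:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        coords = (coords - lo) / span
    return coords, inverse


def detect(points: PointSet | np.ndarray, config: MmodConfig | None = None) -> DetectionResult:
    """Run the full detection loop; no outlier count or fraction is taken.

    Steps: optional preprocessing; global Prim MST; edges sorted
    non-decreasingly; ``T_t`` and ``least_number``; then the sorted-edge
    iteration with the sliding-window stop.  Points never absorbed into an
    accepted cluster are outliers.
    """
    config = config or MmodConfig()
    coords = points.coordinates if isinstance(points, PointSet) else np.asarray(points, float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need an (N, n) matrix with N >= 2")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates contain missing or non-finite values")

    work, inverse = _preprocess(coords, config)
    n_pts, n_feat = work.shape

    if isinstance(config.root, str):
        if config.root != "random":
            raise ValueError(f"root must be an index or 'random', got {config.root!r}")
        root = int(np.random.default_rng(config.random_state).integers(n_pts))
    else:
        root = int(config.root)

    least = (
        config.least_number_override
        if config.least_number_override is not None
        else compute_least_number(n_pts, n_feat)
    )

    if n_pts < 2:
        # All rows were duplicates of one point: a single trivial cluster.
        return DetectionResult(
            outlier_mask=np.zeros(coords.shape[0], dtype=bool),
            cluster_id=np.zeros(coords.shape[0], dtype=int),
            t_t=0.0,
            least_number=least,
        )

    dist = pairwise_distances(work)
    mst = build_prim_mst(work, root=root, distances=dist)
    sorted_edges = sort_edges_nondecreasing(mst)
    weights = np.array([e.weight for e in sorted_edges])
    t_t = termination_threshold(weights, config.deviation_mode)

    cluster = np.full(n_pts, -1, dtype=int)
    if t_t == 0.0:
        # Every point coincides: one cluster, no outliers.
        cluster[:] = 0
        return DetectionResult(
            outlier_mask=np.zeros(coords.shape[0], dtype=bool),
            cluster_id=cluster[inverse],
            t_t=t_t,
            least_number=least,
        )

    labeled: set[int] = set()
    unlabeled: set[int] = set(range(n_pts))
    trees: list[MiniMst] = []
    next_id = 0
    size_ok = (lambda k: k >= least) if config.size_rule == "ge" else (lambda k: k > least)

    for i, edge in enumerate(sorted_edges):
        if edge.a in labeled or edge.b in labeled:
            continue
        # Stop once the local edge-weight level reaches the global
        # threshold; the paper stops on strictly greater, which matters
        # for exactly tied weights.
        if weights[i : i + config.window_len].mean() > t_t:
            break
        tree = _grow(dist, edge.b, unlabeled, t_t, config)
        trees.append(tree)
        for m in tree.member_points:
            labeled.add(m)
            unlabeled.discard(m)
        if size_ok(tree.n_edges):
            cluster[tree.member_points] = next_id
            next_id += 1
        # An undersized tree is an outlier cluster: members keep id -1
        # and stay removed from the unlabeled pool.

    out_cluster = cluster[inverse]
    return DetectionResult(
        outlier_mask=out_cluster < 0,
        cluster_id=out_cluster,
        t_t=t_t,
        least_number=least,
        mini_msts=trees,
    )
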