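"""Seeded generators for the structures the detector assumes.

The canonical scene ("fig1 preset") is several isotropic Gaussian clusters
of clearly different densities plus a handful of scattered far-away
outliers: the densest cluster has the shortest internal edges, so the
sorted global MST reaches it first.  Outlier candidates are drawn
uniformly over the data bounding box and rejected while they fall inside
any cluster's clearance zone (``clearance x spread`` around its center),
so every planted outlier is verifiably remote.

A second family of small 2-D morphologies (density contrast, three
clusters, ring, half-moons, lattice) stands in for hand-made demonstration
sets; their sizes and outlier counts are package conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mst import PointSet

__all__ = [
    "ClusterSpec",
    "ScenarioSpec",
    "make_scenario",
    "fig1_default",
    "make_appendix_like",
    "APPENDIX_NAMES",
]

APPENDIX_NAMES = ("two_densities", "three_clusters", "ring", "moons", "grid")

_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class ClusterSpec:
    """One isotropic Gaussian cluster: center, scale and point count."""

    center: tuple[float, ...]
    spread: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")
        if not self.spread > 0:
            raise ValueError("cluster spread must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """A full scene: clusters plus uniformly scattered remote outliers."""

    clusters: tuple[ClusterSpec, ...]
    n_outliers: int = 0
    clearance: float = 5.0
    dimension: int = 2
    seed: int = 0
    box_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.clearance <= max(c.spread for c in self.clusters):
            raise ValueError("outlier clearance must exceed the largest cluster spread")
        total = sum(c.count for c in self.clusters) + self.n_outliers
        if total < 2:
            raise ValueError("scenario must contain at least 2 points")


def make_scenario(spec: ScenarioSpec) -> PointSet:
    """Draw a scene; ``truth_labels`` mark the planted outliers.

    Cluster points come first (in spec order), outliers last.  Outlier
    candidates are rejected while within ``clearance x spread`` of any
    cluster center; exceeding the retry cap raises, which signals an
    infeasible spec rather than a silent partial scene.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for cl in spec.clusters:
        center = np.asarray(cl.center, dtype=float)
        if center.shape != (spec.dimension,):
            raise ValueError("cluster center dimension does not match scenario dimension")
        blocks.append(rng.normal(center, cl.spread, size=(cl.count, spec.dimension)))
    cluster_points = np.vstack(blocks)

    outliers = []
    if spec.n_outliers:
        lo = cluster_points.min(axis=0) - spec.box_margin
        hi = cluster_points.max(axis=0) + spec.box_margin
        centers = [np.asarray(c.center, float) for c in spec.clusters]
        spreads = [c.spread for c in spec.clusters]
        tries = 0
        while len(outliers) < spec.n_outliers:
            tries += 1
            if tries > _REJECTION_CAP:
                raise RuntimeError(
                    "outlier rejection sampling exceeded the retry cap; spec is infeasible"
                )
            cand = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(cand - c) >= spec.clearance * s
                for c, s in zip(centers, spreads)
            ):
                outliers.append(cand)

    coords = np.vstack([cluster_points] + ([np.array(outliers)] if outliers else []))
    labels = np.concatenate(
        [np.zeros(len(cluster_points), dtype=int), np.ones(len(outliers), dtype=int)]
    )
    return PointSet(coordinates=coords, truth_labels=labels)


def fig1_default(seed: int = 0) -> ScenarioSpec:
    """The canonical four-cluster scene: 121 points, 6 planted outliers.

    Clusters of 40/30/25/20 points with spreads 0.5/1/1.5/2 sit at the
    corners of a 40-unit square (centers >= 20x the largest spread apart);
    6 outliers are scattered with clearance 5.
    """
    side = 40.0
    centers = [(0.0, 0.0), (side, 0.0), (0.0, side), (side, side)]
    counts = (40, 30, 25, 20)
    spreads = (0.5, 1.0, 1.5, 2.0)
    clusters = tuple(
        ClusterSpec(center=c, spread=s, count=k)
        for c, s, k in zip(centers, spreads, counts)
    )
    return ScenarioSpec(clusters=clusters, n_outliers=6, clearance=5.0, dimension=2, seed=seed)


def _plant_uniform_outliers(rng, cluster_points, centers, spreads, n_out, clearance, margin=5.0):
    lo = cluster_points.min(axis=0) - margin
    hi = cluster_points.max(axis=0) + margin
    outs = []
    tries = 0
    while len(outs) < n_out:
        tries += 1
        if tries > _REJECTION_CAP:
            raise RuntimeError("outlier rejection sampling exceeded the retry cap")
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= clearance * s for c, s in zip(centers, spreads)):
            outs.append(cand)
    return np.array(outs)


def make_appendix_like(name: str, seed: int = 0) -> PointSet:
    """A named 2-D morphology with 3-10 planted outliers.

    ``two_densities``
        Two offset Gaussian clusters with a strong density contrast
        (their mean nearest-neighbor distances differ by >= 3x).
    ``three_clusters``
        Three well-separated Gaussian clusters.
    ``ring``
        An annulus of roughly constant width.
    ``moons``
        Two interleaved half-moons (scikit-learn's generator).
    ``grid``
        An exact unit lattice — the fully homogeneous case.
    """
    rng = np.random.default_rng(seed)
    if name == "two_densities":
        dense = rng.normal((0.0, 0.0), 0.5, size=(80, 2))
        sparse = rng.normal((20.0, 0.0), 2.0, size=(40, 2))
        pts = np.vstack([dense, sparse])
        outs = _plant_uniform_outliers(
            rng, pts, [(0, 0), (20, 0)], [0.5, 2.0], n_out=5, clearance=5.0
        )
    elif name == "three_clusters":
        centers = [(0.0, 0.0), (25.0, 0.0), (12.0, 22.0)]
        spreads = [1.0, 1.5, 1.0]
        counts = [40, 35, 30]
        pts = np.vstack(
            [rng.normal(c, s, size=(k, 2)) for c, s, k in zip(centers, spreads, counts)]
        )
        outs = _plant_uniform_outliers(rng, pts, centers, spreads, n_out=6, clearance=5.0)
    elif name == "ring":
        theta = rng.uniform(0, 2 * np.pi, size=120)
        radius = rng.uniform(9.0, 11.0, size=120)
        pts = np.c_[radius * np.cos(theta), radius * np.sin(theta)]
        # clearance zone centred on the ring centre must cover the hole and
        # the annulus; candidates beyond it are genuinely remote.
        outs = _plant_uniform_outliers(
            rng, pts, [(0.0, 0.0)], [1.0], n_out=4, clearance=16.0, margin=15.0
        )
    elif name == "moons":
        from sklearn.datasets import make_moons

        pts, _ = make_moons(n_samples=120, noise=0.05, random_state=seed)
        pts = pts * 10.0
        outs = _plant_uniform_outliers(
            rng, pts, [(5.0, 2.5)], [1.0], n_out=5, clearance=20.0, margin=15.0
        )
    elif name == "grid":
        g = np.stack(np.meshgrid(np.arange(10.0), np.arange(10.0)), axis=-1).reshape(-1, 2)
        pts = g
        outs = _plant_uniform_outliers(
            rng, pts, [(4.5, 4.5)], [1.0], n_out=4, clearance=12.0, margin=10.0
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose one of {APPENDIX_NAMES}")

    coords = np.vstack([pts, outs])
    labels = np.concatenate([np.zeros(len(pts), int), np.ones(len(outs), int)])
    return PointSet(coordinates=coords, truth_labels=labels)
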