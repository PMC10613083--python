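"""Thresholds, mini-MST growth and the full detection loop."""

import inspect

import numpy as np
import pytest

from minimst import (
    MmodConfig,
    adaptive_exit_condition,
    compute_least_number,
    detect,
    grow_mini_mst,
    termination_threshold,
    threshold_scaled_distance,
)
from minimst.synthetic import fig1_default, make_scenario

from conftest import SCENE_2D, unit_lattice


# ---------------------------------------------------------------- thresholds

@pytest.mark.parametrize(
    "weights, mode, expected",
    [
        ([1, 1, 1], "std", 1.0),
        ([1, 1, 1], "sum_squares", 1.0),
        ([1, 3], "std", 3.0),          # mean 2 + population std 1
        ([1, 3], "sum_squares", 4.0),  # mean 2 + (1-2)^2 + (3-2)^2
    ],
)
def test_termination_threshold_hand_computed(weights, mode, expected):
    assert termination_threshold(weights, mode) == pytest.approx(expected)


def test_termination_threshold_empty_input():
    with pytest.raises(ValueError):
        termination_threshold([])


def test_threshold_scaled_distance_examples():
    assert threshold_scaled_distance([0, 0], [3, 4], 2.5) == pytest.approx(2.0)
    assert threshold_scaled_distance([7, 7], [7, 7], 3.0) == 0.0
    with pytest.raises(ValueError):
        threshold_scaled_distance([0], [1], 0.0)


def test_threshold_scaling_preserves_pair_ordering():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a, b, c = rng.normal(size=(3, 4))
        t_t = float(rng.uniform(0.1, 10))
        pairs = [(a, b), (a, c), (b, c)]
        eu = [np.linalg.norm(p - q) for p, q in pairs]
        ted = [threshold_scaled_distance(p, q, t_t) for p, q in pairs]
        assert np.argsort(eu).tolist() == np.argsort(ted).tolist()


@pytest.mark.parametrize(
    "mew, mode, expected",
    [
        ([0.4], "std", 0.4),
        ([0.4], "sum_squares", 0.4),
        ([1, 1, 1, 1], "std", 1.0),
        ([0.2, 0.4], "std", 0.4),  # mean 0.3 + population std 0.1
    ],
)
def test_adaptive_exit_condition_hand_computed(mew, mode, expected):
    assert adaptive_exit_condition(mew, mode) == pytest.approx(expected)


def test_adaptive_exit_condition_empty():
    with pytest.raises(ValueError):
        adaptive_exit_condition([])


@pytest.mark.parametrize(
    "n_points, n_features, expected",
    [
        (270, 13, 21),    # round(20.769)
        (4601, 57, 81),   # round(80.72)
        (10, 20, 1),      # floored at 1
        (121, 2, 61),     # half rounds away from zero
        (195, 22, 9),
    ],
)
def test_compute_least_number(n_points, n_features, expected):
    assert compute_least_number(n_points, n_features) == expected


# ------------------------------------------------------------------- growth

def test_grow_stops_before_far_point():
    # A tight pair far from everything: the tree keeps its single edge.
    coords = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.5, 0.0]])
    tree = grow_mini_mst(coords, 0, set(), {0, 1, 2, 3}, t_t=1.0)
    assert tree.n_edges == 1
    assert sorted(tree.member_points) == [0, 1]
    assert len(tree.mew) == 1


def test_grow_absorbs_uniform_chain():
    # Equal spacing: aec equals every candidate weight, and ties absorb.
    coords = np.arange(8.0).reshape(-1, 1)
    tree = grow_mini_mst(coords, 0, set(), set(range(8)), t_t=2.0)
    assert sorted(tree.member_points) == list(range(8))
    assert tree.n_edges == 7
    assert len(tree.mew) == tree.n_edges


def test_grow_recovers_densest_cluster(fig1_points):
    # Start in the densest cluster (points 0..39) with well-separated
    # clusters: the mini-MST absorbs exactly that cluster.
    coords = fig1_points.coordinates
    from minimst.mst import build_prim_mst, sort_edges_nondecreasing

    mst = build_prim_mst(coords)
    first = sort_edges_nondecreasing(mst)[0]
    t_t = termination_threshold([e.weight for e in mst.edges])
    config = MmodConfig(mew1_policy="fixed", mew1_value=1.0)
    tree = grow_mini_mst(coords, first.b, set(), set(range(len(coords))), t_t, config)
    assert sorted(tree.member_points) == list(range(40))


def test_grow_rejects_labeled_start():
    coords = np.zeros((3, 2))
    with pytest.raises(ValueError):
        grow_mini_mst(coords, 0, {0}, {1, 2}, t_t=1.0)


def test_grow_degenerate_single_point():
    coords = np.array([[0.0], [5.0]])
    tree = grow_mini_mst(coords, 1, {0}, {1}, t_t=1.0)
    assert tree.n_edges == 0 and tree.member_points == [1]


def test_mini_mst_bookkeeping_invariants(fig1_points):
    result = detect(fig1_points.coordinates, MmodConfig(mew1_policy="fixed", mew1_value=1.0))
    for tree in result.mini_msts:
        assert len(tree.mew) == tree.n_edges
        assert len(tree.member_points) == tree.n_edges + 1
        endpoints = {tree.start} | {e.a for e in tree.edges} | {e.b for e in tree.edges}
        assert endpoints == set(tree.member_points)
        assert all(e.measure == "ted" for e in tree.edges)


# ---------------------------------------------------------------- detection

def _scene_config(**kw):
    base = dict(
        mew1_policy="fixed",
        mew1_value=SCENE_2D["mew1"],
        least_number_override=SCENE_2D["least_number"],
    )
    base.update(kw)
    return MmodConfig(**base)


def test_detect_partitions_all_points(fig1_points):
    result = detect(fig1_points.coordinates, _scene_config())
    n = fig1_points.n_points
    assert result.outlier_mask.shape == (n,)
    assert np.array_equal(result.outlier_mask, result.cluster_id < 0)
    sizes = result.cluster_sizes()
    assert sum(sizes.values()) + result.n_outliers == n
    assert all(v >= result.least_number for v in sizes.values())


def test_detect_takes_no_outlier_count():
    # The no-prior-knowledge contract: neither the function nor its
    # configuration admits an outlier count or contamination fraction.
    assert list(inspect.signature(detect).parameters) == ["points", "config"]
    fields = set(MmodConfig.__dataclass_fields__)
    assert not {"contamination", "n_outliers", "outlier_fraction"} & fields


def test_detect_deterministic(fig1_points):
    a = detect(fig1_points.coordinates, _scene_config())
    b = detect(fig1_points.coordinates, _scene_config())
    assert np.array_equal(a.cluster_id, b.cluster_id)
    assert a.t_t == b.t_t


def test_detect_scale_invariant_labels(fig1_points):
    # ted = d / T_t is scale-free: labels are unchanged under coordinate
    # scaling while T_t itself scales linearly (std mode).
    base = detect(fig1_points.coordinates, _scene_config())
    for c in (0.1, 10.0):
        scaled = detect(fig1_points.coordinates * c, _scene_config())
        assert np.array_equal(scaled.cluster_id, base.cluster_id)
        assert scaled.t_t == pytest.approx(c * base.t_t, rel=1e-9)


def test_detect_single_homogeneous_cluster_has_no_outliers():
    result = detect(unit_lattice(7, 7))  # pure defaults
    assert result.n_outliers == 0
    assert len(result.cluster_sizes()) == 1


def test_detect_identical_points_single_cluster():
    result = detect(np.zeros((6, 3)))
    assert result.n_outliers == 0
    assert np.array_equal(result.cluster_id, np.zeros(6, dtype=int))


def test_detect_flags_exactly_the_far_point():
    # One compact cluster plus a point at 100x the cluster diameter.
    cluster = unit_lattice(5, 6)
    diameter = np.sqrt(4**2 + 5**2)
    coords = np.vstack([cluster, [[100 * diameter, 0.0]]])
    result = detect(coords)  # pure defaults
    assert np.flatnonzero(result.outlier_mask).tolist() == [30]


def test_detect_far_point_ted_exceeds_every_aec():
    # Brute-force check of the far point's exclusion: its scaled distance
    # to every cluster point is larger than any adaptive exit value seen.
    cluster = unit_lattice(5, 6)
    far = np.array([[100 * np.sqrt(41), 0.0]])
    coords = np.vstack([cluster, far])
    result = detect(coords)
    far_ted = min(
        threshold_scaled_distance(far[0], p, result.t_t) for p in cluster
    )
    max_aec = max(
        adaptive_exit_condition(tree.mew[: k + 1])
        for tree in result.mini_msts
        for k in range(len(tree.mew))
    )
    assert far_ted > max_aec


@pytest.mark.parametrize("rows, cols", [(5, 6), (7, 7), (4, 10)])
def test_detect_monotone_safety_far_appendage(rows, cols):
    # On compact-cluster fixtures, appending a point farther than 10x the
    # largest pairwise distance never turns an existing outlier normal.
    # (On diffuse Gaussian scenes the inflated T_t can mask moderate
    # outliers — a known limitation, see docs/methods.md.)
    cluster = unit_lattice(rows, cols)
    diameter = np.sqrt((rows - 1) ** 2 + (cols - 1) ** 2)
    coords = np.vstack([cluster, [[100 * diameter, 0.0]]])
    base = detect(coords)
    flagged = np.flatnonzero(base.outlier_mask)
    assert flagged.tolist() == [rows * cols]
    max_pairwise = 100 * diameter + diameter
    appended = np.vstack([coords, [[0.0, -10 * max_pairwise]]])
    grown = detect(appended)
    assert np.all(grown.outlier_mask[:-1][base.outlier_mask])
    assert grown.outlier_mask[-1]


def test_detect_recall_on_planted_outliers(fig1_points):
    result = detect(fig1_points.coordinates, _scene_config())
    truth = fig1_points.truth_labels.astype(bool)
    assert result.outlier_mask[truth].all()


def test_detect_drop_duplicates_consistent_labels():
    rng = np.random.default_rng(0)
    base = np.vstack([unit_lattice(5, 6), [[500.0, 0.0]]])
    dup = np.vstack([base, base[3], base[30]])  # repeat a normal and the outlier
    result = detect(dup, MmodConfig(drop_duplicates=True))
    assert result.cluster_id[31] == result.cluster_id[3]
    assert result.outlier_mask[32] and result.outlier_mask[30]


def test_detect_normalize_rescales_each_feature():
    # A feature with a huge scale dominates raw distances; min-max
    # normalization restores the lattice + far point structure.
    cluster = unit_lattice(5, 6)
    coords = np.vstack([cluster, [[100 * np.sqrt(41), 0.0]]])
    coords[:, 1] *= 1e6
    result = detect(coords, MmodConfig(normalize=True))
    assert result.outlier_mask[30]


def test_detect_input_validation():
    with pytest.raises(ValueError):
        detect(np.ones((1, 2)))
    with pytest.raises(ValueError):
        detect(np.array([[1.0, np.nan], [0.0, 1.0]]))


def test_config_validation():
    with pytest.raises(ValueError):
        MmodConfig(deviation_mode="variance")
    with pytest.raises(ValueError):
        MmodConfig(window_len=0)
    with pytest.raises(ValueError):
        MmodConfig(mew1_policy="fixed", mew1_value=0.0)
    with pytest.raises(ValueError):
        MmodConfig(size_rule="lt")


def test_random_root_is_seeded(fig1_points):
    cfg = lambda: _scene_config(root="random", random_state=123)
    a = detect(fig1_points.coordinates, cfg())
    b = detect(fig1_points.coordinates, cfg())
    assert np.array_equal(a.cluster_id, b.cluster_id)
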