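"""Merging, noise filtering, segmentation, labeling, stratification, balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caveclass.blobs import Blob, MaskImage, PTRF_NEGATIVE, PTRF_POSITIVE
from caveclass import preprocess as pp


def _locs(points, cell="c1"):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {"x_nm": pts[:, 0], "y_nm": pts[:, 1], "z_nm": pts[:, 2],
         "cell_id": cell, "source_row": np.arange(len(pts))}
    )


# ---------------------------------------------------------------- merging

def test_merge_leaves_distant_points():
    pts = np.array([[0.0, 0, 0], [25.0, 0, 0]])
    out = pp.iterative_merge(pts, 20.0)
    assert np.array_equal(np.sort(out, axis=0), np.sort(pts, axis=0))


def test_merge_pair_to_midpoint():
    pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    out = pp.iterative_merge(pts, 20.0)
    assert out.shape == (1, 3)
    assert np.allclose(out[0], [5.0, 0, 0])


def test_merge_collinear_chain_converges_to_center():
    """x = 0, 15, 30 at radius 20: one component in the first pass, centroid 15."""
    pts = np.array([[0.0, 0, 0], [15.0, 0, 0], [30.0, 0, 0]])
    out = pp.iterative_merge(pts, 20.0)
    assert out.shape == (1, 3)
    assert np.allclose(out[0], [15.0, 0, 0])


def _brute_force_merge(points: np.ndarray, radius: float) -> np.ndarray:
    """Reference merge: O(n^2) union-find per iteration, same rule."""
    pts = points.copy()
    while len(pts) > 1:
        parent = list(range(len(pts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged_any = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) <= radius:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
                        merged_any = True
        if not merged_any:
            break
        roots = {}
        for i in range(len(pts)):
            roots.setdefault(find(i), []).append(i)
        pts = np.array([pts[idx].mean(axis=0) for idx in roots.values()])
    return pts


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_merge_matches_brute_force_union_find(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 300, size=(150, 3))
    ours = pp.iterative_merge(pts, 25.0)
    oracle = _brute_force_merge(pts, 25.0)
    assert ours.shape == oracle.shape
    order = np.lexsort(ours.T)
    order_o = np.lexsort(oracle.T)
    assert np.allclose(ours[order], oracle[order_o], atol=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_merge_idempotent_and_contractive(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 150, size=(40, 3))
    once = pp.iterative_merge(pts, 20.0)
    twice = pp.iterative_merge(once, 20.0)
    assert once.shape == twice.shape
    assert np.allclose(np.sort(once, axis=0), np.sort(twice, axis=0))
    assert 1 <= once.shape[0] <= pts.shape[0]
    # post-condition: all pairwise distances exceed the radius
    if once.shape[0] > 1:
        from scipy.spatial import distance_matrix

        dm = distance_matrix(once, once)
        np.fill_diagonal(dm, np.inf)
        assert dm.min() > 20.0


def test_merge_eventlist_keeps_cells_separate():
    a = _locs([[0, 0, 0], [10, 0, 0]], cell="c1")
    b = _locs([[5, 0, 0]], cell="c2")
    merged = pp.merge_eventlist(pd.concat([a, b], ignore_index=True), 20.0)
    assert sorted(merged["cell_id"]) == ["c1", "c2"]
    assert len(merged) == 2  # c1 pair merges; c2 single point untouched


# ---------------------------------------------------------------- noise filter

def test_filter_noise_empty_and_tiny_input():
    with pytest.warns(UserWarning):
        keep = pp.filter_noise(np.empty((0, 3)))
    assert keep.shape == (0,)
    with pytest.warns(UserWarning):
        keep = pp.filter_noise(np.array([[0.0, 0, 0]]))
    assert keep.tolist() == [True]


def test_filter_noise_separates_cluster_from_background():
    """100 points in a 50 nm ball + 100 uniform points in a 2000 nm cube:
    the ball survives, most of the background does not."""
    rng = np.random.default_rng(0)
    ball = rng.normal(1000.0, 50.0 / 3.0, size=(100, 3))
    bg = rng.uniform(0, 2000.0, size=(100, 3))
    pts = np.vstack([ball, bg])
    keep = pp.filter_noise(pts, pp.NoiseFilterConfig(neighbor_radius_nm=50.0, k=2.0))
    assert keep[:100].mean() >= 0.95
    assert (~keep[100:]).mean() >= 0.80


def test_filter_noise_csr_tail_bound():
    """Pure CSR input: retained fraction is bounded by the Poisson tail
    probability implied by k (within 3 binomial SEs)."""
    from scipy import stats

    rng = np.random.default_rng(1)
    n, side = 4000, 1000.0
    pts = rng.uniform(0, side, size=(n, 3))
    cfg = pp.NoiseFilterConfig(neighbor_radius_nm=50.0, k=2.0)
    keep = pp.filter_noise(pts, cfg, bbox_volume=side**3)
    lam = pp.csr_expected_neighbors(n, side**3, cfg.neighbor_radius_nm)
    tail = stats.poisson.sf(lam + cfg.k * np.sqrt(lam), lam)
    se = np.sqrt(tail * (1 - tail) / n)
    assert keep.mean() <= tail + 3 * se


# ---------------------------------------------------------------- segmentation

def test_segment_two_distant_clusters():
    rng = np.random.default_rng(2)
    c1 = rng.normal(0, 10, size=(10, 3))
    c2 = rng.normal(1000, 10, size=(10, 3))
    blobs = pp.segment_blobs(_locs(np.vstack([c1, c2])), 100.0)
    assert sorted(b.molecule_count for b in blobs) == [10, 10]


def test_segment_chain_is_one_blob():
    pts = np.array([[i * 50.0, 0, 0] for i in range(10)])
    blobs = pp.segment_blobs(_locs(pts), 80.0)
    assert len(blobs) == 1 and blobs[0].molecule_count == 10


def test_segment_partition_property_and_union_find_oracle():
    """200 random points: identical partition to an O(n^2) union-find."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 500, size=(200, 3))
    radius = 60.0
    blobs = pp.segment_blobs(_locs(pts), radius)
    # partition property: disjoint cover of all points
    assert sum(b.molecule_count for b in blobs) == 200
    stacked = np.vstack([b.points for b in blobs])
    assert np.allclose(np.sort(stacked, axis=0), np.sort(pts, axis=0))
    # brute-force union-find oracle
    parent = list(range(200))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(200):
        for j in range(i + 1, 200):
            if np.linalg.norm(pts[i] - pts[j]) <= radius:
                parent[find(i)] = find(j)
    oracle_groups = {}
    for i in range(200):
        oracle_groups.setdefault(find(i), set()).add(i)
    ours = {frozenset(map(int, np.flatnonzero(
        np.isin(pts[:, 0], b.points[:, 0])))) for b in blobs}
    oracle = {frozenset(g) for g in oracle_groups.values()}
    assert ours == oracle


def test_segment_blob_ids_deterministic():
    pts = np.array([[0.0, 0, 0], [1000.0, 0, 0], [2000.0, 0, 0]])
    blobs = pp.segment_blobs(_locs(pts), 100.0)
    assert [b.blob_id for b in blobs] == [f"blob_c1_{i:05d}" for i in range(3)]


# ---------------------------------------------------------------- labeling

def _square_mask(size=10, positive=None, pixel=20.0):
    px = np.zeros((size, size), dtype=np.uint8)
    if positive is not None:
        px[positive] = 1
    return MaskImage(px, pixel)


def test_label_empty_mask_all_negative():
    blobs = [Blob("b1", np.array([[50.0, 50.0, 0.0]]))]
    labeled = pp.label_with_mask(blobs, _square_mask(), 0.5)
    assert labeled[0].ptrf_status == PTRF_NEGATIVE


def test_label_all_inside_positive():
    mask = _square_mask(positive=(slice(0, 10), slice(0, 10)))
    blobs = [Blob("b1", np.array([[50.0, 50.0, 0.0], [60.0, 60.0, 0.0]]))]
    labeled = pp.label_with_mask(blobs, mask, 0.5)
    assert labeled[0].ptrf_status == PTRF_POSITIVE


def test_label_half_inside_boundary_inclusive():
    mask = _square_mask(positive=(slice(0, 10), slice(0, 5)))  # x < 100 nm positive
    pts = np.array([[50.0, 50.0, 0], [150.0, 50.0, 0]])  # exactly half inside
    labeled = pp.label_with_mask([Blob("b1", pts)], mask, 0.5)
    assert labeled[0].ptrf_status == PTRF_POSITIVE


def test_label_outside_raster_warns_negative():
    blobs = [Blob("b1", np.array([[1e6, 1e6, 0.0]]))]
    with pytest.warns(UserWarning, match="outside the mask raster"):
        labeled = pp.label_with_mask(blobs, _square_mask(), 0.5)
    assert labeled[0].ptrf_status == PTRF_NEGATIVE


def test_label_mask_free_cell_all_negative():
    blobs = [Blob("b1", np.random.default_rng(0).normal(size=(70, 3)))]
    labeled = pp.label_with_mask(blobs, None, 0.5)
    assert labeled[0].ptrf_status == PTRF_NEGATIVE


# ---------------------------------------------------------------- stratify / balance

def _blob_with(n, status, bid="b"):
    pts = np.random.default_rng(0).normal(size=(n, 3))
    return Blob(bid, pts, ptrf_status=status)


@pytest.mark.parametrize(
    "n,status,expected",
    [
        (60, PTRF_POSITIVE, "caveolae"),
        (59, PTRF_POSITIVE, "non-caveolae"),
        (500, PTRF_NEGATIVE, "non-caveolae"),
    ],
)
def test_stratify_threshold(n, status, expected):
    out = pp.stratify_classes([_blob_with(n, status)], 60)
    assert out[0].class_label == expected


def test_stratify_requires_ptrf_status():
    with pytest.raises(ValueError, match="ptrf_status"):
        pp.stratify_classes([Blob("b", np.zeros((1, 3)))])


def test_balance_downsamples_majority():
    rng = np.random.default_rng(4)
    pos = [Blob(f"p{i}", rng.normal(size=(70, 3)), ptrf_status=PTRF_POSITIVE)
           for i in range(9)]
    neg = [Blob(f"n{i}", rng.normal(size=(20, 3)), ptrf_status=PTRF_NEGATIVE)
           for i in range(245)]
    blobs = pp.stratify_classes(pos + neg, 60)
    balanced = pp.balance_dataset(blobs, seed=0)
    assert len(balanced) == 18
    assert sum(b.class_label == "caveolae" for b in balanced) == 9
    # geometry preserved bitwise
    by_id = {b.blob_id: b for b in blobs}
    for b in balanced:
        assert np.array_equal(b.points, by_id[b.blob_id].points)


def test_balance_already_balanced_is_permutation():
    rng = np.random.default_rng(5)
    blobs = pp.stratify_classes(
        [Blob(f"p{i}", rng.normal(size=(70, 3)), ptrf_status=PTRF_POSITIVE) for i in range(4)]
        + [Blob(f"n{i}", rng.normal(size=(10, 3)), ptrf_status=PTRF_NEGATIVE) for i in range(4)],
        60,
    )
    balanced = pp.balance_dataset(blobs, seed=1)
    assert sorted(b.blob_id for b in balanced) == sorted(b.blob_id for b in blobs)


def test_balance_draws_distinct_members_across_seeds():
    rng = np.random.default_rng(6)
    pos = [Blob(f"p{i}", rng.normal(size=(70, 3)), ptrf_status=PTRF_POSITIVE) for i in range(3)]
    neg = [Blob(f"n{i}", rng.normal(size=(10, 3)), ptrf_status=PTRF_NEGATIVE) for i in range(30)]
    blobs = pp.stratify_classes(pos + neg, 60)
    input_ids = {b.blob_id for b in blobs}
    for seed in range(100):
        kept = pp.balance_dataset(blobs, seed=seed)
        neg_ids = [b.blob_id for b in kept if b.class_label == "non-caveolae"]
        assert len(neg_ids) == len(set(neg_ids)) == 3
        assert set(neg_ids) <= input_ids


def test_balance_requires_both_classes():
    blobs = pp.stratify_classes([_blob_with(70, PTRF_POSITIVE)], 60)
    with pytest.raises(ValueError, match="both classes"):
        pp.balance_dataset(blobs)
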