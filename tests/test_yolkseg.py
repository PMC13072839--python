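"""Enhancement, K-means clustering and yolk extraction."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from ovograde import (
    ClusterResult,
    EnhancementParams,
    KMeansConfig,
    SegmentationError,
    ValidationError,
    enhance,
    iou,
    kmeans,
    kmeanspp_init,
    segment_whole_egg,
    segment_yolk,
    select_yolk_cluster,
    sse_curve,
)
from ovograde.yolkseg import contrast_stretch, hist_equalize
from ovograde.synthetic import SyntheticEggSpec, render_view


def exhaustive_min_sse(points, k):
    """Globally optimal SSE by enumerating every assignment (n <= 12)."""
    points = np.asarray(points, dtype=np.float64)
    best = np.inf
    best_assign = None
    for assign in itertools.product(range(k), repeat=len(points)):
        sse = 0.0
        for j in range(k):
            grp = points[[i for i, a in enumerate(assign) if a == j]]
            if len(grp):
                sse += ((grp - grp.mean(axis=0)) ** 2).sum()
        if sse < best:
            best, best_assign = sse, assign
    return best, np.asarray(best_assign)


class TestEnhance:
    def test_constant_image_passthrough(self):
        img = np.full((16, 16), 99, np.uint8)
        np.testing.assert_array_equal(enhance(img), img)

    def test_contrast_stretch_maps_levels_to_full_range(self):
        img = np.array([[50, 200]] * 8, np.uint8)
        out = contrast_stretch(img, 0.0)
        assert set(np.unique(out)) == {0, 255}

    def test_histogram_equalization_flattens_cdf(self):
        # heavily skewed intensities: output empirical CDF should be close
        # to uniform (Kolmogorov distance on the unit interval)
        rng = np.random.default_rng(0)
        img = np.clip(np.rint(255 * rng.beta(2.0, 5.0, size=(64, 64))), 0, 255).astype(np.uint8)
        out = hist_equalize(img, 64)
        sorted_vals = np.sort(out.ravel()) / 255.0
        uniform = (np.arange(sorted_vals.size) + 0.5) / sorted_vals.size
        assert np.abs(sorted_vals - uniform).max() < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            EnhancementParams(tail_saturation=0.6)
        with pytest.raises(ValidationError):
            EnhancementParams(histeq_bins=1)
        with pytest.raises(ValidationError):
            EnhancementParams(clahe_clip=0.0)


class TestKMeansPP:
    def test_k1_selects_one_of_the_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        centers = kmeanspp_init(pts, 1, np.random.default_rng(0))
        assert centers.shape == (1, 2)
        assert any(np.array_equal(centers[0], p) for p in pts)

    def test_distant_point_chosen_by_d2_weighting(self):
        pts = np.vstack([np.zeros((99, 2)), [[100.0, 100.0]]])
        hits = 0
        for seed in range(10):
            centers = kmeanspp_init(pts, 2, np.random.default_rng(seed))
            if np.array_equal(centers[0], [0.0, 0.0]):
                hits += 1
                # all remaining D^2 mass sits on the outlier
                assert np.array_equal(centers[1], [100.0, 100.0])
        assert hits > 0

    def test_same_seed_identical_centers(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3))
        c1 = kmeanspp_init(pts, 4, np.random.default_rng(7))
        c2 = kmeanspp_init(pts, 4, np.random.default_rng(7))
        np.testing.assert_array_equal(c1, c2)

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValidationError):
            kmeanspp_init(np.zeros((2, 2)), 3, np.random.default_rng(0))


class TestKMeans:
    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 2))
        res = kmeans(pts, KMeansConfig(k=1))
        np.testing.assert_allclose(res.centers[0], pts.mean(axis=0), atol=1e-9)
        assert res.sse == pytest.approx(((pts - pts.mean(0)) ** 2).sum(), rel=1e-12)

    def test_well_separated_triples_match_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [c + 0.1 * rng.normal(size=(3, 2)) for c in ([0, 0], [10, 0], [5, 9])]
        )
        res = kmeans(pts, KMeansConfig(k=3, seed=0))
        best_sse, best_assign = exhaustive_min_sse(pts, 3)
        assert res.sse == pytest.approx(best_sse, rel=1e-9)
        # same partition up to label permutation
        for grp in range(3):
            sel = best_assign == grp
            assert len(set(res.labels[sel])) == 1

    def test_sse_history_non_increasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 2)) * [3, 1]
        res = kmeans(pts, KMeansConfig(k=4, seed=1))
        hist = np.asarray(res.sse_history)
        assert (np.diff(hist) <= 1e-9 * hist[0]).all()

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(120, 2))
        r1 = kmeans(pts, KMeansConfig(k=3, seed=9))
        r2 = kmeans(pts, KMeansConfig(k=3, seed=9))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.centers, r2.centers)
        assert r1.sse == r2.sse and r1.iterations_run == r2.iterations_run

    def test_matches_sklearn_on_separated_blobs(self):
        from sklearn.cluster import KMeans as SkKMeans
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(6)
        pts = np.vstack(
            [c + 0.3 * rng.normal(size=(40, 2)) for c in ([0, 0], [8, 0], [4, 7])]
        )
        mine = kmeans(pts, KMeansConfig(k=3, seed=0))
        sk = SkKMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert adjusted_rand_score(mine.labels, sk.labels_) == 1.0
        assert mine.sse == pytest.approx(sk.inertia_, rel=1e-6)

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValidationError):
            kmeans(np.zeros((2, 2)), KMeansConfig(k=3))


class TestSseCurve:
    def test_three_blob_colors_elbow_at_k3(self):
        rng = np.random.default_rng(7)
        side = 20.0  # equilateral triangle of tight blobs
        centers = np.array(
            [[0, 0], [side, 0], [side / 2, side * np.sqrt(3) / 2]]
        )
        pts = np.vstack([c + 0.4 * rng.normal(size=(60, 2)) for c in centers])
        curve = sse_curve(pts, 5, KMeansConfig(seed=0))
        assert all(b <= a + 1e-9 for a, b in zip(curve, curve[1:]))
        improv = [1 - curve[i] / curve[i - 1] for i in range(1, len(curve))]
        # improv[i] is the relative drop moving to k = i+1
        assert np.argmax(improv) + 2 == 3
        assert improv[2] < 0.2 * improv[1]

    def test_kmax_one(self):
        pts = np.random.default_rng(8).normal(size=(10, 2))
        curve = sse_curve(pts, 1)
        assert len(curve) == 1


class TestSelectYolkCluster:
    def test_tie_prefers_darker_cluster(self):
        # interleaved clusters: both sit at mean distance 1.0 from the
        # centroid (column 1.5), so the darker one must win
        egg = np.ones((1, 4), np.uint8)
        gray = np.array([[10, 200, 10, 200]], np.uint8)
        labels = np.array([0, 1, 0, 1])
        cluster = ClusterResult(
            labels=labels, centers=np.zeros((2, 2)), sse=0.0, iterations_run=1
        )
        # both clusters have the same mean distance to the centroid
        assert select_yolk_cluster(cluster, egg, gray) == 0

    @pytest.mark.parametrize("offset", [(0.0, 0.0), (10.0, 6.0)])
    def test_phantom_yolk_cluster_is_truth(self, offset):
        spec = SyntheticEggSpec(yolk_area_fraction=0.4, yolk_offset=offset)
        img, egg_truth, yolk_truth = render_view(spec, 0)
        seg = segment_whole_egg(img)
        yolk = segment_yolk(img, seg)
        assert iou(yolk.mask, yolk_truth) > 0.9


class TestSegmentYolk:
    def test_noise_free_ratio_within_one_point(self, clean_spec, clean_view):
        img, egg_truth, yolk_truth = clean_view
        seg = segment_whole_egg(img)
        yolk = segment_yolk(img, seg)
        s_est = 100 * yolk.area_pixels / seg.area_pixels
        s_true = 100 * yolk_truth.sum() / egg_truth.sum()
        assert abs(s_est - s_true) <= 1.0

    def test_noisy_phantom_iou(self, noisy_spec):
        img, _, yolk_truth = render_view(noisy_spec, 90, np.random.default_rng(1))
        seg = segment_whole_egg(img)
        yolk = segment_yolk(img, seg)
        assert iou(yolk.mask, yolk_truth) >= 0.85

    def test_yolk_is_subset_of_egg(self, noisy_spec):
        img, _, _ = render_view(noisy_spec, 180, np.random.default_rng(2))
        seg = segment_whole_egg(img)
        yolk = segment_yolk(img, seg)
        assert not (yolk.mask.astype(bool) & ~seg.mask.astype(bool)).any()

    def test_empty_egg_mask_rejected(self, clean_view):
        img, _, _ = clean_view
        seg = segment_whole_egg(img)
        empty = replace(seg, mask=np.zeros_like(seg.mask))
        with pytest.raises(SegmentationError):
            segment_yolk(img, empty)

    def test_full_lab_feature_space_also_recovers_yolk(self, clean_view):
        img, _, yolk_truth = clean_view
        seg = segment_whole_egg(img)
        yolk = segment_yolk(img, seg, kcfg=KMeansConfig(feature_space="lab"))
        assert iou(yolk.mask, yolk_truth) > 0.85


class TestIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), np.uint8)
        a[2:5, 2:5] = 1
        b = np.zeros_like(a)
        b[6:9, 6:9] = 1
        assert iou(a, a) == 1.0
        assert iou(a, b) == 0.0

    def test_half_shifted_square(self):
        a = np.zeros((20, 20), np.uint8)
        b = np.zeros_like(a)
        a[0:10, 0:10] = 1
        b[0:10, 5:15] = 1
        assert iou(a, b) == pytest.approx(50 / 150)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4), np.uint8)
        assert iou(z, z) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError):
            iou(np.zeros((3, 3)), np.zeros((4, 4)))
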