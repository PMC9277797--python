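import numpy as np
import pytest

from conftest import make_blobs
from longbin.cluster import (
    DistanceHistogram,
    candidate_cluster,
    confident_cluster,
    cosine_distance,
    distance_histogram,
    find_peak_valley,
    run_clustering,
    select_seed,
    _unit_rows,
)


class TestCosineDistance:
    def test_identical_direction(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(a, 2 * a) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 5.0])) == pytest.approx(1.0)

    def test_opposite(self):
        a = np.array([1.0, -2.0])
        assert cosine_distance(a, -a) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))


class TestFindPeakValley:
    def test_interior_peak_then_valley(self):
        counts = np.array([2, 9, 6, 3, 8, 1])
        assert find_peak_valley(counts) == (1, 3)
        assert counts[3] / counts[1] == pytest.approx(3 / 9)

    def test_first_bin_can_be_the_peak(self):
        counts = np.array([10, 2, 7])
        assert find_peak_valley(counts) == (0, 1)
        assert counts[1] / counts[0] == pytest.approx(0.2)

    def test_monotone_histogram_is_undefined(self):
        assert find_peak_valley(np.array([1, 2, 3, 4, 5])) == (None, None)

    def test_trailing_end_counts_as_minimal(self):
        # strictly decreasing after the peak: the last bin is the first minimal
        assert find_peak_valley(np.array([1, 5, 3, 2])) == (1, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            find_peak_valley(np.array([]))


def brute_histogram(anchor, points, active, delta, n_bins=400):
    """Independent oracle: bin the explicit pairwise distance list."""
    counts = np.zeros(n_bins, dtype=int)
    a = points[anchor] / np.linalg.norm(points[anchor])
    for p in active:
        if p == anchor:
            continue
        b = points[p] / np.linalg.norm(points[p])
        d = 1.0 - float(a @ b)
        j = min(max(int(d // delta), 0), n_bins - 1)
        counts[j] += 1
    return counts


class TestDistanceHistogram:
    def test_points_at_known_distance_land_in_one_bin(self):
        # construct points at cosine distance exactly 0.012 from the anchor
        rng = np.random.default_rng(0)
        a = np.zeros(8)
        a[0] = 1.0
        theta = np.arccos(1 - 0.012)
        pts = [a]
        for i in range(5):
            b = np.zeros(8)
            b[1 + i] = 1.0
            pts.append(np.cos(theta) * a + np.sin(theta) * b)
        pts = np.array(pts)
        hist = distance_histogram(0, pts, np.arange(6), delta=0.005)
        assert hist.counts[2] == 5  # floor(0.012 / 0.005) = 2
        assert hist.counts.sum() == 5

    def test_total_count_is_active_minus_one(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((40, 8))
        active = np.arange(40)
        hist = distance_histogram(3, pts, active, delta=0.005)
        assert hist.counts.sum() == 39

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            n = int(rng.integers(10, 100))
            pts = rng.standard_normal((n, 8))
            active = np.sort(rng.choice(n, size=max(2, n // 2), replace=False))
            anchor = int(active[0])
            hist = distance_histogram(anchor, pts, active, delta=0.005)
            np.testing.assert_array_equal(hist.counts, brute_histogram(anchor, pts, active, 0.005))

    def test_preconditions(self):
        pts = np.ones((3, 4))
        with pytest.raises(ValueError):
            distance_histogram(0, pts, [0], delta=0.005)
        with pytest.raises(ValueError):
            distance_histogram(2, pts, [0, 1], delta=0.005)


class TestCandidateCluster:
    def _hist(self, anchor, valley):
        return DistanceHistogram(counts=np.zeros(400, dtype=int), anchor=anchor, peak=0, valley=valley)

    def test_brute_force_radius_filter(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((60, 8))
        active = np.arange(60)
        unit = _unit_rows(pts)
        for valley in (3, 10, 40):
            got = candidate_cluster(self._hist(7, valley), pts, active, delta=0.005)
            radius = 0.005 * valley
            expect = {p for p in active if 1 - unit[p] @ unit[7] < radius} | {7}
            assert set(got.tolist()) == expect

    def test_shrinking_valley_never_grows_candidate(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((80, 8))
        active = np.arange(80)
        sizes = [
            len(candidate_cluster(self._hist(0, v), pts, active, delta=0.005)) for v in (40, 20, 10, 5, 1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_undefined_valley_rejected(self):
        hist = DistanceHistogram(counts=np.zeros(400, dtype=int), anchor=0, peak=None, valley=None)
        with pytest.raises(ValueError):
            candidate_cluster(hist, np.ones((3, 2)), np.arange(3), delta=0.005)


class TestSelectSeed:
    def test_dense_cluster_point_is_accepted(self):
        rng = np.random.default_rng(5)
        pts, _ = make_blobs([1000], spread=0.01, rng=rng)
        scatter = rng.standard_normal((5, 8))
        pts = np.vstack([pts, scatter])
        found = select_seed(pts, np.arange(len(pts)), 0.005, np.random.default_rng(0))
        assert found is not None
        seed, hist = found
        assert seed < 1000  # inside the dense blob
        assert hist.ratio < 0.5

    def test_deterministic_under_fixed_rng(self):
        rng = np.random.default_rng(6)
        pts, _ = make_blobs([300, 300], spread=0.01, rng=rng)
        s1 = select_seed(pts, np.arange(len(pts)), 0.005, np.random.default_rng(9))
        s2 = select_seed(pts, np.arange(len(pts)), 0.005, np.random.default_rng(9))
        assert s1[0] == s2[0]


class TestConfidentCluster:
    def test_single_blob_fully_recovered(self):
        rng = np.random.default_rng(7)
        pts, _ = make_blobs([500], spread=0.005, rng=rng)
        active = np.arange(500)
        found = select_seed(pts, active, 0.005, np.random.default_rng(1))
        cand = candidate_cluster(found[1], pts, active, 0.005)
        cluster, anchor, valley = confident_cluster(cand, pts, active, 0.005, np.random.default_rng(2), seed_index=found[0])
        assert len(cluster) >= 0.95 * 500

    def test_anchor_ratio_no_worse_than_seed(self):
        rng = np.random.default_rng(8)
        pts, _ = make_blobs([800], spread=0.01, rng=rng)
        active = np.arange(800)
        unit = _unit_rows(pts)
        seed, seed_hist = select_seed(pts, active, 0.005, np.random.default_rng(3), unit=unit)
        cand = candidate_cluster(seed_hist, pts, active, 0.005, unit=unit)
        _, anchor, _ = confident_cluster(cand, pts, active, 0.005, np.random.default_rng(4), seed_index=seed, unit=unit)
        anchor_hist = distance_histogram(anchor, pts, active, 0.005, unit=unit)
        assert anchor_hist.ratio <= seed_hist.ratio


class TestRunClustering:
    def test_three_balanced_blobs(self):
        rng = np.random.default_rng(9)
        pts, labels = make_blobs([8000, 6000, 7000], spread=0.01, rng=rng)
        res = run_clustering(pts, min_cluster_size=5000, rng_seed=0)
        assert len(res.clusters) == 3
        for cl in res.clusters:
            majority = np.bincount(labels[cl]).max()
            assert majority / len(cl) >= 0.95

    def test_disjoint_cover_partition(self):
        rng = np.random.default_rng(10)
        pts, _ = make_blobs([2000, 1500], spread=0.01, rng=rng)
        res = run_clustering(pts, min_cluster_size=100, rng_seed=1)
        all_idx = np.concatenate(res.clusters + [res.unclustered])
        assert len(all_idx) == len(pts)
        assert len(np.unique(all_idx)) == len(pts)

    def test_varying_sizes_both_recovered(self):
        rng = np.random.default_rng(11)
        pts, labels = make_blobs([500, 50000], spread=0.01, rng=rng)
        res = run_clustering(pts, min_cluster_size=100, rng_seed=2)
        majorities = [np.bincount(labels[cl]).argmax() for cl in res.clusters]
        assert set(majorities) == {0, 1}
        for cl in res.clusters:
            assert np.bincount(labels[cl]).max() / len(cl) >= 0.95

    def test_min_cluster_size_above_n_means_no_clusters(self):
        rng = np.random.default_rng(12)
        pts, _ = make_blobs([50], spread=0.01, rng=rng)
        res = run_clustering(pts, min_cluster_size=100, rng_seed=3)
        assert res.clusters == []
        assert len(res.unclustered) == 50

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        pts, _ = make_blobs([1000, 800], spread=0.01, rng=rng)
        r1 = run_clustering(pts, min_cluster_size=100, rng_seed=7)
        r2 = run_clustering(pts, min_cluster_size=100, rng_seed=7)
        assert len(r1.clusters) == len(r2.clusters)
        for a, b in zip(r1.clusters, r2.clusters):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(r1.unclustered, r2.unclustered)

    def test_zero_latent_vector_does_not_crash(self):
        rng = np.random.default_rng(14)
        pts, _ = make_blobs([300], spread=0.01, rng=rng)
        pts[0] = 0.0
        res = run_clustering(pts, min_cluster_size=10, rng_seed=4)
        assert res.n_points == 300
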