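"""Cloud clustering, semantics, bounding boxes, and tag calibration."""

import numpy as np
import pytest

from paniclekit.cloud import (
    ClusteredCloud,
    assign_semantics,
    calibrate,
    dbscan,
    drop_small_clusters,
    label_length,
    oriented_bounding_box,
    planarity_score,
)
from paniclekit.synthetic import SceneSpec, make_scene_cloud

from conftest import random_rotation, tube_cloud


def _brute_force_dbscan(points, eps, min_pts):
    """O(N^2) density-reachability DBSCAN with index-order expansion."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cid
                if core[j]:
                    queue.extend(neighbors[j])
        cid += 1
    return labels


class TestDbscan:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.3, (60, 3))
        b = rng.normal(0, 0.3, (60, 3)) + [10, 0, 0]
        out = dbscan(np.vstack([a, b]), eps=1.5, min_pts=5)
        assert out.n_clusters == 2
        assert not (out.cluster_id == -1).any()

    def test_sparse_points_all_noise(self, rng):
        pts = rng.uniform(0, 100, (50, 3))
        out = dbscan(pts, eps=0.5, min_pts=5)
        assert out.n_clusters == 0
        assert (out.cluster_id == -1).all()

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(20, 301))
        k = int(rng.integers(1, 6))
        pts = np.vstack([rng.normal(rng.uniform(-5, 5, 3), rng.uniform(0.2, 1.0),
                                    (n // k, 3)) for _ in range(k)])
        eps = float(rng.uniform(0.3, 1.5))
        min_pts = int(rng.integers(2, 10))
        got = dbscan(pts, eps=eps, min_pts=min_pts).cluster_id
        expected = _brute_force_dbscan(pts, eps, min_pts)
        # identical partition: same noise set and same label grouping
        assert np.array_equal(got == -1, expected == -1)
        for cid in np.unique(expected[expected >= 0]):
            members = got[expected == cid]
            assert len(np.unique(members)) == 1

    def test_non_finite_rejected(self):
        pts = np.array([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            dbscan(pts, eps=1.0, min_pts=2)


class TestDropSmallClusters:
    def _cloud(self, sizes):
        points = []
        ids = []
        for cid, s in enumerate(sizes):
            points.append(np.full((s, 3), float(cid) * 10))
            ids.extend([cid] * s)
        return ClusteredCloud(points=np.vstack(points), cluster_id=ids)

    def test_small_cluster_removed(self):
        out = drop_small_clusters(self._cloud([500, 80]), min_size=100)
        assert out.n_clusters == 1

    def test_boundary_inclusive(self):
        out = drop_small_clusters(self._cloud([120, 100, 99]), min_size=100)
        assert out.n_clusters == 2

    def test_min_size_one_identity(self):
        cloud = self._cloud([5, 3])
        out = drop_small_clusters(cloud, min_size=1)
        assert np.array_equal(out.cluster_id, cloud.cluster_id)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            drop_small_clusters(self._cloud([5, 3]), min_size=50)


class TestPlanarity:
    def test_exact_plane_scores_one(self, rng):
        pts = np.column_stack([rng.uniform(0, 3, 500), rng.uniform(0, 1, 500),
                               np.zeros(500)])
        assert planarity_score(pts) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_blob_scores_low(self):
        rng = np.random.default_rng(11)
        assert planarity_score(rng.normal(0, 1, (2000, 3))) < 0.2

    @pytest.mark.parametrize("seed", range(20))
    def test_plane_beats_tube(self, seed):
        rng = np.random.default_rng(seed)
        plane = np.column_stack([rng.uniform(0, 3, 800),
                                 rng.uniform(0, 1, 800),
                                 rng.normal(0, 0.01, 800)])
        tube = tube_cloud(lambda t: np.array([t, 0.2 * t ** 2, 0.0]),
                          (0, 5), 0.3, 800, rng, noise_sd=0.01)
        assert planarity_score(plane) > planarity_score(tube)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50),
                               np.zeros(50)])
        with pytest.raises(ValueError, match="collinear"):
            planarity_score(pts)


class TestAssignSemantics:
    def _scene_clusters(self, rng, n_tubes=1):
        parts = [np.column_stack([rng.uniform(0, 3, 800),
                                  rng.uniform(0, 1, 800),
                                  rng.normal(0, 0.005, 800)]) + [0, 20, 0]]
        for i in range(n_tubes):
            parts.append(tube_cloud(
                lambda t: np.array([t, 0.3 * np.sin(t), 0.0]), (0, 6),
                0.4, 1000, rng, noise_sd=0.01) + [0, -20 * i, 0])
        ids = np.concatenate([np.full(len(p), i) for i, p in enumerate(parts)])
        return ClusteredCloud(points=np.vstack(parts), cluster_id=ids)

    def test_plane_becomes_tag(self, rng):
        sem = assign_semantics(self._scene_clusters(rng))
        assert len(sem.tag_label) == 800
        assert len(sem.panicle) == 1000

    def test_three_clusters_one_tag(self, rng):
        sem = assign_semantics(self._scene_clusters(rng, n_tubes=2))
        assert len(sem.tag_label) == 800
        assert len(sem.panicle) == 2000

    def test_single_cluster_rejected(self, rng):
        cloud = ClusteredCloud(points=rng.normal(0, 1, (100, 3)),
                               cluster_id=np.zeros(100, int))
        with pytest.raises(ValueError, match="at least 2"):
            assign_semantics(cloud)


class TestOrientedBoundingBox:
    def _slab(self, rng, n=4000):
        return np.column_stack([rng.uniform(-1.5, 1.5, n),
                                rng.uniform(-0.5, 0.5, n),
                                rng.uniform(-0.01, 0.01, n)])

    def test_axis_aligned_extents(self, rng):
        box = oriented_bounding_box(self._slab(rng))
        assert box.extents[0] == pytest.approx(3.0, rel=0.01)
        assert box.extents[1] == pytest.approx(1.0, rel=0.01)
        assert box.extents[2] < 0.05

    def test_rotation_invariant_extents(self, rng):
        pts = self._slab(rng)
        rot = random_rotation(rng)
        a = oriented_bounding_box(pts).extents
        b = oriented_bounding_box(pts @ rot.T + [5, -2, 1]).extents
        assert np.allclose(a, b, rtol=0.01)

    def test_contains_all_points(self, rng):
        pts = self._slab(rng) @ random_rotation(rng).T
        box = oriented_bounding_box(pts)
        proj = np.abs((pts - box.center) @ box.axes.T)
        assert np.all(proj <= box.extents / 2 + 1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            oriented_bounding_box(np.zeros((2, 3)))


class TestLabelLength:
    def test_exact_rectangle(self):
        u, v = np.meshgrid(np.linspace(0, 3, 60), np.linspace(0, 1, 20))
        pts = np.column_stack([u.ravel(), v.ravel(), np.zeros(u.size)])
        assert label_length(pts) == pytest.approx(3.0, abs=1e-9)

    def test_noisy_rotated_rectangle(self, rng):
        u, v = np.meshgrid(np.linspace(0, 3, 80), np.linspace(0, 1, 30))
        pts = np.column_stack([u.ravel(), v.ravel(), np.zeros(u.size)])
        pts = pts + rng.normal(0, 0.01, pts.shape)
        pts = pts @ random_rotation(rng).T
        assert 2.94 <= label_length(pts) <= 3.06

    def test_square_tie(self, rng):
        u, v = np.meshgrid(np.linspace(0, 2, 50), np.linspace(0, 2, 50))
        pts = np.column_stack([u.ravel(), v.ravel(),
                               rng.normal(0, 0.005, u.size)])
        assert label_length(pts) == pytest.approx(2.0, rel=0.02)


class TestCalibrate:
    @pytest.mark.parametrize("x1,scale", [(3.0, 2.5), (7.5, 1.0)])
    def test_scale_ratio(self, x1, scale):
        calib = calibrate(x1)
        assert calib.scale == pytest.approx(scale)
        assert calib.normalization == pytest.approx(1.0 / x1)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            calibrate(0.0)

    @pytest.mark.parametrize("scene_scale", [0.25, 0.4, 1.0])
    def test_scene_recovery_within_2_percent(self, scene_scale):
        spec = SceneSpec(rng_seed=3, scene_scale=scene_scale,
                         n_panicle=40_000, n_label=8_000)
        pts, truth = make_scene_cloud(spec)
        label = pts[truth.semantic == 2]
        x1 = label_length(label)
        assert calibrate(x1).scale == pytest.approx(1.0 / scene_scale,
                                                    rel=0.02)
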