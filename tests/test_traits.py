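"""Skeletonization, main-path selection, curve length, and volume."""

import numpy as np
import pytest

from paniclekit.cloud import calibrate
from paniclekit.traits import (
    LBCParams,
    Skeleton,
    build_skeleton,
    curve_length,
    downsample,
    extend_path_to_cloud,
    extract_traits,
    lbc_contract,
    panicle_length,
    panicle_volume,
    select_main_path,
    voxel_count,
)

from conftest import tube_cloud


class TestDownsample:
    def test_single_leaf_collapses_to_centroid(self, rng):
        pts = rng.uniform(0, 0.5, (100, 3))
        out = downsample(pts, leaf=1.0)
        assert out.shape == (1, 3)
        assert np.allclose(out[0], pts.mean(axis=0))

    def test_fine_leaf_is_identity_up_to_order(self, rng):
        pts = rng.uniform(0, 10, (50, 3))
        out = downsample(pts, leaf=1e-4)
        assert len(out) == 50

    def test_lattice_occupancy(self):
        g = np.arange(10, dtype=float)
        pts = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        out = downsample(pts, leaf=2.0)
        assert len(out) == 125


class TestLbcContract:
    def test_line_is_fixed_point(self, rng):
        t = rng.uniform(0, 10, 200)
        pts = np.column_stack([t, 2 * t, -t])
        out = lbc_contract(pts)
        # points on a line stay on it: rank of centered cloud remains 1
        centered = out - out.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[1] < 1e-6 * s[0]

    def test_noisy_cylinder_contracts_to_axis(self, rng):
        pts = tube_cloud(lambda t: np.array([t, 0.0, 0.0]), (0, 10),
                         0.5, 3000, rng, noise_sd=0.01)
        out = lbc_contract(downsample(pts, 0.15))
        dist_to_axis = np.linalg.norm(out[:, 1:], axis=1)
        assert dist_to_axis.mean() < 0.2 * 0.5

    def test_variance_strictly_decreases(self, rng):
        pts = tube_cloud(lambda t: np.array([t, np.sin(t), 0.0]), (0, 8),
                         0.4, 1500, rng)
        out = lbc_contract(pts)
        assert out.var(axis=0).sum() < pts.var(axis=0).sum()

    def test_disconnected_blobs_rejected(self, rng):
        a = rng.normal(0, 0.1, (60, 3))
        b = rng.normal(0, 0.1, (60, 3)) + [100, 0, 0]
        with pytest.raises(ValueError, match="disconnected|fragmented"):
            lbc_contract(np.vstack([a, b]), LBCParams(k_neighbors=4))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            lbc_contract(np.zeros((10, 3)))


class TestBuildSkeleton:
    def test_arc_gives_path_graph(self, rng):
        t = np.sort(rng.uniform(0, np.pi, 500))
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        skel = build_skeleton(pts, node_spacing=0.15)
        assert len(skel.endpoints) == 2
        deg = np.zeros(len(skel.nodes), int)
        for a, b in skel.edges:
            deg[a] += 1
            deg[b] += 1
        assert np.all(deg[deg > 0] <= 2)

    def test_y_shape_has_three_endpoints(self, rng):
        t = np.linspace(0, 1, 300)
        arms = [np.column_stack([t, np.zeros_like(t), np.zeros_like(t)]),
                np.column_stack([-t, np.zeros_like(t), np.zeros_like(t)]),
                np.column_stack([np.zeros_like(t), t, np.zeros_like(t)])]
        pts = np.vstack(arms)
        skel = build_skeleton(pts, node_spacing=0.12)
        assert len(skel.endpoints) == 3
        deg = np.zeros(len(skel.nodes), int)
        for a, b in skel.edges:
            deg[a] += 1
            deg[b] += 1
        assert (deg == 3).sum() == 1

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            build_skeleton(np.zeros((5, 3)), node_spacing=10.0)


class TestSelectMainPath:
    def _skeleton_from_polyline(self, chains):
        """Build a Skeleton from explicit node chains sharing node 0 ids."""
        nodes = np.vstack([c for c in chains])
        edges = []
        offset = 0
        for c in chains:
            for i in range(len(c) - 1):
                edges.append((offset + i, offset + i + 1))
            offset += len(c)
        return Skeleton(nodes=nodes, edges=edges)

    def test_straight_line_whole_path(self):
        nodes = np.column_stack([np.linspace(0, 10, 11), np.zeros(11),
                                 np.zeros(11)])
        skel = Skeleton(nodes=nodes,
                        edges=[(i, i + 1) for i in range(10)])
        path = select_main_path(skel)
        assert path in ([*range(11)], [*range(10, -1, -1)])

    def test_sharp_spurs_rejected(self):
        # smooth arc plus two short spurs leaving at ~90 degrees
        t = np.linspace(0, np.pi / 2, 40)
        arc = np.column_stack([4 * np.cos(t), 4 * np.sin(t), np.zeros_like(t)])
        spur_dir = arc[10] / np.linalg.norm(arc[10])
        spur1 = arc[10] + np.outer(np.linspace(0.2, 1.2, 5), spur_dir)
        spur2 = arc[30] + np.outer(np.linspace(0.2, 1.2, 5),
                                   arc[30] / np.linalg.norm(arc[30]))
        nodes = np.vstack([arc, spur1, spur2])
        edges = [(i, i + 1) for i in range(39)]
        edges += [(10, 40)] + [(40 + i, 41 + i) for i in range(4)]
        edges += [(30, 45)] + [(45 + i, 46 + i) for i in range(4)]
        skel = Skeleton(nodes=nodes, edges=edges)
        path = select_main_path(skel, angle_limit=45.0)
        assert set(path) == set(range(40))  # the arc, no spur nodes

    def test_symmetric_star_falls_back(self, caplog):
        # three straight arms at 120 degrees: no admissible endpoint pair
        arms = []
        for k in range(3):
            ang = 2 * np.pi * k / 3
            d = np.array([np.cos(ang), np.sin(ang), 0.0])
            arms.append(np.outer(np.linspace(0.2, 2.0, 6), d))
        center = np.zeros((1, 3))
        nodes = np.vstack([center] + arms)
        edges = []
        for k in range(3):
            base = 1 + 6 * k
            edges.append((0, base))
            edges += [(base + i, base + i + 1) for i in range(5)]
        skel = Skeleton(nodes=nodes, edges=edges)
        import logging
        with caplog.at_level(logging.WARNING, logger="paniclekit.traits"):
            path = select_main_path(skel, angle_limit=35.0)
        assert "falling back" in caplog.text
        assert len(path) == 13  # two full arms plus the hub


class TestCurveLength:
    def test_straight_segment_exact(self):
        nodes = np.column_stack([np.linspace(0, 10, 9), np.zeros(9),
                                 np.zeros(9)])
        assert curve_length(nodes) == pytest.approx(10.0, abs=1e-3)

    def test_quarter_circle_within_one_percent(self):
        t = np.linspace(0, np.pi / 2, 12)
        nodes = np.column_stack([2 * np.cos(t), 2 * np.sin(t),
                                 np.zeros_like(t)])
        assert curve_length(nodes) == pytest.approx(np.pi, rel=0.01)

    def test_three_nodes_polyline_fallback(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert curve_length(nodes) == pytest.approx(2.0)

    def test_duplicate_nodes_deduplicated(self):
        nodes = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0],
                          [2, 0, 0], [3, 0, 0], [4, 0, 0]], dtype=float)
        assert curve_length(nodes) == pytest.approx(4.0, abs=1e-3)

    def test_length_at_least_endpoint_distance(self, rng):
        for _ in range(10):
            nodes = np.cumsum(rng.normal(0, 1, (8, 3)), axis=0)
            chord = np.linalg.norm(nodes[-1] - nodes[0])
            assert curve_length(nodes) >= chord - 1e-9


class TestExtendPath:
    def test_extends_to_cloud_tip(self, rng):
        cloud = tube_cloud(lambda t: np.array([t, 0.0, 0.0]), (0, 10),
                           0.3, 5000, rng)
        # a path whose ends stop 1 unit short of the data
        nodes = np.column_stack([np.linspace(1, 9, 9), np.zeros(9),
                                 np.zeros(9)])
        ext = extend_path_to_cloud(nodes, cloud, radius=0.5)
        assert ext[0, 0] < 0.15
        assert ext[-1, 0] > 9.85

    def test_max_extension_bounds_overshoot(self, rng):
        cloud = tube_cloud(lambda t: np.array([t, 0.0, 0.0]), (0, 10),
                           0.3, 3000, rng)
        far = np.array([[13.0, 0.0, 0.0]])  # stray structure past the tip
        nodes = np.column_stack([np.linspace(1, 9, 9), np.zeros(9),
                                 np.zeros(9)])
        ext = extend_path_to_cloud(nodes, np.vstack([cloud, far]),
                                   radius=0.5, max_extension=2.0)
        assert ext[-1, 0] < 11.01


class TestTraitFormulas:
    @pytest.mark.parametrize("l1,x1,expected", [
        (10.0, 5.0, 15.0),
        (7.5, 7.5, 7.5),   # the tag's own length maps to 7.5 cm
        (0.0, 3.0, 0.0),
    ])
    def test_length_scaling(self, l1, x1, expected):
        assert panicle_length(l1, calibrate(x1)) == pytest.approx(expected)

    def test_volume_worked_example(self):
        assert panicle_volume(1000) == pytest.approx(0.421875)

    def test_volume_zero(self):
        assert panicle_volume(0) == 0.0


class TestVoxelCount:
    def test_one_cell(self, rng):
        assert voxel_count(rng.uniform(0, 0.009, (50, 3))) == 1

    def test_two_separated_points(self):
        assert voxel_count(np.array([[0, 0, 0], [0.05, 0, 0]])) == 2

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 0.3, (500, 3))
        assert voxel_count(pts) == voxel_count(pts + 17.3)

    def test_monotone_under_addition(self, rng):
        pts = rng.uniform(0, 0.2, (300, 3))
        extra = rng.uniform(0, 0.4, (100, 3))
        assert voxel_count(np.vstack([pts, extra])) >= voxel_count(pts)

    def test_lattice_occupancy_exact(self):
        # pitch slightly above the voxel edge: one occupied cell per point
        g = np.arange(10) * 0.0103
        pts = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        assert voxel_count(pts) == 1000


class TestRigidAndScaleInvariance:
    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_traits_invariant_under_scene_rescale(self, rng, s):
        from paniclekit.synthetic import SceneSpec, make_scene_cloud
        spec = SceneSpec(rng_seed=5, n_panicle=60_000, n_label=8_000)
        pts, truth = make_scene_cloud(spec)
        pan = pts[truth.semantic == 1]
        x1 = truth.label_scene_length
        base = extract_traits(pan, calibrate(x1))
        scaled = extract_traits(pan * s, calibrate(x1 * s))
        assert scaled.length_cm == pytest.approx(base.length_cm, rel=0.01)
        assert scaled.volume_cm3 == pytest.approx(base.volume_cm3, rel=0.01)
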