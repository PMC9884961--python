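"""Ground-truth correctness of the synthetic vessel-tree generator."""

import networkx as nx
import numpy as np
import pytest

from retinakey.synth import (GrowthParams, InvalidParameterError, KeypointSet,
                             TransformSpec, VesselTree, apply_homography,
                             generate_sample, generate_tree, make_pair,
                             merge_close_points, overlap_fraction,
                             rasterize_and_annotate)


def overlap_by_pixel_loop(H, fixed_shape, moving_shape):
    """Brute-force per-pixel in-bounds count."""
    Hh, Ww = fixed_shape[:2]
    mh, mw = moving_shape[:2]
    inside = 0
    for y in range(Hh):
        for x in range(Ww):
            p = H @ np.array([x, y, 1.0])
            px, py = p[0] / p[2], p[1] / p[2]
            if 0 <= px <= mw - 1 and 0 <= py <= mh - 1:
                inside += 1
    return inside / (Hh * Ww)


class TestGenerateTree:
    def test_no_branching_limit_single_path(self):
        gp = GrowthParams(branch_prob=0.0, max_depth=5)
        tree = generate_tree(64, gp, seed=3)
        assert len(tree.branching_nodes()) == 0
        # a path: every node has degree <= 2
        assert tree.degrees().max() <= 2

    def test_same_seed_bitwise_identical(self):
        a = generate_tree(64, seed=11)
        b = generate_tree(64, seed=11)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        assert a.edges == b.edges

    def test_different_seed_differs(self):
        a = generate_tree(64, seed=1)
        b = generate_tree(64, seed=2)
        assert a.nodes.shape != b.nodes.shape or not np.allclose(a.nodes, b.nodes)

    def test_branching_count_matches_graph_traversal_oracle(self):
        gp = GrowthParams(branch_prob=1.0, max_depth=3,
                          segment_length_range=(4.0, 6.0))
        tree = generate_tree(64, gp, seed=7)
        g = nx.Graph()
        g.add_nodes_from(range(len(tree.nodes)))
        g.add_edges_from((a, b) for a, b, _ in tree.edges)
        oracle = sum(1 for n in g.nodes if g.degree[n] >= 3)
        assert len(tree.branching_nodes()) == oracle
        assert nx.is_forest(g)

    def test_tiny_canvas_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_tree(16, seed=0)

    def test_nodes_within_canvas(self):
        tree = generate_tree(64, seed=5)
        assert tree.nodes.min() >= -tree.edges[0][2] if tree.edges else True
        assert np.all(tree.nodes >= -2) and np.all(tree.nodes <= 65)


class TestRasterizeAndAnnotate:
    def test_single_tree_without_branching_has_no_keypoints(self):
        gp = GrowthParams(branch_prob=0.0)
        tree = generate_tree(64, gp, seed=3)
        img, kps = rasterize_and_annotate([tree], 64, seed=0)
        assert len(kps) == 0
        assert img.shape == (64, 64)
        assert img.min() >= 0 and img.max() <= 255

    def test_perpendicular_single_segments_cross_once(self):
        t1 = VesselTree(nodes=np.array([[10.0, 32.0], [54.0, 32.0]]),
                        edges=[(0, 1, 1.5)], tree_id=0)
        t2 = VesselTree(nodes=np.array([[32.0, 10.0], [32.0, 54.0]]),
                        edges=[(0, 1, 1.5)], tree_id=1)
        img, kps = rasterize_and_annotate([t1, t2], 64, seed=0)
        assert len(kps) == 1
        assert kps.labels == ["crossing"]
        np.testing.assert_allclose(kps.points[0], [32.0, 32.0], atol=0.5)

    def test_keypoints_are_dark_vessel_pixels(self):
        img, kps = rasterize_and_annotate(
            [generate_tree(64, seed=s, tree_id=s) for s in range(3)], 64, seed=1)
        for x, y in kps.points:
            r, c = int(round(y)), int(round(x))
            patch = img[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            assert patch.min() < np.median(img)  # junctions lie on dark strokes

    def test_minimum_separation_enforced(self):
        img, kps = rasterize_and_annotate(
            [generate_tree(96, seed=s, tree_id=s) for s in range(4)], 96, seed=2,
            min_separation=3.0)
        pts = kps.points
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.hypot(*(pts[i] - pts[j])) >= 3.0 - 1e-9

    def test_keypoint_count_against_junction_oracle(self):
        """Declared keypoints agree (within +-10%) with junctions counted by
        brute force over the geometry: degree->=3 nodes plus pairwise
        inter-tree segment intersections, deduplicated at the minimum
        separation by an independent clustering method."""
        from scipy.cluster.hierarchy import fcluster, linkage
        trees = [generate_tree(96, GrowthParams(branch_prob=0.6), seed=s,
                               tree_id=s) for s in range(3)]
        img, kps = rasterize_and_annotate(trees, 96, seed=0)
        raw = [t.nodes[i] for t in trees for i in t.branching_nodes()]
        for a in range(len(trees)):
            for b in range(a + 1, len(trees)):
                for (i1, j1, _) in trees[a].edges:
                    for (i2, j2, _) in trees[b].edges:
                        p1, p2 = trees[a].nodes[i1], trees[a].nodes[j1]
                        p3, p4 = trees[b].nodes[i2], trees[b].nodes[j2]
                        d1, d2 = p2 - p1, p4 - p3
                        den = d1[0] * d2[1] - d1[1] * d2[0]
                        if abs(den) < 1e-12:
                            continue
                        t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / den
                        u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / den
                        if 0 <= t <= 1 and 0 <= u <= 1:
                            raw.append(p1 + t * d1)
        raw = np.array(raw)
        clusters = fcluster(linkage(raw, method="single"), t=3.0,
                            criterion="distance")
        oracle = len(set(clusters))
        assert abs(len(kps) - oracle) <= max(0.1 * oracle, 2)


class TestMergeClosePoints:
    def test_merges_to_centroid_with_crossing_priority(self):
        pts, labs = merge_close_points(
            np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0]]),
            ["branching", "crossing", "branching"], min_separation=3.0)
        assert len(pts) == 2
        assert pts[0].tolist() == [1.0, 0.0]
        assert labs[0] == "crossing"


class TestMakePair:
    @pytest.fixture
    def scene(self):
        trees = [generate_tree(64, seed=s, tree_id=s) for s in range(3)]
        return rasterize_and_annotate(trees, 64, seed=4)

    def test_identity_no_perturbation_is_exact_copy(self, scene):
        img, kps = scene
        sample = make_pair(img, kps, TransformSpec(kind="identity"),
                           seed=0, perturb=False)
        np.testing.assert_allclose(sample.moving_image, img, atol=1e-8)
        assert len(sample.gt_matches) == len(kps)
        for i, j in sample.gt_matches:
            np.testing.assert_allclose(sample.moving_keypoints.points[j],
                                       kps.points[i], atol=1e-9)
        assert sample.overlap_fraction == 1.0

    def test_pure_translation_offsets_exactly(self, scene):
        img, kps = scene
        spec = TransformSpec(kind="translation", translation_frac=0.08)
        sample = make_pair(img, kps, spec, seed=5, perturb=False)
        H = sample.gt_transform
        tx, ty = H[0, 2], H[1, 2]
        assert (tx, ty) != (0, 0)
        for i, j in sample.gt_matches:
            np.testing.assert_allclose(
                sample.moving_keypoints.points[j],
                sample.fixed_keypoints.points[i] + [tx, ty], atol=1e-9)

    def test_homography_overlap_matches_pixel_oracle(self, scene):
        img, kps = scene
        sample = make_pair(img, kps, TransformSpec(kind="homography"), seed=9)
        oracle = overlap_by_pixel_loop(sample.gt_transform, img.shape,
                                       sample.moving_image.shape)
        assert sample.overlap_fraction == pytest.approx(oracle, abs=1e-12)

    def test_matches_consistent_with_gt_transform(self, scene):
        img, kps = scene
        sample = make_pair(img, kps, TransformSpec(kind="similarity"), seed=2)
        warped = apply_homography(sample.gt_transform,
                                  sample.fixed_keypoints.points)
        for i, j in sample.gt_matches:
            d = np.hypot(*(warped[i] - sample.moving_keypoints.points[j]))
            assert d < 0.5

    def test_inverse_round_trip_precision(self, scene):
        img, kps = scene
        sample = make_pair(img, kps, TransformSpec(kind="affine"), seed=3)
        H = sample.gt_transform
        back = apply_homography(np.linalg.inv(H),
                                apply_homography(H, kps.points))
        np.testing.assert_allclose(back, kps.points, atol=1e-6)

    def test_unknown_transform_kind_rejected(self, scene):
        img, kps = scene
        with pytest.raises(InvalidParameterError):
            make_pair(img, kps, TransformSpec(kind="rigid"), seed=0)


class TestGenerateSample:
    def test_reproducible_and_annotated(self):
        a = generate_sample(64, seed=42)
        b = generate_sample(64, seed=42)
        np.testing.assert_array_equal(a.fixed_image, b.fixed_image)
        np.testing.assert_array_equal(a.moving_image, b.moving_image)
        assert a.gt_matches == b.gt_matches
        assert len(a.gt_matches) >= 4
        assert 0.0 < a.overlap_fraction <= 1.0

    def test_low_quality_preset_injects_stronger_noise(self):
        """Rendering the same scene with the two presets (noise isolated by a
        shared seed) shows the configured additive-noise gap."""
        from dataclasses import replace
        from retinakey.synth import HIGH_QUALITY, LOW_QUALITY
        assert LOW_QUALITY.noise_sigma > HIGH_QUALITY.noise_sigma
        assert LOW_QUALITY.blur_sigma > HIGH_QUALITY.blur_sigma
        trees = [generate_tree(64, seed=s, tree_id=s) for s in range(2)]
        base = replace(HIGH_QUALITY, noise_sigma=0.0)
        noisy = replace(HIGH_QUALITY, noise_sigma=5.0)
        img0, _ = rasterize_and_annotate(trees, 64, base, seed=9)
        img5, _ = rasterize_and_annotate(trees, 64, noisy, seed=9)
        resid = np.std(img5 - img0)
        assert resid == pytest.approx(5.0, rel=0.25)  # clipping shaves a little

    def test_quality_tag_propagates(self):
        assert generate_sample(64, quality="low", seed=0).quality_tag == "low"
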