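"""Corner detection, ANMS, vesselness, skeleton and junction extraction."""

import numpy as np
import pytest

from thermoreg import (
    FeaturePoint,
    Image,
    anms,
    generate_scene,
    harris_corners,
    junction_barycenters,
    render_scene,
    skeleton_intersections,
    skeletonize,
    vessel_map,
)


def brute_force_anms_radii(points, c_robust):
    """Independent O(n^2) loop oracle for the suppression radii."""
    n = len(points)
    radii = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if c_robust * points[j].response > points[i].response:
                d = np.hypot(points[i].x - points[j].x, points[i].y - points[j].y)
                radii[i] = min(radii[i], d)
    return radii


class TestHarris:
    def test_constant_image_yields_no_corners(self):
        assert harris_corners(Image(np.full((64, 64), 0.5))) == []

    def test_square_vertices_found(self, square_image):
        pts = harris_corners(square_image, sigma=2.0)
        found = np.array([[p.x, p.y] for p in pts])
        for vx, vy in [(30, 30), (30, 65), (65, 30), (65, 65)]:
            d = np.hypot(found[:, 0] - vx, found[:, 1] - vy).min()
            assert d <= 2.0, f"vertex ({vx},{vy}) missed by {d:.1f} px"

    def test_checkerboard_interior_vertices_found(self):
        cell = 16
        tiles = np.indices((4, 4)).sum(axis=0) % 2
        px = np.kron(tiles, np.ones((cell, cell))).astype(float)
        pts = harris_corners(Image(px), sigma=1.5)
        found = np.array([[p.x, p.y] for p in pts])
        for i in range(1, 4):
            for j in range(1, 4):
                vx, vy = j * cell - 0.5, i * cell - 0.5
                d = np.hypot(found[:, 0] - vx, found[:, 1] - vy).min()
                assert d <= 2.0

    def test_coordinates_inside_bounds(self, square_image):
        for p in harris_corners(square_image):
            assert 0 <= p.x < square_image.width
            assert 0 <= p.y < square_image.height


class TestANMS:
    def test_singleton_keeps_point_with_infinite_radius(self):
        p = FeaturePoint(3, 4, 1.0)
        (out,) = anms([p], n_target=1)
        assert out.suppression_radius == np.inf

    def test_two_point_radii_match_definition(self):
        pts = [FeaturePoint(0, 0, 10.0), FeaturePoint(7, 0, 1.0)]
        out = anms(pts, n_target=2, c_robust=1.0)
        by_resp = {p.response: p.suppression_radius for p in out}
        assert by_resp[10.0] == np.inf
        assert by_resp[1.0] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self, rng):
        pts = [
            FeaturePoint(x, y, r)
            for x, y, r in zip(
                rng.uniform(0, 200, 200), rng.uniform(0, 200, 200), rng.uniform(0, 1, 200)
            )
        ]
        out = anms(pts, n_target=50)
        oracle = brute_force_anms_radii(pts, 0.9)
        expect = set(np.argsort(-oracle)[:50])
        got_radii = sorted(p.suppression_radius for p in out)
        assert np.allclose(got_radii, sorted(oracle[list(expect)]))
        # every returned radius is correct per the oracle
        lookup = {(p.x, p.y): r for p, r in zip(pts, oracle)}
        for p in out:
            assert p.suppression_radius == pytest.approx(lookup[(p.x, p.y)])

    def test_n_target_larger_than_set_returns_all_with_radii(self):
        pts = [FeaturePoint(i * 10, 0, float(i + 1)) for i in range(5)]
        out = anms(pts, n_target=50)
        assert len(out) == 5
        assert all(np.isfinite(p.suppression_radius) or p.suppression_radius == np.inf for p in out)


class TestVesselMap:
    def test_constant_image_all_zero(self):
        like, mask = vessel_map(Image(np.full((64, 64), 0.3)))
        assert np.allclose(like.pixels, 0)
        assert not mask.any()

    def test_horizontal_ridge_mask_covers_centerline(self):
        y = np.arange(80)
        px = np.tile(np.exp(-((y - 40.0) ** 2) / (2 * 2.0**2))[:, None], (1, 80)) * 0.8
        _, mask = vessel_map(Image(px), sigma_v=2.0)
        centerline = mask[38:43, 5:75]
        # every column near the center contains mask pixels
        assert (centerline.any(axis=0)).mean() >= 0.9

    def test_ridge_scores_higher_than_equal_blob(self):
        yy, xx = np.mgrid[0:80, 0:80]
        blob = 0.8 * np.exp(-((xx - 40) ** 2 + (yy - 40) ** 2) / (2 * 2.0**2))
        ridge = 0.8 * np.exp(-((yy - 40) ** 2) / (2 * 2.0**2))
        lb, _ = vessel_map(Image(blob))
        lr, _ = vessel_map(Image(ridge))
        assert lr.pixels.max() > lb.pixels.max()


class TestSkeleton:
    def test_bar_thins_to_single_line(self):
        px = np.zeros((40, 80), dtype=bool)
        px[18:23, 10:70] = True
        skel = skeletonize(px)
        rows_per_col = skel.mask[:, 15:65].sum(axis=0)
        assert (rows_per_col == 1).all()

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize(np.zeros((32, 32), dtype=bool)).mask.any()

    def test_thinness_invariant_no_full_2x2_block(self, scene0):
        _, mask = vessel_map(render_scene(scene0, noise_seed=7))
        m = skeletonize(mask).mask
        blocks = m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]
        assert not blocks.any()

    def test_plus_sign_has_single_junction_cluster(self):
        px = np.zeros((41, 41), dtype=bool)
        px[19:22, 5:36] = True
        px[5:36, 19:22] = True
        clusters = skeleton_intersections(skeletonize(px))
        assert len(clusters) == 1
        c = clusters[0].mean(axis=0)
        assert np.hypot(c[0] - 20, c[1] - 20) <= 3

    def test_straight_line_has_no_junctions(self):
        px = np.zeros((32, 32), dtype=bool)
        px[16, 4:28] = True
        assert skeleton_intersections(skeletonize(px)) == []


class TestJunctionBarycenters:
    def test_centroid_arithmetic(self):
        cluster = np.array([[10, 10], [10, 11], [11, 10]], dtype=float)
        (p,) = junction_barycenters([cluster])
        assert p.x == pytest.approx(31 / 3)
        assert p.y == pytest.approx(31 / 3)
        assert p.response == 3

    def test_nearby_clusters_merge(self):
        c1 = np.array([[10.0, 10.0]])
        c2 = np.array([[12.0, 10.0]])
        assert len(junction_barycenters([c1, c2], merge_radius=5)) == 1

    def test_distant_clusters_stay_separate(self):
        c1 = np.array([[10.0, 10.0]])
        c2 = np.array([[60.0, 10.0]])
        assert len(junction_barycenters([c1, c2], merge_radius=5)) == 2


class TestGeneratorCrossCheck:
    def test_detector_recovers_true_junctions(self):
        """Vesselness -> skeleton -> junction pipeline finds every generated branch point."""
        hits = 0
        for seed in range(10):
            scene = generate_scene(seed)
            img = render_scene(scene, noise_seed=seed + 100)
            _, mask = vessel_map(img)
            pts = junction_barycenters(skeleton_intersections(skeletonize(mask)))
            det = np.array([[p.x, p.y] for p in pts]).reshape(-1, 2)
            if len(det) == 0:
                continue
            d = np.sqrt(((scene.junctions[:, None] - det[None]) ** 2).sum(-1)).min(axis=1)
            hits += int((d <= 5.0).all())
        assert hits >= 8
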