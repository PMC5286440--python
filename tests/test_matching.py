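"""Gradient descriptors, SAD, shape context, strict matching and revision."""

import itertools

import numpy as np
import pytest

from thermoreg import (
    FeaturePoint,
    Image,
    Match,
    MatchSet,
    SkeletonMap,
    gradient_descriptor,
    merge_control_pairs,
    relaxation_match,
    revise_relaxed,
    sad_score,
    sc_cost,
    shape_context,
    strict_match,
    train_matching_vectors,
    trim_control_pairs,
)
from thermoreg.matching import ShapeContextDescriptor, UnderdeterminedPairsError


def mk_match(sx, sy, tx, ty, cost=0.0, prov="relaxed"):
    return Match(FeaturePoint(sx, sy, 1.0), FeaturePoint(tx, ty, 1.0), cost, prov)


class TestGradientDescriptor:
    def test_ramp_has_constant_angle(self, ramp_image):
        d = gradient_descriptor(ramp_image, (32, 32), W=9)
        assert d.valid.all()
        assert np.allclose(d.angles, 0.0, atol=1e-9)  # gradient points +x

    def test_rotation_shifts_angles_by_half_pi(self, ramp_image):
        rot = Image(np.rot90(ramp_image.pixels))  # +x gradient becomes -y... +y in image coords
        d0 = gradient_descriptor(ramp_image, (32, 32), W=9)
        d1 = gradient_descriptor(rot, (32, 32), W=9)
        shift = np.mod(d1.angles - d0.angles, 2 * np.pi)
        assert np.allclose(shift, shift.flat[0], atol=1e-9)
        assert np.isclose(shift.flat[0] % (np.pi / 2), 0.0, atol=1e-9)

    def test_constant_image_all_invalid(self):
        d = gradient_descriptor(Image(np.full((32, 32), 0.7)), (16, 16), W=7)
        assert not d.valid.any()

    def test_border_point_rejected(self, ramp_image):
        with pytest.raises(ValueError):
            gradient_descriptor(ramp_image, (2, 2), W=21)


class TestSAD:
    def test_identical_descriptors_zero(self, ramp_image):
        d = gradient_descriptor(ramp_image, (30, 30), W=9)
        assert sad_score(d, d) == 0.0

    def test_opposite_angles_maximal(self):
        ones = np.ones((3, 3), dtype=bool)
        a = ShapeContextDescriptor  # noqa: F841  (keep import area tidy)
        from thermoreg.matching import GradientDescriptor

        d0 = GradientDescriptor(np.zeros((3, 3)), ones, (0, 0))
        d1 = GradientDescriptor(np.full((3, 3), np.pi), ones, (0, 0))
        assert sad_score(d0, d1) == pytest.approx(9 * np.pi)

    def test_matches_per_pixel_loop_oracle(self, rng):
        from thermoreg.matching import GradientDescriptor

        for _ in range(20):
            a = rng.uniform(0, 2 * np.pi, (7, 7))
            b = rng.uniform(0, 2 * np.pi, (7, 7))
            va = rng.random((7, 7)) > 0.2
            vb = rng.random((7, 7)) > 0.2
            da = GradientDescriptor(a, va, (0, 0))
            db = GradientDescriptor(b, vb, (0, 0))
            expect = 0.0
            for i in range(7):
                for j in range(7):
                    if va[i, j] and vb[i, j]:
                        d = abs(a[i, j] - b[i, j])
                        expect += min(d, 2 * np.pi - d)
            assert sad_score(da, db) == pytest.approx(expect)

    def test_no_common_valid_pixels_infinite(self):
        from thermoreg.matching import GradientDescriptor

        z = np.zeros((3, 3))
        d0 = GradientDescriptor(z, np.zeros((3, 3), dtype=bool), (0, 0))
        d1 = GradientDescriptor(z, np.ones((3, 3), dtype=bool), (0, 0))
        assert sad_score(d0, d1) == np.inf


class TestRelaxationMatch:
    def test_identity_pair_matches_in_place_with_zero_cost(self, rng):
        img = Image(rng.uniform(0, 1, (80, 80)))
        pts = [FeaturePoint(30, 30, 1.0), FeaturePoint(50, 45, 1.0)]
        ms = relaxation_match(pts, img, img, W=11, search_radius=8)
        assert len(ms) == 2
        for m in ms:
            assert m.displacement == (0.0, 0.0)
            assert m.cost == 0.0

    def test_pure_translation_recovered(self, rng):
        base = rng.uniform(0, 1, (90, 120))
        src = Image(base[:, :100])
        tgt = Image(base[:, 5:105])  # content shifted left by 5 => matches at x-5... careful
        pts = [FeaturePoint(40, 40, 1.0), FeaturePoint(60, 50, 1.0), FeaturePoint(52, 30, 1.0)]
        ms = relaxation_match(pts, src, tgt, W=11, search_radius=10)
        for m in ms:
            assert m.displacement == (-5.0, 0.0)

    def test_noise_target_still_returns_matches(self, rng):
        src = Image(rng.uniform(0, 1, (64, 64)))
        tgt = Image(rng.uniform(0, 1, (64, 64)))
        pts = [FeaturePoint(32, 32, 1.0)]
        ms = relaxation_match(pts, src, tgt, W=11, search_radius=5)
        assert len(ms) == 1  # permissive tier: a best match always exists


class TestShapeContext:
    def test_empty_maps_all_zero(self):
        skel = SkeletonMap(np.zeros((64, 64), dtype=bool))
        d = shape_context((32, 32), skel, np.zeros((64, 64), dtype=bool), R=20)
        assert np.allclose(d.bins, 0)

    def test_translation_invariance(self, rng):
        m = np.zeros((128, 128), dtype=bool)
        pts = rng.integers(30, 70, (40, 2))
        m[pts[:, 0], pts[:, 1]] = True
        heat = np.zeros_like(m)
        heat[40:60, 35:55] = True
        d0 = shape_context((50, 50), SkeletonMap(m), heat, R=30)
        shifted = np.roll(np.roll(m, 13, axis=0), 7, axis=1)
        heat_s = np.roll(np.roll(heat, 13, axis=0), 7, axis=1)
        d1 = shape_context((57, 63), SkeletonMap(shifted), heat_s, R=30)
        assert np.allclose(d0.bins, d1.bins)

    def test_single_pixel_analytic_bin(self):
        R = 32.0
        cx, cy = 64, 64
        r, ang = R / 2, np.deg2rad(45)
        px, py = cx + r * np.cos(ang), cy + r * np.sin(ang)
        m = np.zeros((128, 128), dtype=bool)
        m[int(round(py)), int(round(px))] = True
        d = shape_context((cx, cy), SkeletonMap(m), np.zeros_like(m), R=R)
        # analytic bin index: angular bin floor(45 / 30) = 1;
        # radial edges geomspace(R/16, R, 6): R/2 falls in bin
        # floor(log(8) / log(16^(1/5))) = 3
        edges = np.geomspace(R / 16, R, 6)
        true_r = np.hypot(int(round(px)) - cx, int(round(py)) - cy)
        rbin = int(np.searchsorted(edges, true_r, side="right")) - 1
        expect = np.zeros(120)
        expect[1 * 5 + rbin] = 1.0
        assert np.allclose(d.bins, expect)

    def test_halves_normalized_independently(self, rng):
        m = rng.random((96, 96)) > 0.9
        heat = rng.random((96, 96)) > 0.5
        d = shape_context((48, 48), SkeletonMap(m), heat, R=40)
        assert d.bins[:60].sum() == pytest.approx(1.0)
        assert d.bins[60:].sum() == pytest.approx(1.0)
        assert (d.bins >= 0).all()

    def test_rotation_equivariance_quarter_turn(self, rng):
        """Rotating point and maps by 90 deg permutes the angular bins by 3."""
        n = 129
        m = np.zeros((n, n), dtype=bool)
        pts = rng.integers(20, 100, (30, 2))
        m[pts[:, 0], pts[:, 1]] = True
        c = n // 2
        d0 = shape_context((c, c), SkeletonMap(m), np.zeros_like(m), R=30)
        rot = np.rot90(m, k=-1)  # (x, y) -> (n-1-y, x): +90 deg in image coords
        d1 = shape_context((c, c), SkeletonMap(rot), np.zeros_like(rot), R=30)
        h0 = d0.bins[:60].reshape(12, 5)
        h1 = d1.bins[:60].reshape(12, 5)
        assert np.allclose(np.roll(h0, 3, axis=0), h1)


class TestSCCost:
    def test_identical_zero(self, rng):
        b = rng.random(120)
        b[:60] /= b[:60].sum()
        b[60:] /= b[60:].sum()
        g = ShapeContextDescriptor(b, radius=30)
        assert sc_cost(g, g) == 0.0

    def test_disjoint_unit_mass_costs_one(self):
        g = np.zeros(120)
        h = np.zeros(120)
        g[0] = 1.0
        h[1] = 1.0
        assert sc_cost(
            ShapeContextDescriptor(g, 30), ShapeContextDescriptor(h, 30)
        ) == pytest.approx(1.0)

    def test_matches_chi2_oracle_and_symmetry(self, rng):
        for _ in range(20):
            g = rng.random(120)
            h = rng.random(120)
            dg = ShapeContextDescriptor(g, 30)
            dh = ShapeContextDescriptor(h, 30)
            expect = 0.0
            for k in range(120):
                if g[k] + h[k] > 0:
                    expect += 0.5 * (g[k] - h[k]) ** 2 / (g[k] + h[k])
            assert sc_cost(dg, dh) == pytest.approx(expect, abs=1e-12)
            assert sc_cost(dg, dh) == pytest.approx(sc_cost(dh, dg), abs=1e-12)


def _descriptors_from_matrix(C):
    """Fake descriptor lists whose sc_cost is irrelevant; strict_match is fed C directly via monkey structure."""


class TestStrictMatch:
    @staticmethod
    def _run_matrix(C, T, monkeypatch=None):
        """Drive strict_match with index-carrying stand-in descriptors so the
        cost matrix is exactly C."""
        import thermoreg.matching as mm

        n, k = C.shape
        src_pts = [FeaturePoint(i, 0, 1.0) for i in range(n)]
        tgt_pts = [FeaturePoint(j, 1, 1.0) for j in range(k)]

        class D:
            def __init__(self, i):
                self.i = i
                self.bins = np.zeros(1)

        src_d = [D(i) for i in range(n)]
        tgt_d = [D(j) for j in range(k)]
        orig = mm.sc_cost
        mm.sc_cost = lambda g, h: float(C[g.i, h.i])
        try:
            out = mm.strict_match(src_d, tgt_d, src_pts, tgt_pts, T)
        finally:
            mm.sc_cost = orig
        return {(int(m.source.x), int(m.target.x)) for m in out}

    def test_diagonal_optimum_kept(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert self._run_matrix(C, 0.5) == {(0, 0), (1, 1)}

    def test_ambiguous_pairs_rejected_by_ratio(self):
        C = np.array([[0.9, 1.0], [1.0, 0.9]])
        assert self._run_matrix(C, 0.5) == set()

    def test_assignment_cost_equals_brute_force(self, rng):
        """Optimal one-to-one assignment equals exhaustive permutation minimum, n <= 7."""
        from scipy.optimize import linear_sum_assignment

        for n in range(2, 8):
            for _ in range(20):
                C = rng.random((n, n))
                rows, cols = linear_sum_assignment(C)
                got = C[rows, cols].sum()
                best = min(
                    sum(C[i, p[i]] for i in range(n))
                    for p in itertools.permutations(range(n))
                )
                assert got == pytest.approx(best, abs=1e-12)


class TestMatchingVectors:
    def test_constant_field_both_sides(self):
        ms = MatchSet(
            [mk_match(10, 10, 13, 8, prov="strict"), mk_match(90, 10, 93, 8, prov="strict")]
        )
        left, right = train_matching_vectors(ms, midline_x=50)
        assert (left.dx, left.dy) == (3, -2)
        assert (right.dx, right.dy) == (3, -2)

    def test_median_robust_to_outlier(self):
        ms = MatchSet(
            [
                mk_match(10, 10, 10, 10, prov="strict"),
                mk_match(20, 10, 20, 10, prov="strict"),
                mk_match(30, 10, 40, 20, prov="strict"),
            ]
        )
        left, right = train_matching_vectors(ms, midline_x=50)
        assert (left.dx, left.dy) == (0, 0)
        assert right is None

    def test_unsupported_side_absent_and_revision_drops_it(self):
        strict = MatchSet([mk_match(10, 10, 12, 10, prov="strict")])
        vectors = train_matching_vectors(strict, midline_x=50)
        assert vectors[1] is None
        relaxed = MatchSet([mk_match(80, 10, 82, 10)])
        assert len(revise_relaxed(relaxed, vectors, midline_x=50)) == 0


class TestReviseRelaxed:
    def test_on_vector_kept_off_vector_removed(self):
        strict = MatchSet([mk_match(10, 10, 13, 8, prov="strict")] * 3)
        vectors = train_matching_vectors(strict, midline_x=50)
        good = mk_match(20, 20, 23, 18)
        bad = mk_match(30, 30, 80, 50)
        out = revise_relaxed(MatchSet([good, bad]), vectors, midline_x=50, tol_px=10)
        assert len(out) == 1
        assert out.pairs[0].source.x == 20
        assert out.pairs[0].provenance == "relaxed_revised"

    def test_simulated_outlier_rejection_rates(self):
        """>= 95% of injected mismatches removed, >= 95% of true matches kept."""
        kept_true = removed_inj = 0
        n_true_total = n_inj_total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vec = rng.uniform(-10, 10, 2)
            strict = MatchSet(
                [
                    mk_match(x, y, x + vec[0], y + vec[1], prov="strict")
                    for x, y in rng.uniform(0, 100, (6, 2))
                ]
            )
            true = [
                mk_match(x, y, x + vec[0] + rng.normal(0, 0.5), y + vec[1] + rng.normal(0, 0.5))
                for x, y in rng.uniform(0, 100, (40, 2))
            ]
            inj = []
            for x, y in rng.uniform(0, 100, (20, 2)):
                ang = rng.uniform(0, 2 * np.pi)
                mag = 60 * np.sqrt(rng.uniform())  # uniform over the 60-px disc
                inj.append(mk_match(x, y, x + mag * np.cos(ang), y + mag * np.sin(ang)))
            vectors = train_matching_vectors(strict, midline_x=200)  # everything "left"
            out = revise_relaxed(MatchSet(true + inj), vectors, midline_x=200, tol_px=10)
            kept_src = {(m.source.x, m.source.y) for m in out}
            kept_true += sum((m.source.x, m.source.y) in kept_src for m in true)
            removed_inj += sum((m.source.x, m.source.y) not in kept_src for m in inj)
            n_true_total += len(true)
            n_inj_total += len(inj)
        assert kept_true / n_true_total >= 0.95
        assert removed_inj / n_inj_total >= 0.95


class TestMergeAndTrim:
    def test_strict_wins_on_duplicate_source(self):
        strict = MatchSet([mk_match(10, 10, 12, 10, cost=0.1, prov="strict")])
        relaxed = MatchSet(
            [
                mk_match(10, 10, 30, 30, cost=5.0, prov="relaxed_revised"),
                mk_match(40, 40, 42, 40, cost=1.0, prov="relaxed_revised"),
                mk_match(60, 60, 62, 60, cost=1.0, prov="relaxed_revised"),
                mk_match(80, 20, 82, 20, cost=1.0, prov="relaxed_revised"),
            ]
        )
        out = merge_control_pairs(strict, relaxed, anms_n=10)
        at_10 = [m for m in out if m.source.x == 10]
        assert len(at_10) == 1
        assert at_10[0].provenance == "strict"

    def test_declustering_bounds_count(self, rng):
        pts = rng.uniform(40, 60, (100, 2))
        relaxed = MatchSet(
            [mk_match(x, y, x + 1, y, cost=rng.random(), prov="relaxed_revised") for x, y in pts]
        )
        out = merge_control_pairs(MatchSet(), relaxed, anms_n=20)
        assert 4 <= len(out) <= 20

    def test_too_few_pairs_flagged(self):
        relaxed = MatchSet([mk_match(10, 10, 12, 10), mk_match(20, 20, 22, 20)])
        with pytest.raises(UnderdeterminedPairsError):
            merge_control_pairs(MatchSet(), relaxed, anms_n=10)

    def test_trim_removes_field_inconsistent_pair(self, rng):
        """A pair deviating strongly from the smooth displacement field is trimmed."""
        pts = rng.uniform(10, 110, (20, 2))
        pairs = MatchSet([mk_match(x, y, x + 5, y - 3) for x, y in pts])
        pairs.pairs.append(mk_match(60, 60, 75, 75))  # inconsistent with translation
        out = trim_control_pairs(pairs)
        assert len(out) == 20
        assert all(np.allclose(m.displacement, (5.0, -3.0)) for m in out)


class TestMatchSetCSV:
    def test_round_trip(self, tmp_path, rng):
        ms = MatchSet(
            [mk_match(*rng.uniform(0, 100, 4), cost=float(rng.random()), prov="strict")
             for _ in range(5)]
        )
        ms.to_csv(tmp_path / "m.csv")
        back = MatchSet.from_csv(tmp_path / "m.csv")
        assert np.allclose(back.source_xy(), ms.source_xy())
        assert np.allclose(back.target_xy(), ms.target_xy())
        assert [m.provenance for m in back] == [m.provenance for m in ms]
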