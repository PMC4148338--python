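import numpy as np
import pytest

from kfmfit.fitting import (
    FitResult,
    InitializationError,
    average_error,
    evaluation_metrics,
    filter_mismatches,
    initialize_pdm,
    iterative_fit,
    matching_metrics,
    pinpoint_landmarks,
)
from kfmfit.geometry import SimilarityTransform
from kfmfit.shapes import (
    LandmarkShape,
    align_shapes,
    build_shape_model,
    build_profile_model,
    project_to_shape_space,
)

from conftest import ellipse_shape


class TestFilterMismatches:
    def test_fully_consistent_matches_all_inliers(self, rng):
        src = rng.uniform(-1, 1, (10, 2))
        t = SimilarityTransform(scale=200.0, rotation=0.3, translation=(100.0, 90.0))
        matches = [(t.apply(s), s) for s in src]
        inliers, est, low = filter_mismatches(matches, inlier_threshold=0.05, seed=4)
        assert len(inliers) == 10 and not low
        assert est.scale == pytest.approx(200.0, rel=1e-8)
        assert est.rotation == pytest.approx(0.3, abs=1e-8)
        np.testing.assert_allclose(est.translation, (100.0, 90.0), atol=1e-6)

    def test_planted_outliers_rejected(self, rng):
        src = rng.uniform(-1, 1, (8, 2))
        t = SimilarityTransform(scale=150.0, rotation=-0.2, translation=(80.0, 70.0))
        matches = [(t.apply(s), s) for s in src]
        # two gross outliers, far beyond threshold x scale
        matches.append((t.apply(np.array([0.5, 0.5])) + 200.0, np.array([0.5, 0.5])))
        matches.append((t.apply(np.array([-0.5, 0.1])) - 150.0, np.array([-0.5, 0.1])))
        inliers, est, _ = filter_mismatches(matches, inlier_threshold=0.05, seed=7)
        assert sorted(inliers) == list(range(8))

    def test_two_matches_exact_fit(self):
        t = SimilarityTransform(scale=2.0, rotation=0.5, translation=(3.0, 4.0))
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        matches = [(t.apply(s), s) for s in src]
        inliers, est, low = filter_mismatches(matches, inlier_threshold=0.1)
        assert sorted(inliers) == [0, 1]
        assert est.scale == pytest.approx(2.0)
        assert est.rotation == pytest.approx(0.5)

    def test_too_few_matches_is_initialization_failure(self):
        with pytest.raises(InitializationError, match="at least 2"):
            filter_mismatches([(np.zeros(2), np.zeros(2))], 0.05)

    def test_deterministic_given_seed(self, rng):
        src = rng.uniform(-1, 1, (12, 2))
        t = SimilarityTransform(scale=100.0, rotation=0.1, translation=(50.0, 50.0))
        matches = [(t.apply(s) + rng.normal(0, 1, 2), s) for s in src]
        r1 = filter_mismatches(matches, 0.05, seed=42)
        r2 = filter_mismatches(matches, 0.05, seed=42)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1].scale == r2[1].scale


class TestInitialization:
    def test_rigidity_preserves_distance_ratios(self):
        mean = ellipse_shape()
        t = SimilarityTransform(scale=3.0, rotation=0.7, translation=(10.0, 5.0))
        init = initialize_pdm(mean, t)
        d_mean = np.linalg.norm(mean.points[:-1] - mean.points[1:], axis=1)
        d_init = np.linalg.norm(init.points[:-1] - init.points[1:], axis=1)
        np.testing.assert_allclose(d_init, 3.0 * d_mean, rtol=1e-10)


class TestPinpoint:
    def square(self):
        return LandmarkShape(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        )

    def test_zero_targets_is_identity(self):
        s = self.square()
        out = pinpoint_landmarks(s, {})
        np.testing.assert_array_equal(out.points, s.points)

    def test_neighbor_at_min_distance_moves_fully(self):
        # landmarks 0 and 1 are 10 apart = d_min(0); j at d_min moves by delta
        s = self.square()
        delta = np.array([2.0, -1.0])
        out = pinpoint_landmarks(s, {0: s.points[0] + delta})
        np.testing.assert_allclose(out.points[0], s.points[0] + delta)
        np.testing.assert_allclose(out.points[1], s.points[1] + delta)
        np.testing.assert_allclose(out.points[3], s.points[3] + delta)

    def test_double_distance_halves_movement(self):
        # a line of 3 landmarks: d_min(0)=5, landmark 2 at distance 10
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]])
        delta = np.array([0.0, 4.0])
        out = pinpoint_landmarks(LandmarkShape(pts), {0: pts[0] + delta}, exponent=1.0)
        np.testing.assert_allclose(out.points[2], pts[2] + delta / 2)

    def test_symmetric_opposite_targets_cancel_at_midpoint(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]])
        delta = np.array([0.0, 2.0])
        out = pinpoint_landmarks(
            LandmarkShape(pts), {0: pts[0] + delta, 2: pts[2] - delta}
        )
        np.testing.assert_allclose(out.points[1], pts[1], atol=1e-12)

    def test_weight_capped_at_one(self):
        # landmark closer to the target than d_min still moves by exactly delta
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        delta = np.array([3.0, 0.0])
        out = pinpoint_landmarks(LandmarkShape(pts), {2: pts[2] + delta})
        # d_min(2) = 9 (to landmark 0? no: to landmark 1 at distance 9)
        # landmark 1 at distance 9 = d_min -> full delta; landmark 0 at 10 -> 9/10
        np.testing.assert_allclose(out.points[1], pts[1] + delta)
        np.testing.assert_allclose(out.points[0], pts[0] + 0.9 * delta)

    def test_coincident_landmark_promoted_with_warning(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        delta = np.array([1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="coincide"):
            out = pinpoint_landmarks(LandmarkShape(pts), {0: pts[0] + delta})
        np.testing.assert_allclose(out.points[1], pts[1] + delta)


class TestIterativeFit:
    def setup_models(self, samples):
        shapes = [s.shape for s in samples]
        aligned, _, _ = align_shapes(shapes)
        sm = build_shape_model(aligned, variance_fraction=0.98)
        pm = build_profile_model([s.image for s in samples], shapes, half_length=6)
        return sm, pm

    def test_truth_start_is_a_near_fixed_point(self, small_phantom):
        sm, pm = self.setup_models(small_phantom)
        s = small_phantom[0]
        start_err = 0.0
        final, iters, converged = iterative_fit(s.image, s.shape, sm, pm)
        assert converged and iters <= 2
        final_err = np.linalg.norm(final.points - s.shape.points, axis=1).mean()
        assert final_err <= 1.5  # stays at the boundary it started on

    def test_normal_displacement_recovered(self, small_phantom):
        from kfmfit.shapes import boundary_normals

        sm, pm = self.setup_models(small_phantom)
        s = small_phantom[1]
        normals = boundary_normals(s.shape)
        start = LandmarkShape(s.shape.points + 3.0 * normals)
        final, _, _ = iterative_fit(s.image, start, sm, pm)
        err = np.linalg.norm(final.points - s.shape.points, axis=1).mean()
        assert err < 1.5

    def test_zero_search_length_projects_only(self, small_phantom):
        # with no search window the only change is the constraint projection
        from kfmfit.geometry import estimate_similarity_transform
        from kfmfit.shapes import reconstruct_shape

        sm, pm = self.setup_models(small_phantom)
        s = small_phantom[0]
        pose = estimate_similarity_transform(sm.mean_shape.points, s.shape.points)
        b = project_to_shape_space(
            sm, LandmarkShape(pose.inverse().apply(s.shape.points))
        )
        expected = pose.apply(reconstruct_shape(sm, b).points)
        first, iters, _ = iterative_fit(
            s.image, s.shape, sm, pm, search_length=0, max_iter=1
        )
        assert iters == 1
        np.testing.assert_allclose(first.points, expected, atol=1e-9)

    def test_output_satisfies_shape_constraint(self, small_phantom):
        sm, pm = self.setup_models(small_phantom)
        s = small_phantom[2]
        final, _, _ = iterative_fit(s.image, s.shape, sm, pm)
        from kfmfit.geometry import estimate_similarity_transform

        pose = estimate_similarity_transform(sm.mean_shape.points, final.points)
        b = project_to_shape_space(
            sm, LandmarkShape(pose.inverse().apply(final.points)), clamp=False
        )
        limits = sm.bound_multiplier * np.sqrt(sm.eigenvalues)
        assert np.all(np.abs(b) <= limits * (1 + 1e-6))


class TestMetrics:
    def test_average_error_closed_forms(self):
        a = ellipse_shape()
        b = LandmarkShape(a.points + np.array([3.0, 4.0]))
        assert average_error([a], [a]) == 0.0
        assert average_error([a, b], [a, a]) == pytest.approx(2.5)
        assert average_error([b], [a]) == pytest.approx(5.0)

    def test_average_error_matches_double_loop(self, rng):
        preds = [LandmarkShape(rng.uniform(0, 50, (7, 2))) for _ in range(4)]
        refs = [LandmarkShape(rng.uniform(0, 50, (7, 2))) for _ in range(4)]
        acc = [
            np.linalg.norm(p.points[l] - r.points[l])
            for p, r in zip(preds, refs)
            for l in range(7)
        ]
        assert average_error(preds, refs) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_count_mismatch_rejected(self):
        a = ellipse_shape()
        with pytest.raises(ValueError):
            average_error([a], [a, a])

    def result_with_offsets(self, ref, init_off, pin_off):
        mk = lambda off: LandmarkShape(ref.points + off)
        return FitResult(
            initialized_shape=mk(init_off), pinpointed_shape=mk(pin_off),
            final_shape=mk(pin_off), init_transform=SimilarityTransform(),
            n_matched_features=5, n_pinpointed=ref.n_landmarks,
            iterations=3, converged=True,
        )

    def test_perfect_fit_metrics(self):
        ref = ellipse_shape()
        res = self.result_with_offsets(ref, np.array([0.5, 0.5]), np.array([0.1, 0.0]))
        m = evaluation_metrics([res], [ref])
        assert m["correct_initialization_ratio"] == 1.0
        assert m["pinpoint_counts"] == [38]

    def test_exactly_half_within_tolerance_is_incorrect(self):
        # boundary: exactly N/2 landmarks within 5 px must NOT count
        ref = ellipse_shape()
        pts = ref.points.copy()
        pts[:19] += np.array([1.0, 0.0])   # 19 within 5 px
        pts[19:] += np.array([100.0, 0.0])  # 19 far away
        res = FitResult(
            initialized_shape=LandmarkShape(pts), pinpointed_shape=LandmarkShape(pts),
            final_shape=LandmarkShape(pts), init_transform=SimilarityTransform(),
            n_matched_features=0, n_pinpointed=0, iterations=0, converged=True,
        )
        m = evaluation_metrics([res], [ref])
        assert m["correct_initialization_ratio"] == 0.0
        # one more within tolerance flips the criterion
        pts[19] = ref.points[19] + np.array([1.0, 0.0])
        res.initialized_shape = LandmarkShape(pts)
        m = evaluation_metrics([res], [ref])
        assert m["correct_initialization_ratio"] == 1.0

    def test_pinpoint_tolerance_boundary(self):
        # exact arithmetic: integer coordinates so the offset is exactly 3 px
        ref = LandmarkShape(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        )
        pts = ref.points + np.array([3.0, 0.0])  # exactly 3 px: not precise
        res = FitResult(
            initialized_shape=ref, pinpointed_shape=LandmarkShape(pts),
            final_shape=ref, init_transform=SimilarityTransform(),
            n_matched_features=0, n_pinpointed=0, iterations=0, converged=True,
        )
        assert evaluation_metrics([res], [ref])["pinpoint_counts"] == [0]
        res.pinpointed_shape = LandmarkShape(ref.points + np.array([2.5, 0.0]))
        assert evaluation_metrics([res], [ref])["pinpoint_counts"] == [4]

    def test_matching_metrics_against_direct_count(self, rng):
        n_coll = 3
        matched, truth = [], []
        expect_correct = 0
        expect_total = 0
        for _ in range(5):
            m, t = [], {}
            for k in range(n_coll):
                if rng.random() < 0.7:
                    t[k] = rng.uniform(0, 100, 2)
                if rng.random() < 0.8:
                    pos = (
                        t[k] + rng.normal(0, 1, 2)
                        if k in t and rng.random() < 0.7
                        else rng.uniform(0, 100, 2)
                    )
                    m.append((pos, k))
                    expect_total += 1
                    if k in t and np.linalg.norm(pos - t[k]) < 6.0:
                        expect_correct += 1
            matched.append(m)
            truth.append(t)
        out = matching_metrics(matched, truth, n_coll, tolerance=6.0)
        assert out["n_matches"] == expect_total
        assert out["correct_match_ratio"] == pytest.approx(
            expect_correct / expect_total
        )
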