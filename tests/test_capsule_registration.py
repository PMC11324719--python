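import numpy as np
import pytest
from shapely.geometry import Polygon

from prostacoreg.capsule_registration import (
    CapsuleContour,
    SimilarityTransform2D,
    SlideCorrespondence,
    correspond_contours,
    fit_similarity,
    register_slice,
    transition_zone_dice,
    validate_slide_correspondence,
)
from prostacoreg.phantom import random_tps_deformation


def circle(center, radius, n=100, phase=0.0):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def teardrop(center=(0.0, 0.0), n=720):
    """Blob with a sharp posterior (min-y) spike that stays posterior-most under rotation."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 20.0 + 3.0 * np.cos(2 * ang) + 18.0 * np.exp(-((ang - 1.5 * np.pi) ** 2) / 0.01)
    return np.column_stack(
        [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
    )


def blob(scale=1.0, n=240):
    """Smooth capsule outline with enough shape features to pin correspondence."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = scale * (
        20.0
        + 2.5 * np.cos(2 * ang)
        + 1.5 * np.sin(3 * ang)
        + 1.2 * np.cos(5 * ang)
        + 0.8 * np.sin(7 * ang)
    )
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def contour(verts, kind="capsule", sid="s0"):
    return CapsuleContour(sid, kind, verts)


class TestSlideCorrespondence:
    def test_standard_spacing_valid(self):
        corr = SlideCorrespondence(
            entries=[("wm_0", 3), ("wm_1", 6), ("wm_2", 9), ("wm_3", 12)],
            mri_slice_spacing_mm=1.5,
            wm_thickness_mm=4.5,
        )
        assert validate_slide_correspondence(corr).ok

    def test_duplicate_index_flagged(self):
        corr = SlideCorrespondence(entries=[("a", 3), ("b", 3)])
        report = validate_slide_correspondence(corr)
        assert any("duplicate" in v for v in report.violations)

    def test_non_monotone_flagged(self):
        corr = SlideCorrespondence(entries=[("a", 6), ("b", 3)])
        report = validate_slide_correspondence(corr)
        assert any("non-monotone" in v for v in report.violations)

    def test_irregular_spacing_flagged(self):
        corr = SlideCorrespondence(entries=[("a", 3), ("b", 10)])
        report = validate_slide_correspondence(corr)
        assert any("spacing" in v for v in report.violations)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            validate_slide_correspondence(SlideCorrespondence(entries=[]))


class TestCorrespondContours:
    def test_identical_circles_different_density(self):
        # both polygon counts divisible by 4 so the posterior vertex is exact
        a = contour(circle((5, 3), 10, n=200))
        b = contour(circle((5, 3), 10, n=36))
        fa, fb = correspond_contours(a, b, n_points=64)
        circumference = 2 * np.pi * 10
        # resampling tolerance plus the coarse polygon's chord sagitta
        tol = 0.01 * circumference / 64 + 10 * (1 - np.cos(np.pi / 36)) + 0.1
        assert np.linalg.norm(fa - fb, axis=1).max() < tol

    def test_rotation_recovered_via_similarity(self):
        # posterior spike anchors the same material point before/after a 40 deg turn
        base = teardrop()
        th = np.deg2rad(40.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = base @ R.T
        fixed_pts, moving_pts = correspond_contours(
            contour(base), contour(rotated), n_points=64
        )
        sim = fit_similarity(moving_pts, fixed_pts)
        assert sim.rotation_deg == pytest.approx(-40.0, abs=1.5)
        assert sim.scale == pytest.approx(1.0, abs=0.02)

    def test_square_anchored_at_posterior_corner(self):
        # diamond: four corners, unique posterior-most vertex
        diamond = np.array([[0.0, -10.0], [10.0, 0.0], [0.0, 10.0], [-10.0, 0.0]])
        pts, _ = correspond_contours(contour(diamond), contour(diamond), n_points=4)
        assert np.allclose(pts[0], [0.0, -10.0], atol=0.1)
        corners = {tuple(np.round(p).astype(int)) for p in pts}
        assert corners == {(0, -10), (10, 0), (0, 10), (-10, 0)}

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            CapsuleContour("s", "capsule", np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestFitSimilarity:
    def test_identity(self, rng):
        pts = rng.uniform(-10, 10, (20, 2))
        sim = fit_similarity(pts, pts)
        assert sim.scale == pytest.approx(1.0)
        assert sim.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sim.translation, 0.0, atol=1e-9)

    def test_exact_recovery(self, rng):
        pts = rng.uniform(-10, 10, (30, 2))
        truth = SimilarityTransform2D(0.9, 15.0, np.array([2.0, -1.0]))
        sim = fit_similarity(pts, truth.apply(pts))
        assert sim.scale == pytest.approx(0.9, abs=1e-9)
        assert sim.rotation_deg == pytest.approx(15.0, abs=1e-9)
        assert np.allclose(sim.translation, [2.0, -1.0], atol=1e-9)

    def test_noise_perturbation_bounded(self, rng):
        # Monte-Carlo: noisy recovery stays within 3x the expected perturbation
        pts = rng.uniform(-20, 20, (100, 2))
        truth = SimilarityTransform2D(0.9, 15.0, np.array([2.0, -1.0]))
        fixed = truth.apply(pts)
        noise_sd = 0.1
        rms = np.sqrt(((pts - pts.mean(0)) ** 2).sum(axis=1).mean())
        bound = 3 * noise_sd / (rms * np.sqrt(len(pts) / 2))
        for seed in range(5):
            noisy = fixed + np.random.default_rng(seed).normal(0, noise_sd, fixed.shape)
            sim = fit_similarity(pts, noisy)
            assert abs(sim.scale - 0.9) < bound
            assert abs(np.deg2rad(sim.rotation_deg - 15.0)) < bound / 0.9

    def test_coincident_moving_points_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_similarity(pts, np.ones((5, 2)))

    def test_residual_invariant_under_joint_rigid_motion(self, rng):
        mov = rng.uniform(-10, 10, (25, 2))
        fix = mov + rng.normal(0, 0.5, mov.shape)
        sim = fit_similarity(mov, fix)
        res0 = np.linalg.norm(sim.apply(mov) - fix, axis=1).sum()
        th = np.deg2rad(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([4.0, -7.0])
        sim2 = fit_similarity(mov @ R.T + shift, fix @ R.T + shift)
        res1 = np.linalg.norm(
            sim2.apply(mov @ R.T + shift) - (fix @ R.T + shift), axis=1
        ).sum()
        assert res1 == pytest.approx(res0, rel=1e-6)


def capsule_dice(moving_verts, fixed_verts, transform):
    return transition_zone_dice(
        contour(fixed_verts, "transition_zone"),
        contour(moving_verts, "transition_zone"),
        transform=transform,
    )


class TestRegisterSlice:
    def test_identity_inputs(self):
        cap = contour(blob())
        xf = register_slice(cap, cap)
        probes = blob(scale=0.8)
        assert np.abs(xf.apply(probes) - probes).max() < 0.3
        assert capsule_dice(blob(), blob(), xf) > 0.99

    def test_uniform_shrinkage_recovered(self):
        fixed = contour(blob())
        moving = contour(blob(scale=0.85))
        xf = register_slice(moving, fixed)
        sim = xf.steps[0]
        assert sim.scale == pytest.approx(1 / 0.85, rel=0.01)
        assert capsule_dice(blob(scale=0.85), blob(), xf) >= 0.99

    def test_known_tps_warp_recovered(self):
        base = blob()
        # corner-driven smooth warp: specimen deformation acts through the
        # boundary, so no independent interior displacement bump
        warp = random_tps_deformation(
            base.min(axis=0), base.max(axis=0), magnitude_mm=3.0, seed=21, n_grid=2
        )
        moving = contour(warp.apply(base))
        fixed = contour(base)
        # register the warped capsule back onto the original
        xf = register_slice(moving, fixed)
        assert capsule_dice(warp.apply(base), base, xf) >= 0.98
        interior = base * 0.6
        err = np.linalg.norm(xf.apply(warp.apply(interior)) - interior, axis=1)
        assert err.max() < 1.0

    def test_interior_fiducial_error_reduced(self, rng):
        # deformation <= 4 mm + shrink 0.9: mean post-registration interior
        # error <= 40% of the pre-registration error across the seeded suite
        base = blob()
        pres, posts = [], []
        for seed in range(5):
            warp = random_tps_deformation(
                base.min(axis=0) - 5, base.max(axis=0) + 5, 4.0, seed=seed, n_grid=2
            )
            fids = rng.uniform(-12, 12, (10, 2))
            moving_caps = contour(warp.apply(base * (1 / 0.9)))
            xf = register_slice(moving_caps, contour(base), n_points=128)
            moving_fids = warp.apply(fids * (1 / 0.9))
            pres.append(np.linalg.norm(moving_fids - fids, axis=1).mean())
            posts.append(np.linalg.norm(xf.apply(moving_fids) - fids, axis=1).mean())
        assert np.mean(posts) <= 0.4 * np.mean(pres)


class TestTransitionZoneDice:
    def test_identical(self):
        tz = contour(circle((0, 0), 8), "transition_zone")
        assert transition_zone_dice(tz, tz) == pytest.approx(1.0, abs=0.01)

    def test_disjoint(self):
        a = contour(circle((0, 0), 5), "transition_zone")
        b = contour(circle((30, 0), 5), "transition_zone")
        assert transition_zone_dice(a, b) == 0.0

    def test_half_overlapping_squares(self):
        sq = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        a = contour(sq, "transition_zone")
        b = contour(sq + [5.0, 0.0], "transition_zone")
        # analytic: intersection 50, areas 100 each -> dice 0.5
        assert transition_zone_dice(a, b) == pytest.approx(0.5, abs=0.02)

    def test_symmetric(self):
        a = contour(circle((0, 0), 8), "transition_zone")
        b = contour(circle((4, 1), 7), "transition_zone")
        assert transition_zone_dice(a, b) == pytest.approx(
            transition_zone_dice(b, a), abs=1e-6
        )


class TestContourValidation:
    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(ValueError, match="self-intersect"):
            CapsuleContour("s", "capsule", bowtie)

    def test_closed_duplicate_endpoint_dropped(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float)
        c = CapsuleContour("s", "capsule", sq)
        assert len(c.vertices) == 4

    def test_bad_kind(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        with pytest.raises(ValueError, match="kind"):
            CapsuleContour("s", "lesion", sq)
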