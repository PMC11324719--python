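import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from prostacoreg.landmark_registration import (
    CompositeTransform,
    RigidTransform,
    apply_transform,
    combine_quadrature,
    compute_tre,
    exclude_tre_outliers,
    fit_tps,
    initialize_alignment,
    load_transform,
    save_transform,
)


def rotation_x(deg):
    th = np.deg2rad(deg)
    return np.array(
        [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
    )


def random_points(rng, n, d, scale=30.0):
    return rng.uniform(-scale, scale, (n, d))


class TestInitializeAlignment:
    def test_identity(self, rng):
        pts = random_points(rng, 12, 3)
        xf = initialize_alignment(pts, pts)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(xf.translation, 0.0, atol=1e-9)

    def test_recovers_known_rigid_motion(self, rng):
        # anisotropic cloud so principal axes are unambiguous
        pts = rng.normal(size=(40, 3)) * np.array([10.0, 4.0, 1.5])
        R = rotation_x(20.0)
        t = np.array([5.0, 0.0, 0.0])
        moved = pts @ R.T + t
        xf = initialize_alignment(pts, moved)
        assert np.abs(xf.apply(pts) - moved).max() < 1e-6

    def test_sign_ambiguity_resolved_by_cost(self, rng):
        # asymmetric cloud: the flipped orientation has strictly larger cost
        pts = rng.normal(size=(30, 3)) * np.array([8.0, 3.0, 1.0])
        pts[:, 0] += 0.5 * pts[:, 0] ** 2 / 8.0  # break the x symmetry
        xf = initialize_alignment(pts, pts)
        assert np.abs(xf.apply(pts) - pts).max() < 1e-6

    def test_degenerate_collinear(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            initialize_alignment(line, line)

    def test_too_few_points(self):
        pts = np.eye(3)[:2]
        with pytest.raises(ValueError):
            initialize_alignment(pts, pts)


class TestFitTPS:
    def test_identity_map(self, rng):
        pts = random_points(rng, 8, 3)
        tps = fit_tps(pts, pts)
        assert np.abs(tps.weights).max() < 1e-9
        probes = random_points(rng, 20, 3)
        assert np.abs(tps.apply(probes) - probes).max() < 1e-8

    def test_pure_translation_reproduced_everywhere(self, rng):
        pts = random_points(rng, 10, 3)
        t = np.array([2.0, -1.0, 4.0])
        tps = fit_tps(pts, pts + t)
        probes = random_points(rng, 50, 3)
        assert np.abs(tps.apply(probes) - (probes + t)).max() < 1e-8

    @pytest.mark.parametrize("dim", [2, 3])
    def test_exact_interpolation_vs_dense_solver_oracle(self, rng, dim):
        src = random_points(rng, 10, dim)
        tgt = src + rng.normal(scale=3.0, size=src.shape)
        tps = fit_tps(src, tgt)
        assert np.abs(tps.apply(src) - tgt).max() < 1e-9

        # independent oracle: rebuild and solve the interpolation system with
        # scipy.linalg and a locally written kernel, then compare probe values
        import scipy.linalg

        r = cdist(src, src)
        U = r**2 * np.log(r, out=np.zeros_like(r), where=r > 0) if dim == 2 else r
        n = len(src)
        P = np.hstack([np.ones((n, 1)), src])
        A = np.block([[U, P], [P.T, np.zeros((dim + 1, dim + 1))]])
        sol = scipy.linalg.solve(A, np.vstack([tgt, np.zeros((dim + 1, dim))]))
        probes = random_points(rng, 30, dim)
        rp = cdist(probes, src)
        Up = rp**2 * np.log(rp, out=np.zeros_like(rp), where=rp > 0) if dim == 2 else rp
        oracle = Up @ sol[:n] + np.hstack([np.ones((30, 1)), probes]) @ sol[n:]
        assert np.abs(tps.apply(probes) - oracle).max() < 1e-6

    def test_side_conditions(self, rng):
        src = random_points(rng, 12, 3)
        tgt = src + rng.normal(scale=2.0, size=src.shape)
        tps = fit_tps(src, tgt)
        assert np.abs(tps.weights.sum(axis=0)).max() < 1e-8
        assert np.abs(src.T @ tps.weights).max() < 1e-6

    def test_duplicate_control_points_named(self, rng):
        src = random_points(rng, 6, 3)
        src[4] = src[1]
        with pytest.raises(ValueError, match="coincident"):
            fit_tps(src, src)

    def test_mismatched_shapes(self, rng):
        with pytest.raises(ValueError):
            fit_tps(random_points(rng, 5, 3), random_points(rng, 6, 3))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_tps(np.zeros((2, 3)) + np.arange(6).reshape(2, 3), np.ones((2, 3)))

    def test_regularization_smooths(self, rng):
        src = random_points(rng, 15, 2)
        tgt = src + rng.normal(scale=2.0, size=src.shape)
        exact = fit_tps(src, tgt, regularization=0.0)
        smooth = fit_tps(src, tgt, regularization=100.0)
        res_exact = np.abs(exact.apply(src) - tgt).max()
        res_smooth = np.abs(smooth.apply(src) - tgt).max()
        assert res_exact < 1e-9 < res_smooth

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), dim=st.sampled_from([2, 3]))
    def test_property_exact_interpolation(self, seed, dim):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(dim + 2, 20))
        src = rng.uniform(-40, 40, (n, dim))
        if np.linalg.matrix_rank(src - src.mean(0)) < dim:
            return  # skip degenerate draws
        tgt = src + rng.normal(scale=4.0, size=src.shape)
        tps = fit_tps(src, tgt)
        assert np.abs(tps.apply(src) - tgt).max() < 1e-9

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_property_affine_reproduction(self, seed):
        # TPS reproduces any affine target map exactly at arbitrary probes
        rng = np.random.default_rng(seed)
        src = rng.uniform(-30, 30, (9, 3))
        M = np.eye(3) + rng.normal(scale=0.1, size=(3, 3))
        b = rng.normal(scale=5.0, size=3)
        tps = fit_tps(src, src @ M.T + b)
        probes = rng.uniform(-30, 30, (40, 3))
        assert np.abs(tps.apply(probes) - (probes @ M.T + b)).max() < 1e-6


class TestApplyTransform:
    def test_identity(self, rng):
        pts = random_points(rng, 10, 3)
        assert np.allclose(apply_transform(RigidTransform.identity(3), pts), pts)

    def test_chain_equals_sequential(self, rng):
        A = RigidTransform(rotation_x(25.0), np.array([1.0, 2.0, 3.0]))
        src = random_points(rng, 9, 3)
        B = fit_tps(src, src + rng.normal(scale=2.0, size=src.shape))
        pts = random_points(rng, 1000, 3)
        joint = apply_transform([A, B], pts)
        seq = apply_transform(B, apply_transform(A, pts))
        assert np.abs(joint - seq).max() < 1e-9

    def test_translation_only_tps(self, rng):
        src = random_points(rng, 8, 3)
        t = np.array([0.5, -2.0, 1.0])
        tps = fit_tps(src, src + t)
        pts = random_points(rng, 30, 3)
        assert np.abs(apply_transform(tps, pts) - (pts + t)).max() < 1e-8

    def test_dimension_mismatch(self, rng):
        src = random_points(rng, 8, 3)
        tps = fit_tps(src, src)
        with pytest.raises(ValueError, match="3D"):
            tps.apply(np.zeros((4, 2)))

    def test_serialization_roundtrip(self, rng, tmp_path):
        A = RigidTransform(rotation_x(10.0), np.array([1.0, 0.0, -2.0]))
        src = random_points(rng, 7, 3)
        B = fit_tps(src, src + rng.normal(size=src.shape))
        chain = CompositeTransform((A, B))
        save_transform(chain, tmp_path / "xf.json")
        loaded = load_transform(tmp_path / "xf.json")
        pts = random_points(rng, 50, 3)
        assert np.abs(chain.apply(pts) - loaded.apply(pts)).max() < 1e-12


class TestComputeTRE:
    def test_coincident_pairs(self, rng):
        pts = random_points(rng, 5, 3)
        report = compute_tre(pts, pts)
        assert report.mean_mm == 0.0

    def test_3_4_5_triangle(self):
        report = compute_tre(np.zeros((1, 3)), np.array([[3.0, 4.0, 0.0]]))
        assert report.per_pair_mm[0] == pytest.approx(5.0)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_tre(np.empty((0, 3)), np.empty((0, 3)))

    def test_order_invariance(self, rng):
        mov, fix = random_points(rng, 10, 3), random_points(rng, 10, 3)
        a = compute_tre(mov, fix)
        order = rng.permutation(10)
        b = compute_tre(mov[order], fix[order])
        assert a.mean_mm == pytest.approx(b.mean_mm)
        assert a.se_mm == pytest.approx(b.se_mm)

    def test_registration_reduces_phantom_tre(self, scene):
        # known smooth 4 mm deformation; controls disjoint from held-out fiducials
        from prostacoreg.phantom import random_tps_deformation, scene_control_landmarks
        from prostacoreg.landmark_registration import landmark_array

        vol = scene.intensity_volume
        lo = np.asarray(vol.origin)
        hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
        deform = random_tps_deformation(lo, hi, 4.0, seed=11)
        src = landmark_array(scene_control_landmarks(scene))
        tps = fit_tps(src, deform.apply(src))
        fids = np.array(list(scene.fiducials.values()))
        fids_true = deform.apply(fids)
        pre = compute_tre(fids, fids_true)
        post = compute_tre(fids, fids_true, transform=tps)
        assert post.mean_mm < pre.mean_mm


class TestExcludeOutliers:
    def test_zero_variance(self):
        kept, excluded = exclude_tre_outliers([5.0, 5.0, 5.0])
        assert excluded == []
        assert list(kept) == [5.0, 5.0, 5.0]

    def test_single_outlier(self):
        # direct arithmetic: mean 2.9, sd 6.008, threshold 14.92
        d = [1.0] * 9 + [20.0]
        assert np.mean(d) == pytest.approx(2.9)
        assert np.std(d, ddof=1) == pytest.approx(6.0083, abs=1e-3)
        kept, excluded = exclude_tre_outliers(d)
        assert excluded == [9]
        assert len(kept) == 9

    def test_no_exclusion_when_all_within(self, rng):
        d = rng.uniform(1.0, 2.0, 50)
        threshold = d.mean() + 2 * d.std(ddof=1)
        assert np.all(d <= threshold)
        kept, excluded = exclude_tre_outliers(d)
        assert excluded == []
        assert np.array_equal(kept, d)

    def test_fewer_than_three_warns(self):
        with pytest.warns(UserWarning):
            kept, excluded = exclude_tre_outliers([1.0, 2.0])
        assert excluded == []


class TestCombineQuadrature:
    def test_pythagorean(self):
        mean, _ = combine_quadrature([3.0, 4.0], [0.0, 0.0])
        assert mean == pytest.approx(5.0)

    def test_zero_second_term(self):
        mean, se = combine_quadrature([2.7, 0.0], [0.1, 0.0])
        assert mean == pytest.approx(2.7)
        assert se == pytest.approx(0.1)

    def test_reported_cohort_values(self):
        # per-step 2.23 and 3.20 mm (SE 0.08 each) combine to 3.90 +- 0.11 mm
        mean, se = combine_quadrature([2.23, 3.20], [0.08, 0.08])
        assert round(mean, 2) == 3.90
        assert round(se, 2) == 0.11

    def test_symmetric(self, rng):
        m = rng.uniform(0, 5, 4)
        s = rng.uniform(0, 1, 4)
        order = rng.permutation(4)
        assert combine_quadrature(m, s) == combine_quadrature(m[order], s[order])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_quadrature([-1.0], [0.0])
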