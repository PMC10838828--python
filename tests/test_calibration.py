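import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endosize.calibration import (
    CalibrationError,
    CheckerboardSpec,
    DegenerateMotionsError,
    MotionPair,
    build_motions,
    detect_checkerboard,
    estimate_intrinsics,
    handeye_solve,
    select_motions,
)
from endosize.geometry import (
    RigidTransform,
    compose,
    invert,
)
from endosize.simulator import add_sensor_noise, NoiseSpec
from endosize.geometry import transform_to_sensor, sensor_to_transform
from conftest import checkerboard_views, handeye_dataset, random_transform


@pytest.fixture
def spec():
    return CheckerboardSpec(inner_cols=8, inner_rows=9, square_size=3.0)


class TestCheckerboardSpec:
    def test_object_points_grid(self, spec):
        pts = spec.object_points()
        assert pts.shape == (72, 3)
        assert pts[:, 2].max() == 0.0
        np.testing.assert_allclose(pts[1] - pts[0], [3.0, 0, 0])

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            CheckerboardSpec(inner_cols=2, inner_rows=9)
        with pytest.raises(ValueError):
            CheckerboardSpec(square_size=0)


class TestEstimateIntrinsics:
    def test_recovers_camera_from_noiseless_corners(self, camera, spec, rng):
        views, _ = checkerboard_views(camera, spec, 50, rng)
        res = estimate_intrinsics(views, spec, image_size=(480, 480))
        assert res.camera.fx == pytest.approx(camera.fx, rel=0.01)
        assert res.camera.fy == pytest.approx(camera.fy, rel=0.01)
        assert res.camera.k1 == pytest.approx(camera.k1, abs=0.01)
        assert res.rmse_px <= 0.05

    def test_unusable_view_skipped(self, camera, spec, rng):
        views, _ = checkerboard_views(camera, spec, 5, rng)
        blank = np.zeros((480, 480), dtype=np.uint8)
        with pytest.warns(UserWarning, match="skipped"):
            res = estimate_intrinsics(views[:4] + [blank], spec,
                                      image_size=(480, 480))
        assert res.used_views == [0, 1, 2, 3]

    def test_too_few_views(self, camera, spec, rng):
        views, _ = checkerboard_views(camera, spec, 2, rng)
        with pytest.raises(CalibrationError):
            estimate_intrinsics(views, spec, image_size=(480, 480))

    def test_extrinsics_reproject(self, camera, spec, rng):
        views, poses = checkerboard_views(camera, spec, 10, rng)
        res = estimate_intrinsics(views, spec, image_size=(480, 480))
        # recovered extrinsics match the generating poses
        for T_est, T_true in zip(res.extrinsics, poses):
            np.testing.assert_allclose(T_est.as_matrix(), T_true.as_matrix(),
                                       atol=1e-5)


class TestDetectCheckerboard:
    def test_rendered_board_detected_in_order(self, spec, rng):
        # render a moderately tilted board through a homography
        from endosize.calibration import estimate_homography, _apply_homography
        from skimage.transform import warp, ProjectiveTransform

        cell = 28
        rows, cols = spec.inner_rows + 1, spec.inner_cols + 1
        tile = np.indices((rows * cell, cols * cell)).sum(axis=0)
        board = (((np.indices((rows, cols)).sum(axis=0)) % 2)
                 .repeat(cell, axis=0).repeat(cell, axis=1)).astype(float)
        img = np.full((420, 420), 0.7)
        corners_src = np.array(
            [[cell, cell], [cols * cell - cell, cell],
             [cols * cell - cell, rows * cell - cell],
             [cell, rows * cell - cell]], float)
        corners_dst = np.array([[70, 60], [340, 80], [330, 350], [60, 330]],
                               float)
        H = estimate_homography(corners_src, corners_dst)
        tf = ProjectiveTransform(np.linalg.inv(H))
        warped = warp(board, tf, output_shape=img.shape, cval=0.7)
        mask = warp(np.ones_like(board), tf, output_shape=img.shape, cval=0)
        img = np.where(mask > 0.5, warped, img)

        detected = detect_checkerboard(img, spec)
        assert detected is not None
        # expected inner corners through the same homography
        obj = spec.object_points()[:, :2] / spec.square_size * cell + cell
        expected = _apply_homography(H, obj)
        np.testing.assert_allclose(detected, expected, atol=1.0)

    def test_blank_image_returns_none(self, spec):
        assert detect_checkerboard(np.zeros((200, 200)), spec) is None


class TestBuildMotions:
    def test_identical_poses_give_identity(self, rng):
        T = random_transform(rng, from_frame="pattern", to_frame="camera")
        S = random_transform(rng, from_frame="sensor", to_frame="generator")
        motions = build_motions([T, T], [S, S])
        np.testing.assert_allclose(motions[0].A.as_matrix(), np.eye(4),
                                   atol=1e-12)
        np.testing.assert_allclose(motions[0].B.as_matrix(), np.eye(4),
                                   atol=1e-12)

    def test_construction_satisfies_hand_eye_identity(self, rng):
        extrinsics, sensors, X = handeye_dataset(rng, n_poses=8)
        for m in build_motions(extrinsics, sensors, pairing="all"):
            lhs = compose(m.A, X).as_matrix()
            rhs = compose(X, m.B).as_matrix()
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_pairing_counts(self, rng):
        extrinsics, sensors, _ = handeye_dataset(rng, n_poses=6)
        assert len(build_motions(extrinsics, sensors, "consecutive")) == 5
        assert len(build_motions(extrinsics, sensors, "all")) == 15

    def test_length_mismatch(self, rng):
        extrinsics, sensors, _ = handeye_dataset(rng, n_poses=4)
        with pytest.raises(ValueError):
            build_motions(extrinsics[:3], sensors)


def _motion_about(axis, angle_deg, rng):
    R = Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis, float)
                             ).as_matrix()
    A = RigidTransform(R, rng.uniform(-5, 5, 3))
    return MotionPair(A=A, B=A)


class TestSelectMotions:
    def test_identity_selection(self, rng):
        motions = [_motion_about([0, 0, 1], a, rng) for a in (10, 20, 30)]
        out = select_motions(motions, k=3, min_angle_deg=0.0)
        assert len(out) == 3

    def test_prefers_spread_axes(self, rng):
        mx1 = _motion_about([1, 0, 0], 15, rng)
        mx2 = _motion_about([1, 0, 0], 18, rng)
        mz = _motion_about([0, 0, 1], 12, rng)
        out = select_motions([mx1, mx2, mz], k=2)
        axes = sorted(tuple(np.abs(np.round(
            Rotation.from_matrix(m.A.rotation).as_rotvec()
            / np.linalg.norm(Rotation.from_matrix(m.A.rotation).as_rotvec())
        )).astype(int)) for m in out)
        assert axes == [(0, 0, 1), (1, 0, 0)]

    def test_small_rotations_dropped_with_warning(self, rng):
        motions = [_motion_about([1, 0, 0], 2, rng),
                   _motion_about([0, 1, 0], 15, rng)]
        with pytest.warns(UserWarning):
            out = select_motions(motions, k=2, min_angle_deg=5.0)
        assert len(out) == 1

    def test_selection_not_worse_than_random_subset(self, rng):
        """When the capture contains many near-useless small rotations,
        axis-spread selection should beat a random subset of the same size
        on noisy hand-eye recovery (median over trials)."""
        noise = NoiseSpec(sigma_t=0.73, sigma_r=0.61, sigma_px=0, seed=0)
        sel_err, rand_err = [], []
        for trial in range(30):
            trial_rng = np.random.default_rng(100 + trial)
            X = random_transform(trial_rng, scale_mm=20.0,
                                 from_frame="sensor", to_frame="camera")
            motions = []
            for i in range(20):
                ang = trial_rng.uniform(1, 4) if i % 2 else trial_rng.uniform(15, 40)
                axis = trial_rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                A = RigidTransform(
                    Rotation.from_rotvec(np.radians(ang) * axis).as_matrix(),
                    trial_rng.uniform(-15, 15, 3))
                Bm = (invert(X).as_matrix() @ A.as_matrix() @ X.as_matrix())
                B = RigidTransform.from_matrix(Bm, "sensor", "generator")
                # sensor-side noise on B
                Bn = sensor_to_transform(add_sensor_noise(
                    transform_to_sensor(B), noise, trial_rng)
                ).relabel("scene", "scene")
                motions.append(MotionPair(A=A, B=Bn))
            selected = select_motions(motions, k=8, min_angle_deg=5.0)
            ridx = trial_rng.choice(len(motions), size=8, replace=False)
            randoms = [motions[i] for i in ridx]

            def err(ms):
                T = handeye_solve(ms).T
                return np.linalg.norm(T.translation - X.translation)

            sel_err.append(err(selected))
            rand_err.append(err(randoms))
        assert np.median(sel_err) <= np.median(rand_err)


class TestHandEyeSolve:
    def test_equal_motions_give_identity(self, rng):
        motions = []
        for axis in ([1, 0, 0], [0, 1, 0], [0.5, 0.5, 0.7]):
            motions.append(_motion_about(axis, 25, rng))
        res = handeye_solve(motions)
        np.testing.assert_allclose(res.T.as_matrix(), np.eye(4), atol=1e-9)

    def test_exact_recovery_noiseless(self, rng):
        extrinsics, sensors, X = handeye_dataset(rng, n_poses=11)
        res = handeye_solve(build_motions(extrinsics, sensors))
        assert np.linalg.norm(res.T.rotation - X.rotation) <= 1e-8
        assert np.linalg.norm(res.T.translation - X.translation) <= 1e-6
        assert res.residual_rotation <= 1e-8
        assert res.residual_translation <= 1e-8

    def test_matches_independent_rotation_solver(self, rng):
        """Cross-check the Kronecker linear solve against the classical
        two-stage rotation-axis solution (log-map least squares)."""
        extrinsics, sensors, X = handeye_dataset(rng, n_poses=9)
        motions = build_motions(extrinsics, sensors)
        res = handeye_solve(motions)
        # the hand-eye rotation maps each sensor-motion rotation axis onto
        # the matching camera-motion axis; solve that mapping by Kabsch
        N = np.zeros((3, 3))
        for m in motions:
            a = Rotation.from_matrix(m.A.rotation).as_rotvec()
            b = Rotation.from_matrix(m.B.rotation).as_rotvec()
            N += np.outer(a, b)
        U, _, Vt = np.linalg.svd(N)
        R_oracle = U @ np.diag([1, 1, np.linalg.det(U @ Vt)]) @ Vt
        np.testing.assert_allclose(res.T.rotation, R_oracle, atol=1e-6)

    def test_parallel_axes_degenerate(self, rng):
        motions = [
            MotionPair(A=_motion_about([0, 0, 1], 10, rng).A,
                       B=_motion_about([0, 0, 1], 10, rng).A),
            MotionPair(A=_motion_about([0, 0, 1], 25, rng).A,
                       B=_motion_about([0, 0, 1], 25, rng).A),
        ]
        with pytest.raises(DegenerateMotionsError):
            handeye_solve(motions)

    def test_too_few_motions(self, rng):
        with pytest.raises(ValueError):
            handeye_solve([_motion_about([1, 0, 0], 20, rng)])

    def test_vec_convention_self_consistent(self, rng):
        """Re-substituting the solved rotation into the rotation equation
        reproduces the reported rotation residual."""
        extrinsics, sensors, X = handeye_dataset(rng, n_poses=8)
        motions = build_motions(extrinsics, sensors)
        res = handeye_solve(motions)
        recomputed = np.mean([
            np.linalg.norm(m.A.rotation @ res.T.rotation
                           - res.T.rotation @ m.B.rotation)
            for m in motions])
        assert recomputed == pytest.approx(res.residual_rotation, abs=1e-12)

    def test_noise_monotonicity(self, rng):
        """Median recovery error is non-decreasing in sensor noise."""
        medians = []
        for sigma in (0.0, 0.73, 1.5):
            errs = []
            for trial in range(30):
                trial_rng = np.random.default_rng(500 + trial)
                extrinsics, sensors, X = handeye_dataset(trial_rng, n_poses=10)
                noise = NoiseSpec(sigma_t=sigma, sigma_r=sigma * 0.8,
                                  sigma_px=0)
                noisy = [sensor_to_transform(add_sensor_noise(
                    transform_to_sensor(S), noise, trial_rng))
                    for S in sensors] if sigma else sensors
                res = handeye_solve(build_motions(extrinsics, noisy))
                errs.append(np.linalg.norm(res.T.translation - X.translation))
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]
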