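import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endosize import simulator as sim
from endosize.geometry import (
    RigidTransform,
    SensorReading,
    compose,
    invert,
    project,
    sensor_to_transform,
    undistort_points,
)
from endosize.reconstruction import (
    InsufficientBaselineError,
    distance_to_landmark,
    fit_ellipse_3d,
    polyp_location,
    relative_camera_pose,
    triangulate,
)
from conftest import random_transform


def lateral_relpose(baseline=10.0):
    return RigidTransform(np.eye(3), [baseline, 0, 0], "camera", "camera")


class TestRelativeCameraPose:
    def test_identical_readings_give_identity(self, rng):
        r = SensorReading(rng.uniform(-50, 50, 3), 10.0, -20.0, 30.0)
        X = random_transform(rng, from_frame="sensor", to_frame="camera")
        rel = relative_camera_pose(r, r, X)
        np.testing.assert_allclose(rel.as_matrix(), np.eye(4), atol=1e-12)

    def test_identity_handeye_equals_sensor_motion(self, rng):
        r1 = SensorReading(rng.uniform(-50, 50, 3), 10.0, 5.0, 0.0)
        r2 = SensorReading(rng.uniform(-50, 50, 3), -15.0, 12.0, 40.0)
        X = RigidTransform.identity().relabel("sensor", "camera")
        rel = relative_camera_pose(r1, r2, X)
        expected = compose(invert(sensor_to_transform(r1)),
                           sensor_to_transform(r2))
        np.testing.assert_allclose(rel.as_matrix(), expected.as_matrix(),
                                   atol=1e-9)

    def test_matches_simulator_ground_truth(self, scene):
        p1, p2 = sim.sample_pose_pair(scene, 1, 30.0, seed=2)
        o1, o2 = sim.make_observation_pair(scene, p1, p2)
        rel = relative_camera_pose(o1.sensor, o2.sensor, scene.hand_eye)
        truth = compose(invert(p1), p2)
        np.testing.assert_allclose(rel.as_matrix(), truth.as_matrix(),
                                   atol=1e-9)


class TestTriangulate:
    def test_known_point_exact(self, pinhole):
        X = np.array([0.0, 0.0, 30.0])
        rel = lateral_relpose(10.0)
        uv1 = project(pinhole, RigidTransform.identity("camera"), X)
        uv2 = project(pinhole, invert(rel), X)
        out, valid = triangulate(pinhole, rel, uv1, uv2)
        assert valid.all()
        np.testing.assert_allclose(out[0], X, atol=1e-6)

    def test_many_random_points_roundtrip(self, pinhole, rng):
        rel = RigidTransform(
            Rotation.from_euler("y", 8, degrees=True).as_matrix(),
            [12.0, 2.0, 1.0], "camera", "camera")
        X = np.column_stack([rng.uniform(-8, 8, (100, 2)),
                             rng.uniform(25, 60, 100)])
        uv1 = project(pinhole, RigidTransform.identity("camera"), X)
        uv2 = project(pinhole, invert(rel), X)
        out, valid = triangulate(pinhole, rel, uv1, uv2)
        assert valid.all()
        assert np.abs(out - X).max() <= 1e-6

    def test_midpoint_agrees_with_dlt(self, pinhole, rng):
        rel = lateral_relpose(10.0)
        X = np.column_stack([rng.uniform(-5, 5, (20, 2)),
                             rng.uniform(25, 50, 20)])
        uv1 = project(pinhole, RigidTransform.identity("camera"), X)
        uv2 = project(pinhole, invert(rel), X)
        dlt, _ = triangulate(pinhole, rel, uv1, uv2)
        mid, _ = triangulate(pinhole, rel, uv1, uv2, method="midpoint")
        np.testing.assert_allclose(dlt, mid, atol=1e-6)

    def test_point_behind_camera_flagged(self, pinhole):
        rel = lateral_relpose(10.0)
        # negative-disparity correspondence: consistent only with a point
        # behind the cameras
        uv1 = np.array([[30.0, 240.0]])
        uv2 = np.array([[600.0, 240.0]])
        good1 = project(pinhole, RigidTransform.identity("camera"),
                        np.array([0, 0, 40.0]))
        good2 = project(pinhole, invert(rel), np.array([0, 0, 40.0]))
        pts, valid = triangulate(pinhole, rel,
                                 np.vstack([uv1, good1]),
                                 np.vstack([uv2, good2]))
        assert not valid[0]
        assert valid[1]
        assert np.isnan(pts[0]).all()

    def test_insufficient_baseline_refused(self, pinhole):
        rel = lateral_relpose(0.1)
        with pytest.raises(InsufficientBaselineError, match="insufficient"):
            triangulate(pinhole, rel, np.zeros((3, 2)), np.zeros((3, 2)))

    def test_error_grows_as_baseline_shrinks(self, pinhole, rng):
        """Reconstruction error under fixed pixel noise explodes for small
        baselines — the failure mode behind near-static movement types."""
        X = np.column_stack([rng.uniform(-5, 5, (80, 2)),
                             rng.uniform(25, 35, 80)])
        errs = {}
        for b in (1.0, 10.0):
            rel = lateral_relpose(b)
            uv1 = project(pinhole, RigidTransform.identity("camera"), X)
            uv2 = project(pinhole, invert(rel), X)
            noise = rng.normal(0, 0.2, uv2.shape)
            out, valid = triangulate(pinhole, rel, uv1, uv2 + noise)
            errs[b] = np.nanmedian(np.linalg.norm(out - X, axis=1))
        assert errs[1.0] > errs[10.0]

    def test_rigid_invariance_of_size(self, scene, rng):
        """A global rigid transform applied to both camera poses leaves the
        relative pose, hence the measured size, unchanged."""
        p1, p2 = sim.sample_pose_pair(scene, 1, 30.0, seed=5)
        G = random_transform(rng, from_frame="generator",
                             to_frame="generator")
        rel1 = compose(invert(p1), p2)
        rel2 = compose(invert(compose(G, p1)), compose(G, p2))
        np.testing.assert_allclose(rel1.as_matrix(), rel2.as_matrix(),
                                   atol=1e-9)


def ellipse_points(a, b, center, e1, e2, n=100, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return (np.asarray(center)
            + np.outer(a * np.cos(t), e1) + np.outer(b * np.sin(t), e2))


class TestFitEllipse3D:
    def setup_method(self):
        n = np.array([0.3, -0.2, 0.93])
        self.normal = n / np.linalg.norm(n)
        e1 = np.cross([0, 0, 1.0], self.normal)
        self.e1 = e1 / np.linalg.norm(e1)
        self.e2 = np.cross(self.normal, self.e1)
        self.center = np.array([5.0, -3.0, 40.0])

    def test_circle_in_tilted_plane(self):
        pts = ellipse_points(5.0, 5.0, self.center, self.e1, self.e2)
        e = fit_ellipse_3d(pts)
        assert e.major_axis_length == pytest.approx(10.0, abs=1e-9)
        assert e.minor_axis_length == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_allclose(e.center, self.center, atol=1e-9)
        assert abs(abs(np.dot(e.normal, self.normal)) - 1) < 1e-9

    def test_ellipse_axis_lengths(self):
        pts = ellipse_points(6.0, 4.0, self.center, self.e1, self.e2)
        e = fit_ellipse_3d(pts)
        assert e.major_axis_length == pytest.approx(12.0, abs=1e-6)
        assert e.minor_axis_length == pytest.approx(8.0, abs=1e-6)
        assert abs(np.dot(e.normal, e.major_axis_direction)) <= 1e-9

    def test_noisy_ellipse_major_within_2pct(self, rng):
        pts = ellipse_points(6.0, 4.0, self.center, self.e1, self.e2)
        pts = pts + rng.normal(0, 0.1, pts.shape)
        e = fit_ellipse_3d(pts)
        assert e.major_axis_length == pytest.approx(12.0, rel=0.02)
        assert e.rms_residual_mm < 0.3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ellipse_3d(np.zeros((5, 3)))

    def test_collinear_points(self):
        pts = np.outer(np.linspace(0, 1, 20), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_ellipse_3d(pts)

    def test_degenerate_arc_uses_enclosing_fallback(self, rng):
        # a tiny arc fragment plus noise defeats the direct conic fit
        t = np.linspace(0, 0.25, 12)
        pts = (self.center + np.outer(50 * np.cos(t), self.e1)
               + np.outer(50 * np.sin(t), self.e2))
        pts = pts + rng.normal(0, 0.8, pts.shape)
        e = fit_ellipse_3d(pts)
        assert e.major_axis_length > 0
        # either route must report a usable ellipse; the fallback is flagged
        assert isinstance(e.fallback_enclosing, bool)


class TestLocation:
    def test_identity_chain_keeps_center(self):
        pts = ellipse_points(5, 5, [1.0, 2.0, 30.0], [1, 0, 0], [0, 1, 0])
        e = fit_ellipse_3d(pts)
        r = SensorReading(np.zeros(3), 0, 0, 0)
        X = RigidTransform.identity().relabel("sensor", "camera")
        np.testing.assert_allclose(polyp_location(e, r, X), e.center,
                                   atol=1e-12)

    def test_translation_only_chain(self):
        pts = ellipse_points(5, 5, [0.0, 0.0, 30.0], [1, 0, 0], [0, 1, 0])
        e = fit_ellipse_3d(pts)
        r = SensorReading(np.array([0, 0, 100.0]), 0, 0, 0)
        X = RigidTransform.identity().relabel("sensor", "camera")
        out = polyp_location(e, r, X)
        assert out[2] == pytest.approx(e.center[2] + 100.0)

    def test_matches_simulator_ground_truth(self, scene):
        p1, p2 = sim.sample_pose_pair(scene, 1, 26.7, seed=3)
        o1, o2 = sim.make_observation_pair(scene, p1, p2)
        cam = scene.camera
        b1 = undistort_points(cam, o1.border_px)
        b2 = undistort_points(cam, o2.border_px)
        rel = relative_camera_pose(o1.sensor, o2.sensor, scene.hand_eye)
        pts, valid = triangulate(cam, rel, b1, b2)
        e = fit_ellipse_3d(pts[valid])
        center_g = polyp_location(e, o1.sensor, scene.hand_eye)
        np.testing.assert_allclose(center_g, scene.polyp_center, atol=1e-6)


class TestDistanceToLandmark:
    def test_coincident_points(self):
        assert distance_to_landmark(np.zeros(3), np.zeros(3)) == 0.0

    def test_z_line_magnitude(self):
        # distance on the scale of a gastroesophageal-junction measurement
        assert distance_to_landmark(
            np.zeros(3), np.array([0, 0, 223.57])) == pytest.approx(223.57)

    def test_matches_formula(self, rng):
        for _ in range(20):
            p = rng.uniform(-200, 200, 3)
            q = rng.uniform(-200, 200, 3)
            assert distance_to_landmark(p, q) == pytest.approx(
                np.sqrt(((p - q) ** 2).sum()))

    def test_accepts_sensor_reading(self, rng):
        r = SensorReading(np.array([1.0, 2.0, 2.0]), 0, 0, 0)
        assert distance_to_landmark(np.zeros(3), r) == pytest.approx(3.0)
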