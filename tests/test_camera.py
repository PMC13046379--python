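"""Camera model, pose estimation, triangulation, world-frame merging, RMSE."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from marmogaze.camera import (
    BehindCameraError,
    Camera,
    CameraIntrinsics,
    CameraPose,
    CameraRig,
    DegenerateGeometryError,
    backproject_ray,
    estimate_pose,
    load_calibration,
    merge_world_frames,
    project,
    rmse,
    save_calibration,
    triangulate_multiview,
    triangulate_pair,
)
from conftest import make_camera


class TestProject:
    def test_principal_point_identity(self, axis_camera):
        assert np.allclose(project(axis_camera, [0, 0, 500.0]), [960, 540])

    def test_pinhole_arithmetic(self, axis_camera):
        # x' = fx * X / Z + cx = 1000 * 100 / 1000 + 960
        assert np.allclose(project(axis_camera, [100.0, 0.0, 1000.0]), [1060, 540])

    def test_behind_camera_raises(self, axis_camera):
        with pytest.raises(BehindCameraError):
            project(axis_camera, [0.0, 0.0, -10.0])

    def test_nonfinite_raises(self, axis_camera):
        with pytest.raises(ValueError):
            project(axis_camera, [np.nan, 0.0, 100.0])

    def test_radial_distortion_moves_off_axis_points(self, axis_camera):
        intr = CameraIntrinsics(fx=1000, fy=1000, cx=960, cy=540, distortion=(0.1,))
        cam = Camera("d", intr, axis_camera.pose)
        on_axis = project(cam, [0, 0, 1000.0])
        off_axis = project(cam, [100.0, 0, 1000.0])
        assert np.allclose(on_axis, [960, 540])
        # r^2 = 0.01 -> factor 1.001 -> x' = 1000 * 0.1001 + 960
        assert np.isclose(off_axis[0], 1060.1)


class TestBackprojectRay:
    def test_principal_point_gives_optical_axis(self, axis_camera):
        origin, direction = backproject_ray(axis_camera, [960, 540])
        assert np.allclose(origin, 0)
        assert np.allclose(direction, [0, 0, 1])

    def test_round_trip_random_points(self, axis_camera):
        rng = np.random.default_rng(42)
        pts = rng.uniform([-300, -150, 500], [300, 150, 2000], size=(100, 3))
        for p in pts:
            px = project(axis_camera, p)
            origin, d = backproject_ray(axis_camera, px)
            # the ray must pass through p: reproject the closest ray point
            t = np.dot(p - origin, d)
            err = np.linalg.norm(project(axis_camera, origin + t * d) - px)
            assert err < 1e-6

    def test_round_trip_with_distortion(self):
        cam = make_camera([0, 0, 0], [0, 0, 1], distortion=(0.05, -0.01))
        p = np.array([120.0, -60.0, 900.0])
        px = project(cam, p)
        origin, d = backproject_ray(cam, px)
        t = np.dot(p - origin, d)
        assert np.linalg.norm(origin + t * d - p) < 1e-6

    def test_degenerate_intrinsics_rejected(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=0.0, fy=1000.0, cx=960, cy=540)


class TestEstimatePose:
    def _random_pose_points(self, seed, n=6):
        rng = np.random.default_rng(seed)
        R = Rotation.from_rotvec(rng.normal(size=3) * 0.4).as_matrix()
        pts = rng.uniform([-200, -200, -200], [200, 200, 200], size=(n, 3))
        center = np.array([0.0, 0.0, -1200.0]) + rng.normal(size=3) * 50
        t = -R @ center
        pose = CameraPose(R, t)
        intr = CameraIntrinsics(fx=1000, fy=1000, cx=960, cy=540)
        cam = Camera("gt", intr, pose)
        return pts, project(cam, pts), intr, pose

    def test_noiseless_round_trip(self):
        pts, obs, intr, true_pose = self._random_pose_points(0)
        est = estimate_pose(pts, obs, intr)
        assert np.linalg.norm(est.rotation - true_pose.rotation) < 1e-6
        assert np.linalg.norm(est.translation - true_pose.translation) < 1e-3

    def test_four_point_minimal_case(self):
        pts, obs, intr, true_pose = self._random_pose_points(3, n=4)
        est = estimate_pose(pts, obs, intr)
        cam = Camera("e", intr, est)
        assert rmse(obs, project(cam, pts)) < 1e-6

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float) * 100
        obs = np.tile([960.0, 540.0], (4, 1))
        with pytest.raises(DegenerateGeometryError):
            estimate_pose(pts, obs, CameraIntrinsics(fx=1000, fy=1000, cx=960, cy=540))

    def test_noisy_observations_bounded_error(self):
        """1 px noise gives reprojection RMSE near the noise level."""
        rng = np.random.default_rng(11)
        rmses = []
        for seed in range(20):
            pts, obs, intr, _ = self._random_pose_points(seed + 100, n=10)
            noisy = obs + rng.normal(0, 1.0, size=obs.shape)
            est = estimate_pose(pts, noisy, intr)
            cam = Camera("e", intr, est)
            rmses.append(rmse(noisy, project(cam, pts)))
        # within a factor 2 of the 1 px noise level on average
        assert 0.5 < np.mean(rmses) < 2.0


class TestTriangulation:
    def test_noiseless_pair_round_trip(self, camera_pair):
        cam_a, cam_b = camera_pair
        p = np.array([100.0, 200.0, 150.0])
        est = triangulate_pair(cam_a, project(cam_a, p), cam_b, project(cam_b, p))
        assert np.linalg.norm(est - p) < 1e-6

    def test_identical_poses_rejected(self, camera_pair):
        cam_a, _ = camera_pair
        with pytest.raises(DegenerateGeometryError):
            triangulate_pair(cam_a, [960, 540], cam_a, [960, 540])

    def test_noisy_pair_matches_least_squares_oracle(self, camera_pair):
        """Midpoint of the common perpendicular equals the minimizer of the
        summed squared point-to-ray distance (refined numerically)."""
        cam_a, cam_b = camera_pair
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform([0, 50, 50], [250, 250, 250])
            pa = project(cam_a, p) + rng.uniform(-2, 2, 2)
            pb = project(cam_b, p) + rng.uniform(-2, 2, 2)
            est = triangulate_pair(cam_a, pa, cam_b, pb)
            rays = [backproject_ray(cam_a, pa), backproject_ray(cam_b, pb)]

            def cost(x):
                return sum(
                    np.sum((x - (o + np.dot(x - o, d) * d)) ** 2) for o, d in rays
                )

            res = minimize(cost, p, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-15})
            assert np.linalg.norm(est - res.x) < 1e-6
            assert cost(est) <= res.fun + 1e-9

    def test_multiview_equals_pairwise_mean(self, camera_pair):
        cam_a, cam_b = camera_pair
        cam_c = make_camera([100.0, 500.0, 300.0], [100.0, 150.0, 150.0], "C")
        p = np.array([120.0, 140.0, 160.0])
        rng = np.random.default_rng(8)
        obs = [(c, project(c, p) + rng.normal(0, 1, 2)) for c in (cam_a, cam_b, cam_c)]
        est = triangulate_multiview(obs)
        pairs = [
            triangulate_pair(obs[i][0], obs[i][1], obs[j][0], obs[j][1])
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert np.allclose(est, np.mean(pairs, axis=0), atol=1e-12)

    def test_multiview_noiseless_exact(self, camera_pair):
        cam_a, cam_b = camera_pair
        cam_c = make_camera([100.0, 500.0, 300.0], [100.0, 150.0, 150.0], "C")
        cam_d = make_camera([-200.0, 300.0, 400.0], [100.0, 150.0, 150.0], "D")
        p = np.array([90.0, 180.0, 120.0])
        obs = [(c, project(c, p)) for c in (cam_a, cam_b, cam_c, cam_d)]
        assert np.linalg.norm(triangulate_multiview(obs) - p) < 1e-6

    def test_single_view_returns_missing(self, camera_pair):
        assert triangulate_multiview([(camera_pair[0], [960, 540])]) is None


class TestMergeWorldFrames:
    def _rig_with_offset(self, offset):
        cams = [
            make_camera([-400, 0, 0], [100, 150, 150], cid)
            for cid in ("ML1", "ML2", "OL1", "OL2")
        ]
        right = [
            Camera(cid, c.intrinsics, c.pose, group="right_arena")
            for cid, c in zip(("MR1", "MR2", "OR1", "OR2"), cams)
        ]
        cams = [
            Camera(c.id, c.intrinsics, c.pose, group="left_arena") for c in cams
        ]
        return CameraRig(cameras=cams + right, group_offset=np.asarray(offset, float))

    def test_offset_maps_local_origin(self):
        """Arena length 609.6 + separation 304.8 = 914.4 mm offset: a point at
        the right group's local origin projects like (914.4, 0, 0) unified."""
        rig = merge_world_frames(self._rig_with_offset([914.4, 0.0, 0.0]))
        cam = rig.by_id("MR1")
        local_origin_px_before = project(self._rig_with_offset([914.4, 0, 0]).by_id("MR1"), [0.0, 0.0, 100.0])
        unified_px = project(cam, [914.4, 0.0, 100.0])
        assert np.allclose(local_origin_px_before, unified_px, atol=1e-9)

    def test_zero_offset_is_identity(self):
        rig = self._rig_with_offset([0.0, 0.0, 0.0])
        merged = merge_world_frames(rig)
        for a, b in zip(rig.cameras, merged.cameras):
            assert np.allclose(a.pose.translation, b.pose.translation)

    def test_idempotent(self):
        rig = self._rig_with_offset([914.4, 0.0, 0.0])
        once = merge_world_frames(rig)
        twice = merge_world_frames(once)
        for a, b in zip(once.cameras, twice.cameras):
            assert np.array_equal(a.pose.translation, b.pose.translation)


class TestRmse:
    def test_identical_lists_zero(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert rmse(pts, pts) == 0.0

    def test_single_offset(self):
        assert np.isclose(rmse([[10.0, 10.0]], [[13.0, 14.0]]), 5.0)

    def test_two_features_mixed(self):
        gt = [[1.0, 1.0], [5.0, 5.0]]
        est = [[1.0, 1.0], [8.0, 9.0]]
        assert np.isclose(rmse(gt, est), np.sqrt(25 / 2))

    def test_occluded_sentinel_excluded(self):
        gt = [[0.0, 0.0], [5.0, 5.0]]  # first feature occluded
        est = [[100.0, 100.0], [8.0, 9.0]]
        assert np.isclose(rmse(gt, est), 5.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        gt = rng.normal(size=(10, 3))
        est = gt + rng.normal(0, 0.5, size=(10, 3))
        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        t = np.array([5.0, -2.0, 7.0])
        assert np.isclose(rmse(gt, est), rmse(gt @ R.T + t, est @ R.T + t))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestCalibrationIO:
    def test_round_trip_lossless(self, rig, tmp_path):
        path = tmp_path / "calib.yaml"
        save_calibration(rig, path)
        loaded = load_calibration(path)
        assert [c.id for c in loaded.cameras] == [c.id for c in rig.cameras]
        for a, b in zip(rig.cameras, loaded.cameras):
            assert np.allclose(a.pose.rotation, b.pose.rotation, atol=1e-12)
            assert np.allclose(a.pose.translation, b.pose.translation, atol=1e-12)
            assert a.group == b.group and a.sees_both_animals == b.sees_both_animals
        assert np.allclose(loaded.group_offset, rig.group_offset, atol=1e-12)
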