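"""Pinhole camera model, pose estimation, and multi-view triangulation.

The rig is two groups of four cameras, one group per arena.  Each group has
its own world frame anchored by an L-shaped reference object; the two frames
are unified by a measured inter-group translation.  World coordinates are in
millimetres; image coordinates in pixels with the origin at the top-left
corner, x right, y down.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


class BehindCameraError(ValueError):
    """A 3D point has non-positive depth in the camera frame."""


class DegenerateGeometryError(ValueError):
    """The geometric configuration does not determine a solution."""


class ConvergenceError(RuntimeError):
    """Iterative refinement failed to converge; diagnostics attached."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with optional radial distortion.

    fx, fy are focal lengths in pixels, (cx, cy) the principal point.
    ``distortion`` holds radial coefficients (k1, k2, ...); all-zero means an
    ideal linear lens.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    image_width: int = 1920
    image_height: int = 1080
    distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (0 <= self.cx < self.image_width and 0 <= self.cy < self.image_height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rigid transform: x_cam = R @ x_world + t (t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation


@dataclass(frozen=True)
class Camera:
    id: str
    intrinsics: CameraIntrinsics
    pose: CameraPose
    group: str = "left_arena"
    sees_both_animals: bool = False


@dataclass
class CameraRig:
    """Eight cameras in two groups plus the measured inter-group offset."""

    cameras: list[Camera]
    group_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    merged: bool = False

    def __post_init__(self) -> None:
        self.group_offset = np.asarray(self.group_offset, dtype=float).reshape(3)
        ids = [c.id for c in self.cameras]
        if len(set(ids)) != len(ids):
            raise ValueError("camera ids must be unique within a rig")

    def by_id(self, cam_id: str) -> Camera:
        for c in self.cameras:
            if c.id == cam_id:
                return c
        raise KeyError(cam_id)

    def group_cameras(self, group: str) -> list[Camera]:
        return [c for c in self.cameras if c.group == group]


def _distort(xn: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    """Apply radial distortion to normalized image coordinates (N, 2)."""
    if not coeffs or not any(coeffs):
        return xn
    r2 = np.sum(xn**2, axis=-1, keepdims=True)
    factor = np.ones_like(r2)
    rpow = np.ones_like(r2)
    for k in coeffs:
        rpow = rpow * r2
        factor = factor + k * rpow
    return xn * factor


def _undistort(xd: np.ndarray, coeffs: tuple[float, ...], iters: int = 20) -> np.ndarray:
    """Invert radial distortion by fixed-point iteration."""
    if not coeffs or not any(coeffs):
        return xd
    xn = xd.copy()
    for _ in range(iters):
        r2 = np.sum(xn**2, axis=-1, keepdims=True)
        factor = np.ones_like(r2)
        rpow = np.ones_like(r2)
        for k in coeffs:
            rpow = rpow * r2
            factor = factor + k * rpow
        xn = xd / factor
    return xn


def project(camera: Camera, p) -> np.ndarray:
    """Project world point(s) (mm) to pixel coordinates.

    Accepts a single 3-vector or an (N, 3) array.  Raises
    :class:`BehindCameraError` if any point has non-positive depth.
    """
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite input point")
    cam_pts = pts @ camera.pose.rotation.T + camera.pose.translation
    z = cam_pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("point(s) at non-positive depth in camera frame")
    xn = cam_pts[:, :2] / z[:, None]
    xn = _distort(xn, camera.intrinsics.distortion)
    intr = camera.intrinsics
    px = np.column_stack([intr.fx * xn[:, 0] + intr.cx, intr.fy * xn[:, 1] + intr.cy])
    return px[0] if single else px


def backproject_ray(camera: Camera, p) -> tuple[np.ndarray, np.ndarray]:
    """Back-project pixel ``p`` to a world-frame ray (origin, unit direction)."""
    px = np.asarray(p, dtype=float).reshape(2)
    intr = camera.intrinsics
    xn = np.array([[(px[0] - intr.cx) / intr.fx, (px[1] - intr.cy) / intr.fy]])
    xn = _undistort(xn, intr.distortion)[0]
    d_cam = np.array([xn[0], xn[1], 1.0])
    d_world = camera.pose.rotation.T @ d_cam
    d_world /= np.linalg.norm(d_world)
    return camera.pose.center, d_world


def _reprojection_residuals(params, points3d, observations, intrinsics):
    rot = Rotation.from_rotvec(params[:3])
    cam_pts = rot.apply(points3d) + params[3:6]
    z = cam_pts[:, 2]
    z = np.where(np.abs(z) < 1e-12, 1e-12, z)
    xn = cam_pts[:, :2] / z[:, None]
    xn = _distort(xn, intrinsics.distortion)
    px = np.column_stack(
        [intrinsics.fx * xn[:, 0] + intrinsics.cx, intrinsics.fy * xn[:, 1] + intrinsics.cy]
    )
    return (px - observations).ravel()


def _dlt_pose(points3d: np.ndarray, observations: np.ndarray, intrinsics: CameraIntrinsics):
    """Direct linear transform for the full projection matrix (needs >= 6 pts)."""
    n = len(points3d)
    A = np.zeros((2 * n, 12))
    for i, (X, x) in enumerate(zip(points3d, observations)):
        Xh = np.array([*X, 1.0])
        A[2 * i, 0:4] = Xh
        A[2 * i, 8:12] = -x[0] * Xh
        A[2 * i + 1, 4:8] = Xh
        A[2 * i + 1, 8:12] = -x[1] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    M = np.linalg.inv(intrinsics.K) @ P
    scale = np.cbrt(np.linalg.det(M[:, :3]))
    if abs(scale) < 1e-12:
        return None
    M = M / scale
    U, _, Vt2 = np.linalg.svd(M[:, :3])
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        R = -R
    t = M[:, 3]
    return np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])


def _seed_poses(points3d: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start initializations for 4-5 point PnP."""
    centroid = points3d.mean(axis=0)
    span = max(np.ptp(points3d, axis=0).max(), 1.0)
    seeds = []
    for rotvec in itertools.product([0.0, np.pi / 2, np.pi, -np.pi / 2], repeat=2):
        rv = np.array([rotvec[0], rotvec[1], 0.0])
        R = Rotation.from_rotvec(rv)
        # place the camera so points sit ~3 spans in front of it
        t = np.array([0.0, 0.0, 3.0 * span]) - R.apply(centroid[None, :])[0]
        seeds.append(np.concatenate([rv, t]))
    return seeds


def estimate_pose(reference_points, observations, intrinsics: CameraIntrinsics) -> CameraPose:
    """Recover camera extrinsics from >= 4 non-collinear 3D-2D correspondences.

    Linear (DLT) initialization when six or more points are available,
    otherwise a deterministic multi-start, followed by Levenberg-Marquardt
    minimization of the mean squared reprojection error.
    """
    pts = np.asarray(reference_points, dtype=float).reshape(-1, 3)
    obs = np.asarray(observations, dtype=float).reshape(-1, 2)
    if len(pts) != len(obs):
        raise ValueError("reference_points and observations must have equal length")
    if len(pts) < 4:
        raise DegenerateGeometryError("at least 4 correspondences required")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(np.abs(centered).max(), 1.0)) < 2:
        raise DegenerateGeometryError("reference points are collinear")

    inits = []
    if len(pts) >= 6:
        dlt = _dlt_pose(pts, obs, intrinsics)
        if dlt is not None:
            inits.append(dlt)
    inits.extend(_seed_poses(pts))

    best = None
    for x0 in inits:
        try:
            res = least_squares(
                _reprojection_residuals,
                x0,
                args=(pts, obs, intrinsics),
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18 * len(pts):
            break
    if best is None:
        raise ConvergenceError("pose refinement failed for all initializations")
    rot = Rotation.from_rotvec(best.x[:3]).as_matrix()
    pose = CameraPose(rotation=rot, translation=best.x[3:6])
    # sanity: points must be in front of the recovered camera
    depths = (pts @ pose.rotation.T + pose.translation)[:, 2]
    if np.any(depths <= 0):
        raise ConvergenceError(
            f"recovered pose places points behind the camera (min depth {depths.min():.3g})"
        )
    return pose


def triangulate_pair(cam_a: Camera, p_a, cam_b: Camera, p_b) -> np.ndarray:
    """Triangulate one point from two views: midpoint of the common
    perpendicular between the two back-projected rays (least squares for two
    rays)."""
    oa, da = backproject_ray(cam_a, p_a)
    ob, db = backproject_ray(cam_b, p_b)
    if np.linalg.norm(oa - ob) < 1e-9:
        raise DegenerateGeometryError("camera centers coincide")
    cross = np.cross(da, db)
    denom = np.linalg.norm(cross) ** 2
    if denom < 1e-18:
        raise DegenerateGeometryError("rays are parallel")
    w = ob - oa
    ta = np.dot(np.cross(w, db), cross) / denom
    tb = np.dot(np.cross(w, da), cross) / denom
    return 0.5 * ((oa + ta * da) + (ob + tb * db))


def triangulate_multiview(observations) -> np.ndarray | None:
    """All-pairs triangulation averaged without weighting.

    ``observations`` is a list of (Camera, pixel) tuples.  Returns ``None``
    when fewer than two views are available (missing value, interpolated
    downstream).
    """
    if len(observations) < 2:
        return None
    results = []
    for (ca, pa), (cb, pb) in itertools.combinations(observations, 2):
        results.append(triangulate_pair(ca, pa, cb, pb))
    return np.mean(results, axis=0)


def merge_world_frames(rig: CameraRig) -> CameraRig:
    """Express right-group camera poses in the left group's world frame.

    A world point X_left relates to the right group's local frame by
    X_left = X_right + group_offset, so each right camera's translation
    becomes t - R @ group_offset.  Idempotent.
    """
    if rig.merged:
        return rig
    offset = rig.group_offset
    if not np.all(np.isfinite(offset)):
        raise ValueError("group_offset must be finite")
    cams = []
    for cam in rig.cameras:
        if cam.group == "right_arena":
            new_t = cam.pose.translation - cam.pose.rotation @ offset
            cams.append(replace(cam, pose=CameraPose(cam.pose.rotation, new_t)))
        else:
            cams.append(cam)
    return CameraRig(cameras=cams, group_offset=offset, merged=True)


OCCLUDED_2D = np.zeros(2)


def rmse(ground_truth, estimates) -> float:
    """Root mean square error over paired features.

    Each term is the Euclidean distance between a ground-truth feature and
    its estimate (pixels in 2D, mm in 3D).  Ground-truth features flagged
    occluded with the (0, 0) sentinel are excluded from the mean.
    """
    gt = np.asarray(ground_truth, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if gt.shape != est.shape or gt.size == 0:
        raise ValueError("inputs must be equal-shaped and non-empty")
    gt = np.atleast_2d(gt)
    est = np.atleast_2d(est)
    keep = ~np.all(gt == 0.0, axis=1)
    if not np.any(keep):
        raise ValueError("all features are flagged occluded")
    d2 = np.sum((gt[keep] - est[keep]) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


# ---------------------------------------------------------------------------
# calibration file IO


def save_calibration(rig: CameraRig, path) -> None:
    data = {
        "group_offset": [float(v) for v in rig.group_offset],
        "merged": bool(rig.merged),
        "cameras": [],
    }
    for c in rig.cameras:
        intr = c.intrinsics
        data["cameras"].append(
            {
                "id": c.id,
                "group": c.group,
                "sees_both_animals": bool(c.sees_both_animals),
                "K": [[intr.fx, 0.0, intr.cx], [0.0, intr.fy, intr.cy], [0.0, 0.0, 1.0]],
                "image_size": [intr.image_width, intr.image_height],
                "distortion": list(intr.distortion),
                "R": [[float(v) for v in row] for row in c.pose.rotation],
                "t": [float(v) for v in c.pose.translation],
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, default_flow_style=None, sort_keys=False)


def load_calibration(path) -> CameraRig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cams = []
    for entry in data["cameras"]:
        K = np.asarray(entry["K"], dtype=float)
        w, h = entry.get("image_size", [1920, 1080])
        intr = CameraIntrinsics(
            fx=K[0, 0],
            fy=K[1, 1],
            cx=K[0, 2],
            cy=K[1, 2],
            image_width=int(w),
            image_height=int(h),
            distortion=tuple(entry.get("distortion", [])),
        )
        pose = CameraPose(np.asarray(entry["R"], dtype=float), np.asarray(entry["t"], dtype=float))
        cams.append(
            Camera(
                id=entry["id"],
                intrinsics=intr,
                pose=pose,
                group=entry["group"],
                sees_both_animals=bool(entry["sees_both_animals"]),
            )
        )
    return CameraRig(
        cameras=cams,
        group_offset=np.asarray(data["group_offset"], dtype=float),
        merged=bool(data.get("merged", False)),
    )
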