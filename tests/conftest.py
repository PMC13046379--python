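import numpy as np
import pytest

from marmogaze.camera import Camera, CameraIntrinsics, CameraPose
from marmogaze import synthetic as syn


def make_camera(center, target, cam_id="C0", fx=1000.0, fy=1000.0, distortion=()):
    """Camera at ``center`` looking at ``target`` (world mm)."""
    center = np.asarray(center, dtype=float)
    target = np.asarray(target, dtype=float)
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(z, up)) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    intr = CameraIntrinsics(fx=fx, fy=fy, cx=960.0, cy=540.0, distortion=distortion)
    return Camera(id=cam_id, intrinsics=intr, pose=CameraPose(R, -R @ center))


@pytest.fixture
def axis_camera():
    """Camera at the origin looking down +Z with fx = fy = 1000."""
    intr = CameraIntrinsics(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0)
    return Camera(id="axis", intrinsics=intr, pose=CameraPose(np.eye(3), np.zeros(3)))


@pytest.fixture
def camera_pair():
    return (
        make_camera([-400.0, 0.0, 0.0], [100.0, 150.0, 150.0], "A"),
        make_camera([500.0, -400.0, 100.0], [100.0, 150.0, 150.0], "B"),
    )


@pytest.fixture(scope="session")
def rig():
    return syn.default_rig()


@pytest.fixture(scope="session")
def small_scene(rig):
    """60-frame noiseless scene covering four scripted gaze states."""
    script = syn.BehaviorScript(
        [
            ("partner_a_to_b", 15, "stationary"),
            ("none", 15, "stationary"),
            ("joint", 15, "stationary"),
            ("partner_b_to_a", 15, "stationary"),
        ]
    )
    return syn.simulate_dyad(script, rig=rig, seed=7)
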