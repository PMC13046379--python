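"""Synthetic dyad scenes: ground-truth trajectories, camera rig, and
detector-like corrupted keypoint tables.

Emulates the physical setup: two transparent box arenas (609.6 x 304.8 x
304.8 mm) separated by a 304.8 mm gap, with a monitor beyond each outer end
and two groups of four cameras — per group, two "monitor-end" cameras that
see both animals down the long axis and two "middle" cameras that see only
their own arena from the side.  Sampling is 30 frames/s.

Scripted behaviors pose rigid 6-landmark face frames so that each segment's
requested dyadic gaze state holds under the noiseless classification
oracle (the generator verifies itself and refuses unrealizable segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .camera import (
    Camera,
    CameraIntrinsics,
    CameraPose,
    CameraRig,
    merge_world_frames,
    project,
)
from .gaze import FEATURE_ORDER, FaceFrame3D, gaze_cone
from .intersections import FacialTriangle
from .states import GazeState, classify_frame

FPS = 30.0


@dataclass(frozen=True)
class ArenaGeometry:
    """The two-box arena: dimensions and inter-arena separation, in mm."""

    length: float = 609.6
    width: float = 304.8
    height: float = 304.8
    separation: float = 304.8

    @property
    def group_offset(self) -> np.ndarray:
        """Right group's local origin in the unified (left) world frame."""
        return np.array([self.length + self.separation, 0.0, 0.0])

    def box(self, animal: int) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of an animal's arena in the unified frame."""
        x0 = 0.0 if animal == 0 else self.length + self.separation
        return (
            np.array([x0, 0.0, 0.0]),
            np.array([x0 + self.length, self.width, self.height]),
        )

    def overall_bounds(self, inflate: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box of both arenas (including the gap), inflated."""
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([2 * self.length + self.separation, self.width, self.height])
        pad = inflate * (hi - lo)
        return lo - pad, hi + pad


# rigid face template in face-local coordinates (mm): x right, y up, z = gaze.
# Eye spacing 20, blaze 12 above the eye midline, mouth 15 below, tufts 25
# lateral and 8 behind the facial plane — plausible marmoset scale.
FACE_TEMPLATE = {
    "right_eye": np.array([-10.0, 0.0, 0.0]),
    "left_eye": np.array([10.0, 0.0, 0.0]),
    "central_blaze": np.array([0.0, 12.0, 0.0]),
    "mouth": np.array([0.0, -15.0, 0.0]),
    "right_tuft": np.array([-25.0, 0.0, -8.0]),
    "left_tuft": np.array([25.0, 0.0, -8.0]),
}


@dataclass
class BehaviorScript:
    """Ordered (state, duration_frames, motion_profile) segments."""

    segments: list[tuple[str, int, str]]  # profile in {stationary, translate, head_turn}

    def __post_init__(self) -> None:
        valid_states = {s.value for s in GazeState}
        norm = []
        for seg in self.segments:
            state, dur = seg[0], int(seg[1])
            profile = seg[2] if len(seg) > 2 else "stationary"
            if state not in valid_states:
                raise ValueError(f"unknown gaze state {state!r}")
            if dur < 1:
                raise ValueError("segment durations must be >= 1 frame")
            if profile not in ("stationary", "translate", "head_turn"):
                raise ValueError(f"unknown motion profile {profile!r}")
            norm.append((state, dur, profile))
        self.segments = norm

    @property
    def n_frames(self) -> int:
        return sum(d for _, d, _ in self.segments)


@dataclass
class RenderConfig:
    """Detection corruption model for rendering ground truth to candidates."""

    pixel_noise_sd: float = 0.0
    dropout: float = 0.0
    false_positive_rate: float = 0.0  # expected false peaks per camera-frame
    true_confidence: tuple[float, float] = (0.96, 0.999)
    false_confidence: tuple[float, float] = (0.5, 0.94)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        if self.pixel_noise_sd < 0 or self.false_positive_rate < 0:
            raise ValueError("noise and false-positive rates must be non-negative")


@dataclass
class SceneGroundTruth:
    faces: dict[int, list[FaceFrame3D]]  # animal -> per-frame face frames
    states: list[GazeState]
    rig: CameraRig
    arena: ArenaGeometry
    seed: int
    fps: float = FPS
    scripts: dict[int, BehaviorScript] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.states)


class ScriptingError(ValueError):
    """A script segment cannot be realized within the arena geometry."""


# ---------------------------------------------------------------------------
# rig construction


def _look_at(center: np.ndarray, target: np.ndarray) -> CameraPose:
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(z, up)) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # rows: camera axes in world coords (world->cam)
    return CameraPose(rotation=R, translation=-R @ center)


def _projects_inside(cam: Camera, point: np.ndarray) -> bool:
    try:
        px = project(cam, point)
    except Exception:
        return False
    intr = cam.intrinsics
    return bool(0 <= px[0] < intr.image_width and 0 <= px[1] < intr.image_height)


def _box_vertices(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])


def default_rig(arena: ArenaGeometry | None = None, check_visibility: bool = True) -> CameraRig:
    """Build the 8-camera rig (two groups of four) around the two arenas.

    Monitor-end cameras (ML*/MR*) sit beyond the outer arena ends looking
    down the long axis and see both animals; middle cameras (OL*/OR*) view
    their own arena from the open side.  Intrinsics: fx = fy = 1000 px,
    1920 x 1080, zero distortion (linear lens).  Every arena vertex must be
    visible to >= 2 cameras of its own group (verified at build time).
    """
    arena = arena or ArenaGeometry()
    L, W, H, S = arena.length, arena.width, arena.height, arena.separation
    offset = arena.group_offset
    intr = CameraIntrinsics(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0)
    far_x = 2 * L + S  # outer end of the right arena, unified frame
    gap_mid = np.array([L + S / 2, W / 2, H / 2])

    def cam(cid, group, sees_both, center, target, local):
        pose = _look_at(np.asarray(center, float), np.asarray(target, float))
        if local:  # re-express in the right group's local frame
            t_local = pose.translation + pose.rotation @ offset
            pose = CameraPose(pose.rotation, t_local)
        return Camera(id=cid, intrinsics=intr, pose=pose, group=group, sees_both_animals=sees_both)

    # middle cameras sit near the gap end, one per open side, angled back
    # toward their own arena so the other arena stays outside their frusta
    # monitor-end cameras straddle the arena laterally (wide stereo baseline,
    # which keeps pairwise triangulation well-conditioned at rig scale)
    cameras = [
        cam("ML1", "left_arena", True, [-450, -250, 420], gap_mid, False),
        cam("ML2", "left_arena", True, [-450, W + 250, 420], gap_mid, False),
        cam("OL1", "left_arena", False, [600, -120, 230], [380, W / 2, 140], False),
        cam("OL2", "left_arena", False, [600, W + 120, 230], [380, W / 2, 140], False),
        cam("MR1", "right_arena", True, [far_x + 450, -250, 420], gap_mid, True),
        cam("MR2", "right_arena", True, [far_x + 450, W + 250, 420], gap_mid, True),
        cam("OR1", "right_arena", False, [far_x - 600, -120, 230], [far_x - 380, W / 2, 140], True),
        cam("OR2", "right_arena", False, [far_x - 600, W + 120, 230], [far_x - 380, W / 2, 140], True),
    ]
    rig = CameraRig(cameras=cameras, group_offset=offset)
    if check_visibility:
        merged = merge_world_frames(rig)
        for animal, group in ((0, "left_arena"), (1, "right_arena")):
            lo, hi = arena.box(animal)
            for v in _box_vertices(lo, hi):
                n_seen = sum(_projects_inside(c, v) for c in merged.group_cameras(group))
                if n_seen < 2:
                    raise RuntimeError(
                        f"arena vertex {v} visible to only {n_seen} camera(s) of {group}"
                    )
    return rig


# ---------------------------------------------------------------------------
# scripted dyad simulation


def _orientation_from_axis(axis: np.ndarray) -> np.ndarray:
    """Rotation whose columns map face-local (x, y, z) to world, z -> axis."""
    z = axis / np.linalg.norm(axis)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(z, up)) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _face_at(animal: int, frame: int, head: np.ndarray, axis: np.ndarray) -> FaceFrame3D:
    R = _orientation_from_axis(axis)
    landmarks = {k: head + R @ v for k, v in FACE_TEMPLATE.items()}
    return FaceFrame3D(animal=animal, frame=frame, landmarks=landmarks)


def _cone_origin_at(head: np.ndarray, axis: np.ndarray) -> np.ndarray:
    R = _orientation_from_axis(axis)
    local = (FACE_TEMPLATE["right_eye"] + FACE_TEMPLATE["left_eye"] + FACE_TEMPLATE["central_blaze"]) / 3.0
    return head + R @ local


def _aim(head: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Axis pointing the cone origin at ``target`` (two fixed-point passes)."""
    axis = target - head
    axis = axis / np.linalg.norm(axis)
    for _ in range(3):
        org = _cone_origin_at(head, axis)
        axis = target - org
        axis = axis / np.linalg.norm(axis)
    return axis


def simulate_dyad(
    script_a: BehaviorScript,
    script_b: BehaviorScript | None = None,
    arena: ArenaGeometry | None = None,
    rig: CameraRig | None = None,
    seed: int = 0,
    theta: float = 10.0,
) -> SceneGroundTruth:
    """Generate ground-truth face-frame trajectories realizing a dyadic
    gaze-state script.

    The dyadic state timeline is taken from ``script_a``; ``script_b`` (if
    given) must share the same (state, duration) sequence and contributes
    animal B's motion profiles.  Head reorientation between segments is
    abrupt, so the 5-frame velocity stencil marks segment boundaries as
    high-velocity and stable epochs fall inside segments.  The generator
    re-classifies every frame with the noiseless oracle and raises
    :class:`ScriptingError` if any segment fails to realize its state.
    """
    arena = arena or ArenaGeometry()
    if rig is None:
        rig = default_rig(arena)
    if script_b is not None:
        if [(s, d) for s, d, _ in script_b.segments] != [(s, d) for s, d, _ in script_a.segments]:
            raise ValueError("script_b must share script_a's (state, duration) sequence")
    profiles_b = [p for _, _, p in (script_b or script_a).segments]
    rng = np.random.default_rng(seed)

    L, W, H, S = arena.length, arena.width, arena.height, arena.separation
    base_a = np.array([L - 130.0, W / 2, H / 2])  # near the inner end, left arena
    base_b = np.array([L + S + 130.0, W / 2, H / 2])  # near the inner end, right arena
    monitor_dir_a = np.array([-1.0, 0.0, 0.0])  # toward A's own monitor
    monitor_dir_b = np.array([1.0, 0.0, 0.0])
    joint_target = np.array([L + S / 2, W / 2, 30.0])  # gap floor between arenas

    faces: dict[int, list[FaceFrame3D]] = {0: [], 1: []}
    states: list[GazeState] = []
    bounds = arena.overall_bounds()
    frame = 0
    for seg_idx, (state, dur, profile_a) in enumerate(script_a.segments):
        profile_b = profiles_b[seg_idx]
        # deterministic per-segment drift direction for 'translate'
        drift = rng.uniform(-1, 1, size=3) * np.array([0.3, 0.5, 0.3])
        for k in range(dur):
            head_a = base_a + (drift * k if profile_a == "translate" else 0.0)
            head_b = base_b + (-drift * k if profile_b == "translate" else 0.0)
            fa_probe = _face_at(0, frame, head_a, np.array([1.0, 0, 0]))
            fb_probe = _face_at(1, frame, head_b, np.array([-1.0, 0, 0]))
            if state == "partner_a_to_b":
                axis_a = _aim(head_a, fb_probe.centroid)
                axis_b = monitor_dir_b
            elif state == "partner_b_to_a":
                axis_a = monitor_dir_a
                axis_b = _aim(head_b, fa_probe.centroid)
            elif state == "reciprocal":
                axis_a = _aim(head_a, fb_probe.centroid)
                axis_b = _aim(head_b, fa_probe.centroid)
            elif state == "joint":
                axis_a = _aim(head_a, joint_target)
                axis_b = _aim(head_b, joint_target)
            else:  # none: both face their own monitors; cones diverge
                axis_a = monitor_dir_a
                axis_b = monitor_dir_b
            # re-aim at the actual (orientation-dependent) face centroids
            fa = _face_at(0, frame, head_a, axis_a)
            fb = _face_at(1, frame, head_b, axis_b)
            if state in ("partner_a_to_b", "reciprocal"):
                axis_a = _aim(head_a, fb.centroid)
            if state in ("partner_b_to_a", "reciprocal"):
                axis_b = _aim(head_b, fa.centroid)
            fa = _face_at(0, frame, head_a, axis_a)
            fb = _face_at(1, frame, head_b, axis_b)
            for f, animal in ((fa, 0), (fb, 1)):
                lo, hi = arena.box(animal)
                pts = np.stack(list(f.landmarks.values()))
                if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
                    raise ScriptingError(
                        f"segment {seg_idx} ({state}): animal {animal} leaves its arena"
                    )
            got = classify_frame(
                gaze_cone(fa, theta),
                FacialTriangle.from_face(fa),
                gaze_cone(fb, theta),
                FacialTriangle.from_face(fb),
                search_bounds=bounds,
            )
            if got is None or got.value != state:
                raise ScriptingError(
                    f"segment {seg_idx} ({state}) frame {frame}: oracle classifies "
                    f"{None if got is None else got.value}"
                )
            faces[0].append(fa)
            faces[1].append(fb)
            states.append(got)
            frame += 1
    return SceneGroundTruth(
        faces=faces,
        states=states,
        rig=rig,
        arena=arena,
        seed=seed,
        scripts={0: script_a, 1: script_b or script_a},
    )


# ---------------------------------------------------------------------------
# rendering ground truth into detector-like candidate tables


def _visible_animals(cam: Camera) -> list[int]:
    if cam.sees_both_animals:
        return [0, 1]
    return [0] if cam.group == "left_arena" else [1]


def render(
    scene: SceneGroundTruth,
    rig: CameraRig | None = None,
    cfg: RenderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Project ground-truth landmarks per camera and corrupt them into a
    detector-like keypoint table (DLC dialect: frame, camera, bodypart, x, y,
    likelihood).

    True detections get Gaussian pixel noise and high confidence, are
    dropped with the dropout probability, and each camera-frame receives a
    Poisson number of uniformly placed low-confidence false positives.
    """
    rig = merge_world_frames(rig or scene.rig)
    cfg = cfg or RenderConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for cam in rig.cameras:
        intr = cam.intrinsics
        for t in range(scene.n_frames):
            for animal in _visible_animals(cam):
                face = scene.faces[animal][t]
                for label in FEATURE_ORDER:
                    try:
                        px = project(cam, face.point(label))
                    except Exception:
                        continue
                    if not (0 <= px[0] < intr.image_width and 0 <= px[1] < intr.image_height):
                        continue
                    if rng.random() < cfg.dropout:
                        continue
                    if cfg.pixel_noise_sd > 0:
                        px = px + rng.normal(0.0, cfg.pixel_noise_sd, size=2)
                    conf = rng.uniform(*cfg.true_confidence)
                    rows.append((t, cam.id, label, px[0], px[1], conf))
            if cfg.false_positive_rate > 0:
                for _ in range(rng.poisson(cfg.false_positive_rate)):
                    label = FEATURE_ORDER[rng.integers(len(FEATURE_ORDER))]
                    x = rng.uniform(0, intr.image_width)
                    y = rng.uniform(0, intr.image_height)
                    conf = rng.uniform(*cfg.false_confidence)
                    rows.append((t, cam.id, label, x, y, conf))
    return pd.DataFrame(rows, columns=["frame", "camera", "bodypart", "x", "y", "likelihood"])


def ground_truth_table(scene: SceneGroundTruth) -> pd.DataFrame:
    """Tidy per-frame 3D landmark table (frame, animal, bodypart, X, Y, Z)."""
    rows = []
    for animal, frames in scene.faces.items():
        for f in frames:
            for label in FEATURE_ORDER:
                X, Y, Z = f.point(label)
                rows.append((f.frame, animal, label, X, Y, Z))
    return pd.DataFrame(rows, columns=["frame", "animal", "bodypart", "X", "Y", "Z"])


# ---------------------------------------------------------------------------
# synthetic detector heatmaps (Gaussian bumps) for candidate selection


def gaussian_bump_heatmap(shape: tuple[int, int], peaks, sigma: float = 3.0) -> np.ndarray:
    """Synthesize a detector probability heatmap as a sum of Gaussian bumps.

    ``peaks`` is a list of ((x, y), amplitude); shape is (height, width).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    hm = np.zeros(shape, dtype=float)
    for (x, y), amp in peaks:
        hm = np.maximum(hm, amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)))
    return hm


def heatmap_peaks(hm: np.ndarray, min_distance: int = 5) -> list[tuple[np.ndarray, float]]:
    """Local maxima of a heatmap as ((x, y), value), descending by value."""
    footprint = maximum_filter(hm, size=2 * min_distance + 1, mode="constant")
    mask = (hm == footprint) & (hm > 0)
    ys, xs = np.nonzero(mask)
    peaks = [(np.array([x, y], dtype=float), float(hm[y, x])) for y, x in zip(ys, xs)]
    return sorted(peaks, key=lambda pv: -pv[1])
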