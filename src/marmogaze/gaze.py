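"""Face-frame geometry and head-gaze dynamics.

The six tracked facial landmarks (two ear tufts, central blaze, two eyes,
mouth) form a semi-rigid 3D "face frame".  Head gaze is modeled as the unit
normal of the plane through the two eyes and the central blaze ("face norm
vector"), sign-oriented away from the ear tufts, widened into a single-nappe
cone of 10 degree half-angle — the envelope of likely eye-gaze directions
given the limited saccade amplitude of marmosets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class FeatureLabel(str, Enum):
    """The six tracked facial features, in stable serialization order."""

    right_tuft = "right_tuft"
    central_blaze = "central_blaze"
    left_tuft = "left_tuft"
    right_eye = "right_eye"
    left_eye = "left_eye"
    mouth = "mouth"


FEATURE_ORDER = [l.value for l in FeatureLabel]


class DegenerateFaceError(ValueError):
    """Eyes and blaze are collinear; no facial plane exists."""


@dataclass
class FaceFrame3D:
    """Six labeled 3D landmarks (mm) for one animal in one frame."""

    animal: int
    frame: int
    landmarks: dict  # FeatureLabel value -> (3,) array
    valid: bool = True

    def __post_init__(self) -> None:
        self.landmarks = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()}

    def point(self, label) -> np.ndarray:
        return self.landmarks[label.value if isinstance(label, FeatureLabel) else label]

    @property
    def centroid(self) -> np.ndarray:
        """Centroid of all six landmarks (the animal's tracked position)."""
        return np.mean([self.landmarks[l] for l in FEATURE_ORDER], axis=0)


@dataclass(frozen=True)
class GazeCone:
    """Single-nappe cone: apex ``origin``, unit ``axis``, half-angle θ in degrees."""

    origin: np.ndarray
    axis: np.ndarray
    half_angle_deg: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("cone axis must be a unit vector")
        object.__setattr__(self, "axis", axis / n)
        if not (0.0 < self.half_angle_deg < 90.0):
            raise ValueError("half-angle must lie strictly between 0 and 90 degrees")


@dataclass(frozen=True)
class StableEpoch:
    """Run of >= 3 consecutive frames with head-gaze velocity <= threshold."""

    animal: int
    start: int
    end: int  # inclusive

    def __len__(self) -> int:
        return self.end - self.start + 1

    def frames(self) -> range:
        return range(self.start, self.end + 1)


def face_norm(frame: FaceFrame3D) -> np.ndarray:
    """Unit normal of the eyes-blaze plane, oriented away from the ear tufts.

    The sign convention: the mean tuft position has negative projection onto
    the returned normal (tufts sit behind the facial plane).
    """
    if not frame.valid:
        return np.full(3, np.nan)
    re = frame.point(FeatureLabel.right_eye)
    le = frame.point(FeatureLabel.left_eye)
    bz = frame.point(FeatureLabel.central_blaze)
    if not np.all(np.isfinite(np.concatenate([re, le, bz]))):
        return np.full(3, np.nan)
    n = np.cross(le - re, bz - re)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(le - re), np.linalg.norm(bz - re), 1e-12)
    if nn < 1e-9 * scale**2:
        raise DegenerateFaceError("eyes and blaze are collinear")
    n = n / nn
    tuft_mean = 0.5 * (frame.point(FeatureLabel.right_tuft) + frame.point(FeatureLabel.left_tuft))
    plane_point = (re + le + bz) / 3.0
    if np.dot(n, tuft_mean - plane_point) > 0:
        n = -n
    return n


def gaze_cone(frame: FaceFrame3D, theta: float = 10.0) -> GazeCone:
    """Gaze cone of a face frame: axis along the face norm, apex at the
    centroid of the two eyes and the central blaze."""
    axis = face_norm(frame)
    if np.any(np.isnan(axis)):
        raise ValueError("face frame invalid; no gaze cone")
    origin = (
        frame.point(FeatureLabel.right_eye)
        + frame.point(FeatureLabel.left_eye)
        + frame.point(FeatureLabel.central_blaze)
    ) / 3.0
    return GazeCone(origin=origin, axis=axis, half_angle_deg=theta)


def head_gaze_velocity(norms: np.ndarray) -> np.ndarray:
    """Head-gaze velocity from the face-norm series via the central stencil

        v(t) = [N(t+2) + N(t+1) - N(t-1) - N(t-2)] / 6

    applied per component at 30 Hz.  Input is (T, 3); output (T, 3) with the
    first two and last two frames set to NaN (undefined).
    """
    N = np.asarray(norms, dtype=float)
    if N.ndim != 2 or N.shape[1] != 3 or N.shape[0] < 5:
        raise ValueError("need an (T, 3) series with T >= 5")
    v = np.full_like(N, np.nan)
    v[2:-2] = (N[4:] + N[3:-1] - N[1:-3] - N[:-4]) / 6.0
    return v


def velocity_magnitude(v: np.ndarray) -> np.ndarray:
    return np.linalg.norm(v, axis=1)


def stable_epochs(
    velocity: np.ndarray, animal: int = 0, threshold: float = 0.05, min_length: int = 3
) -> list[StableEpoch]:
    """Maximal runs of frames with ||v|| <= threshold and length >= min_length.

    ``velocity`` may be an (T, 3) velocity series or a (T,) magnitude series.
    Frames with undefined (NaN) velocity count as above threshold and break
    epochs.
    """
    v = np.asarray(velocity, dtype=float)
    mag = np.linalg.norm(v, axis=1) if v.ndim == 2 else v
    below = np.zeros(len(mag), dtype=bool)
    finite = np.isfinite(mag)
    below[finite] = mag[finite] <= threshold
    epochs = []
    start = None
    for i, ok in enumerate(below):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_length:
                epochs.append(StableEpoch(animal=animal, start=start, end=i - 1))
            start = None
    if start is not None and len(below) - start >= min_length:
        epochs.append(StableEpoch(animal=animal, start=start, end=len(below) - 1))
    return epochs
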