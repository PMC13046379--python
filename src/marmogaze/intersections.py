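"""Gaze-cone intersection geometry.

All gaze interaction analyses reduce to three tests on single-nappe cones:
point containment (the printed inequality cos θ − dot(d, X−o)/‖X−o‖ ≤ 0),
cone vs. the partner's finite facial triangle (numerical, barycentric grid),
and cone vs. cone (numerical, regular 3D grid within the arena volume).
The cone-monitor intersection is analytic (a conic section clipped to the
monitor rectangle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze import FaceFrame3D, FeatureLabel, GazeCone


@dataclass(frozen=True)
class FacialTriangle:
    """Finite triangular facial plane: two eyes and mouth."""

    right_eye: np.ndarray
    left_eye: np.ndarray
    mouth: np.ndarray
    animal: int = 0

    def __post_init__(self) -> None:
        for name in ("right_eye", "left_eye", "mouth"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    @classmethod
    def from_face(cls, frame: FaceFrame3D) -> "FacialTriangle":
        return cls(
            right_eye=frame.point(FeatureLabel.right_eye),
            left_eye=frame.point(FeatureLabel.left_eye),
            mouth=frame.point(FeatureLabel.mouth),
            animal=frame.animal,
        )

    @property
    def vertices(self) -> np.ndarray:
        return np.stack([self.right_eye, self.left_eye, self.mouth])

    @property
    def area(self) -> float:
        return 0.5 * np.linalg.norm(
            np.cross(self.left_eye - self.right_eye, self.mouth - self.right_eye)
        )

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.left_eye - self.right_eye, self.mouth - self.right_eye)
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class MonitorPlane:
    """Monitor rectangle in 3D: corner + two orthogonal edge vectors (mm)."""

    origin: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "edge_u", np.asarray(self.edge_u, dtype=float).reshape(3))
        object.__setattr__(self, "edge_v", np.asarray(self.edge_v, dtype=float).reshape(3))
        if abs(np.dot(self.edge_u, self.edge_v)) > 1e-6 * (
            np.linalg.norm(self.edge_u) * np.linalg.norm(self.edge_v)
        ):
            raise ValueError("monitor edge vectors must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.edge_u, self.edge_v)
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class ConicSection:
    """Cone-plane intersection: an ellipse, nothing, or a non-elliptical cut."""

    kind: str  # 'ellipse' | 'none' | 'non_elliptical'
    center: np.ndarray | None = None  # 3D point
    semi_axes: tuple[float, float] | None = None  # (major, minor), mm
    orientation: float | None = None  # radians of major axis vs edge_u, in-plane
    clipped: bool = False


def cone_contains_points(cone: GazeCone, X: np.ndarray) -> np.ndarray:
    """Vectorized containment test for points (N, 3); boundary counts inside."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u = X - cone.origin
    dist = np.linalg.norm(u, axis=1)
    cos_theta = np.cos(np.radians(cone.half_angle_deg))
    with np.errstate(invalid="ignore", divide="ignore"):
        lhs = cos_theta - (u @ cone.axis) / dist
    out = np.zeros(len(X), dtype=bool)
    ok = dist > 0
    out[ok] = lhs[ok] <= 0.0
    return out


def cone_contains_point(cone: GazeCone, X) -> bool:
    """The printed containment inequality for a single point."""
    X = np.asarray(X, dtype=float).reshape(3)
    if np.linalg.norm(X - cone.origin) == 0.0:
        raise ValueError("containment undefined at the cone apex")
    return bool(cone_contains_points(cone, X[None, :])[0])


def _barycentric_grid(grid_n: int) -> np.ndarray:
    """Barycentric sample weights covering a triangle, incl. the vertices."""
    ij = [(i, j) for i in range(grid_n + 1) for j in range(grid_n + 1 - i)]
    w = np.array([(i / grid_n, j / grid_n, (grid_n - i - j) / grid_n) for i, j in ij])
    return w


def cone_intersects_triangle(cone: GazeCone, tri: FacialTriangle, grid_n: int = 25) -> bool:
    """Numerical cone-facial-plane test: any sampled triangle point inside the
    cone.  Samples the 3 vertices plus a regular barycentric grid."""
    if tri.area < 1e-9:
        raise ValueError("degenerate facial triangle")
    pts = _barycentric_grid(grid_n) @ tri.vertices
    return bool(np.any(cone_contains_points(cone, pts)))


def cones_intersect(
    cone_a: GazeCone,
    cone_b: GazeCone,
    search_bounds: tuple[np.ndarray, np.ndarray],
    grid_n: int = 40,
) -> tuple[bool, np.ndarray | None]:
    """Numerical cone-cone test on a regular 3D grid within ``search_bounds``.

    Returns (intersects, representative point), the representative point
    being the centroid of all grid points satisfying both containment
    inequalities — used as the joint-gaze location.
    """
    lo = np.asarray(search_bounds[0], dtype=float).reshape(3)
    hi = np.asarray(search_bounds[1], dtype=float).reshape(3)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("search bounds must be finite with positive extent")
    axes = [np.linspace(lo[k], hi[k], grid_n) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = cone_contains_points(cone_a, pts)
    if not np.any(inside):
        return False, None
    inside[inside] = cone_contains_points(cone_b, pts[inside])
    if not np.any(inside):
        return False, None
    return True, pts[inside].mean(axis=0)


def cone_axis_plane_point(cone: GazeCone, plane) -> np.ndarray | None:
    """Forward intersection of the cone axis ray with an (infinite) plane.

    ``plane`` may be a MonitorPlane, a FacialTriangle, or a (point, normal)
    tuple.  Returns None if the axis is parallel to the plane or the
    intersection lies behind the apex.
    """
    if isinstance(plane, MonitorPlane):
        p0, n = plane.origin, plane.normal
    elif isinstance(plane, FacialTriangle):
        p0, n = plane.right_eye, plane.normal
    else:
        p0, n = (np.asarray(v, dtype=float).reshape(3) for v in plane)
        n = n / np.linalg.norm(n)
    denom = np.dot(cone.axis, n)
    if abs(denom) < 1e-12:
        return None
    t = np.dot(p0 - cone.origin, n) / denom
    if t <= 0:
        return None
    return cone.origin + t * cone.axis


def cone_monitor_intersection(cone: GazeCone, monitor: MonitorPlane) -> ConicSection:
    """Analytic conic of the gaze cone and the monitor's plane.

    An ellipse results exactly when the plane cuts every forward generator
    (axis-to-normal angle below 90° − θ) and the axis crosses the plane in
    the forward direction; the ellipse is flagged ``clipped`` when it
    exceeds the monitor rectangle.
    """
    e1 = monitor.edge_u / np.linalg.norm(monitor.edge_u)
    e2 = monitor.edge_v / np.linalg.norm(monitor.edge_v)
    L1 = np.linalg.norm(monitor.edge_u)
    L2 = np.linalg.norm(monitor.edge_v)
    n = monitor.normal
    a = cone.axis
    theta = np.radians(cone.half_angle_deg)

    axis_pt = cone_axis_plane_point(cone, monitor)
    if axis_pt is None:
        return ConicSection(kind="none")
    if abs(np.dot(a, n)) <= np.sin(theta) + 1e-15:
        return ConicSection(kind="non_elliptical")

    c2 = np.cos(theta) ** 2
    q = monitor.origin - cone.origin
    alpha, beta, gamma = np.dot(e1, a), np.dot(e2, a), np.dot(q, a)
    A = alpha**2 - c2
    B = 2 * alpha * beta
    C = beta**2 - c2
    D = 2 * alpha * gamma - 2 * c2 * np.dot(e1, q)
    E = 2 * beta * gamma - 2 * c2 * np.dot(e2, q)
    F = gamma**2 - c2 * np.dot(q, q)
    disc = B**2 - 4 * A * C
    if disc >= 0:
        return ConicSection(kind="non_elliptical")

    uc, vc = np.linalg.solve(np.array([[2 * A, B], [B, 2 * C]]), -np.array([D, E]))
    Fc = F + 0.5 * (D * uc + E * vc)  # conic value at its center
    Q = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        axes2 = -Fc / evals
    if np.any(axes2 <= 0):
        return ConicSection(kind="none")
    semi = np.sqrt(axes2)
    order = np.argsort(semi)[::-1]  # major first
    semi = semi[order]
    major_vec = evecs[:, order[0]]
    orientation = float(np.arctan2(major_vec[1], major_vec[0]))

    center3d = monitor.origin + uc * e1 + vc * e2

    # boundary sample in plane coordinates to detect clipping by the rectangle
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    R = np.column_stack([major_vec, evecs[:, order[1]]])
    ring = np.column_stack([semi[0] * np.cos(t), semi[1] * np.sin(t)]) @ R.T + [uc, vc]
    clipped = bool(
        np.any(ring[:, 0] < 0) or np.any(ring[:, 0] > L1) or np.any(ring[:, 1] < 0) or np.any(ring[:, 1] > L2)
    )
    return ConicSection(
        kind="ellipse",
        center=center3d,
        semi_axes=(float(semi[0]), float(semi[1])),
        orientation=orientation,
        clipped=clipped,
    )
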