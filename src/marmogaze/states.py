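"""Interactive gaze-state classification and downstream statistics.

Frame-level classification follows a hierarchical priority rule: a gaze cone
containing the partner's facial triangle defines partner (or reciprocal)
gaze regardless of incidental external cone-cone intersections; joint gaze
requires an external cone-cone intersection with neither face hit.  Stable
epochs inherit the modal frame state.  Epoch sequences feed Markov
transition matrices, per-edge chi-square comparisons, social distance
binning, and periphery-of-face gaze distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import chi2_contingency

from .gaze import FaceFrame3D, GazeCone, StableEpoch
from .intersections import (
    FacialTriangle,
    cone_axis_plane_point,
    cone_intersects_triangle,
    cones_intersect,
)


class GazeState(str, Enum):
    partner_a_to_b = "partner_a_to_b"
    partner_b_to_a = "partner_b_to_a"
    reciprocal = "reciprocal"
    joint = "joint"
    none = "none"


#: tie-break priority, highest first (hierarchy of the classification rule)
STATE_PRIORITY = [
    GazeState.reciprocal,
    GazeState.partner_a_to_b,
    GazeState.partner_b_to_a,
    GazeState.joint,
    GazeState.none,
]

MISSING_STATE = None


@dataclass
class EpochState:
    start: int
    end: int  # inclusive
    state: GazeState
    mean_distance_mm: float | None = None
    distance_bin: str | None = None


class DistanceBin(str, Enum):
    Near = "Near"
    Intermediate = "Intermediate"
    Far = "Far"


@dataclass
class TransitionMatrix:
    states: list[str]
    counts: np.ndarray  # (S, S) integer counts
    probs: np.ndarray  # row-normalized; NaN rows where count total is 0


def classify_frame(
    cone_a: GazeCone | None,
    tri_a: FacialTriangle | None,
    cone_b: GazeCone | None,
    tri_b: FacialTriangle | None,
    search_bounds=None,
    grid_n: int = 40,
    tri_grid_n: int = 25,
):
    """Classify one frame's dyadic gaze configuration.

    Returns a :class:`GazeState`, or None (missing) when either animal's
    geometry is invalid.
    """
    if cone_a is None or cone_b is None or tri_a is None or tri_b is None:
        return MISSING_STATE
    a_hits_b = cone_intersects_triangle(cone_a, tri_b, grid_n=tri_grid_n)
    b_hits_a = cone_intersects_triangle(cone_b, tri_a, grid_n=tri_grid_n)
    if a_hits_b and b_hits_a:
        return GazeState.reciprocal
    if a_hits_b:
        return GazeState.partner_a_to_b
    if b_hits_a:
        return GazeState.partner_b_to_a
    if search_bounds is not None:
        hit, _ = cones_intersect(cone_a, cone_b, search_bounds, grid_n=grid_n)
        if hit:
            return GazeState.joint
    return GazeState.none


def _modal_state(states: list, allowed: set | None = None) -> GazeState:
    counts: dict[GazeState, int] = {}
    for s in states:
        if s is None:
            continue
        if allowed is not None and s not in allowed:
            s = GazeState.none
        counts[s] = counts.get(s, 0) + 1
    if not counts:
        return GazeState.none
    best = max(counts.values())
    for s in STATE_PRIORITY:  # hierarchy resolves ties
        if counts.get(s, 0) == best:
            return s
    return GazeState.none


def _intersect_epochs(epochs_a: list[StableEpoch], epochs_b: list[StableEpoch]):
    segs = []
    for ea in epochs_a:
        for eb in epochs_b:
            lo, hi = max(ea.start, eb.start), min(ea.end, eb.end)
            if lo <= hi:
                segs.append((lo, hi))
    return sorted(segs)


def _subtract_segments(epoch: StableEpoch, segs: list[tuple[int, int]]):
    """Frames of ``epoch`` not covered by any segment, as maximal runs."""
    covered = np.zeros(len(epoch), dtype=bool)
    for lo, hi in segs:
        a = max(lo, epoch.start) - epoch.start
        b = min(hi, epoch.end) - epoch.start
        if a <= b:
            covered[a : b + 1] = True
    runs = []
    start = None
    for i, c in enumerate(covered):
        if not c and start is None:
            start = i
        elif c and start is not None:
            runs.append((epoch.start + start, epoch.start + i - 1))
            start = None
    if start is not None:
        runs.append((epoch.start + start, epoch.end))
    return runs


def classify_epochs(
    epochs_a: list[StableEpoch],
    epochs_b: list[StableEpoch],
    per_frame_states: list,
) -> list[EpochState]:
    """Attribute gaze states to stable epochs.

    Joint and reciprocal states require both animals to be stationary, so
    maximal overlap segments of the two epoch sets may take any state (modal
    frame state, hierarchy tie-break).  Partner states require only the
    gazer's stability: the non-overlapping remainder of each animal's epochs
    is classified among {that animal's partner state, none}.
    """
    overlaps = _intersect_epochs(epochs_a, epochs_b)
    out = []
    for lo, hi in overlaps:
        state = _modal_state(per_frame_states[lo : hi + 1])
        out.append(EpochState(start=lo, end=hi, state=state))
    for epochs, partner_state in (
        (epochs_a, GazeState.partner_a_to_b),
        (epochs_b, GazeState.partner_b_to_a),
    ):
        for ep in epochs:
            for lo, hi in _subtract_segments(ep, overlaps):
                state = _modal_state(
                    per_frame_states[lo : hi + 1], allowed={partner_state, GazeState.none}
                )
                out.append(EpochState(start=lo, end=hi, state=state))
    return sorted(out, key=lambda e: (e.start, e.end))


def social_distance(frame_a: FaceFrame3D | None, frame_b: FaceFrame3D | None) -> float:
    """Euclidean distance (mm) between the two face-frame centroids."""
    if frame_a is None or frame_b is None or not frame_a.valid or not frame_b.valid:
        return float("nan")
    return float(np.linalg.norm(frame_a.centroid - frame_b.centroid))


def bin_distance(d: float, boundaries: tuple[float, float]) -> DistanceBin:
    """Half-open binning of social distance: [0,b1) Near, [b1,b2)
    Intermediate, [b2,inf) Far."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    b1, b2 = boundaries
    if not b1 < b2:
        raise ValueError("bin boundaries must be strictly increasing")
    if d < b1:
        return DistanceBin.Near
    if d < b2:
        return DistanceBin.Intermediate
    return DistanceBin.Far


def transition_matrix(sequence: list, states: list[str] | None = None) -> TransitionMatrix:
    """Count consecutive epoch-state transitions; missing states break chains.

    Self-transitions (recurrent edges — returning to the same stable gaze
    state after a movement break) land on the diagonal.
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 epochs")
    if states is None:
        states = [s.value for s in GazeState]
    index = {s: i for i, s in enumerate(states)}
    S = len(states)
    counts = np.zeros((S, S), dtype=int)
    for prev, cur in zip(sequence[:-1], sequence[1:]):
        if prev is None or cur is None:
            continue
        pv = prev.value if isinstance(prev, GazeState) else prev
        cv = cur.value if isinstance(cur, GazeState) else cur
        counts[index[pv], index[cv]] += 1
    totals = counts.sum(axis=1)
    probs = np.full((S, S), np.nan)
    nz = totals > 0
    probs[nz] = counts[nz] / totals[nz, None]
    return TransitionMatrix(states=list(states), counts=counts, probs=probs)


def compare_transition_counts(
    counts_x: TransitionMatrix, counts_y: TransitionMatrix, edge: tuple[str, str]
):
    """2x2 chi-square (no continuity correction, two-sided) comparing one
    edge's transition proportion between two conditions."""
    if counts_x.states != counts_y.states:
        raise ValueError("transition matrices must share state ordering")
    i = counts_x.states.index(edge[0])
    j = counts_x.states.index(edge[1])
    kx, nx = counts_x.counts[i, j], counts_x.counts[i].sum()
    ky, ny = counts_y.counts[i, j], counts_y.counts[i].sum()
    if nx < 1 or ny < 1:
        return None
    table = np.array([[kx, nx - kx], [ky, ny - ky]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        # degenerate margin: identical all-or-nothing proportions
        return (0.0, 1.0)
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def periphery_gaze_distance(cone: GazeCone, partner: FaceFrame3D) -> float:
    """Distance (mm) from the partner's face-frame centroid to the point
    where the gaze-cone axis pierces the partner's facial plane; NaN when the
    axis does not cross the plane in the forward direction."""
    tri = FacialTriangle.from_face(partner)
    pt = cone_axis_plane_point(cone, tri)
    if pt is None:
        return float("nan")
    return float(np.linalg.norm(pt - partner.centroid))


def joint_gaze_projections(
    locations: np.ndarray,
    bins: int = 20,
    ranges: dict | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Project 3D joint-gaze locations onto the XY, XZ and YZ planes and
    histogram each; counts are conserved on every plane."""
    pts = np.atleast_2d(np.asarray(locations, dtype=float))
    if pts.size and not np.all(np.isfinite(pts)):
        raise ValueError("joint gaze locations must be finite")
    planes = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}
    out = {}
    for name, (i, j) in planes.items():
        rng = None if ranges is None else ranges.get(name)
        H, xe, ye = np.histogram2d(pts[:, i], pts[:, j], bins=bins, range=rng)
        out[name] = (H, xe, ye)
    return out
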