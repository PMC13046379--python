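"""Two-animal facial-feature tracking in image space.

Implements the per-frame pipeline: candidate selection from detector peaks,
K-means clustering into per-animal feature sets under the one-feature-per-
animal uniqueness constraint, within-frame outlier removal, centroid
computation, temporally smooth identity assignment, cross-view identity
transfer, and gap interpolation.  All steps operate independently per video
frame except identity linking and interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .camera import Camera, project
from .gaze import FEATURE_ORDER

DETECTION_THRESHOLD = 0.95
MAX_CANDIDATES_PER_LABEL = 2


@dataclass(eq=False)
class Candidate:
    label: str
    position: np.ndarray  # (2,) pixels
    confidence: float
    camera: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)


@dataclass
class FeatureCluster:
    """A per-animal set of candidates with at most one per feature label."""

    members: list[Candidate] = field(default_factory=list)
    animal: int | None = None

    @property
    def centroid(self) -> np.ndarray | None:
        if not self.members:
            return None
        return np.mean([m.position for m in self.members], axis=0)

    def labels(self) -> list[str]:
        return [m.label for m in self.members]

    def has_duplicate_labels(self) -> bool:
        lab = self.labels()
        return len(lab) != len(set(lab))


@dataclass
class CentroidTrack:
    animal: int
    positions: np.ndarray  # (T, D)
    valid: np.ndarray  # (T,) bool


def select_candidates(
    peak_scores: dict,
    threshold: float = DETECTION_THRESHOLD,
    max_per_label: int = MAX_CANDIDATES_PER_LABEL,
    camera: str = "",
    frame: int = 0,
) -> list[Candidate]:
    """Keep, per feature label, the top ``max_per_label`` detector peaks with
    confidence strictly above ``threshold``, in descending confidence."""
    out: list[Candidate] = []
    for label, peaks in peak_scores.items():
        ranked = sorted(peaks, key=lambda pc: -pc[1])
        kept = [pc for pc in ranked if pc[1] > threshold][:max_per_label]
        out.extend(
            Candidate(label=label, position=p, confidence=c, camera=camera, frame=frame)
            for p, c in kept
        )
    return out


def _repair_uniqueness(clusters: list[FeatureCluster]) -> None:
    """Enforce at most one candidate per label per cluster.

    When a cluster holds duplicates of a label, the member farther from its
    cluster centroid is moved to the other cluster if that cluster lacks the
    label, else dropped.
    """
    if len(clusters) < 2:
        # single cluster: keep the highest-confidence member per label
        for cl in clusters:
            best: dict[str, Candidate] = {}
            for m in cl.members:
                if m.label not in best or m.confidence > best[m.label].confidence:
                    best[m.label] = m
            cl.members = list(best.values())
        return
    changed = True
    while changed:
        changed = False
        for idx, cl in enumerate(clusters):
            other = clusters[1 - idx]
            by_label: dict[str, list[Candidate]] = {}
            for m in cl.members:
                by_label.setdefault(m.label, []).append(m)
            for label, dups in by_label.items():
                if len(dups) < 2:
                    continue
                cen = cl.centroid
                dups.sort(key=lambda m: np.linalg.norm(m.position - cen))
                for extra in dups[1:]:
                    cl.members.remove(extra)
                    if label not in other.labels():
                        other.members.append(extra)
                    changed = True
                break  # centroids moved; recompute


def cluster_features(
    candidates: list[Candidate],
    n_clusters: int = 2,
    seed: int = 0,
    merge_radius: float = 120.0,
) -> list[FeatureCluster]:
    """K-means on candidate positions followed by uniqueness-constraint repair.

    When only one animal is visible, K-means would still split its features
    in two; clusters whose union has no duplicate labels and whose centroids
    lie within ``merge_radius`` px (about two face widths) are therefore
    merged back into one.
    """
    if not candidates:
        return []
    pos = np.stack([c.position for c in candidates])
    k = min(n_clusters, len(candidates))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pos)
    clusters = [FeatureCluster() for _ in range(n_clusters)]
    for cand, lab in zip(candidates, km.labels_):
        clusters[int(lab)].members.append(cand)
    if n_clusters == 2 and all(cl.members for cl in clusters[:2]):
        union_labels = clusters[0].labels() + clusters[1].labels()
        if len(union_labels) == len(set(union_labels)):
            sep = np.linalg.norm(clusters[0].centroid - clusters[1].centroid)
            if sep <= merge_radius:
                clusters = [
                    FeatureCluster(members=clusters[0].members + clusters[1].members),
                    FeatureCluster(),
                ]
    _repair_uniqueness(clusters)
    return clusters


def remove_outliers(clusters: list[FeatureCluster], sd_multiplier: float = 2.0) -> list[FeatureCluster]:
    """Drop candidates whose within-cluster nearest-neighbor distance exceeds
    mean + ``sd_multiplier``·SD of the frame's pooled within-cluster
    nearest-neighbor distance distribution.  Clusters with fewer than 3
    members pass through unmodified (insufficient statistics)."""
    pooled = []
    for cl in clusters:
        if len(cl.members) < 3:
            continue
        pos = np.stack([m.position for m in cl.members])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        pooled.extend(d.min(axis=1))
    if not pooled:
        return clusters
    thresh = np.mean(pooled) + sd_multiplier * np.std(pooled)
    out = []
    for cl in clusters:
        if len(cl.members) < 3:
            out.append(cl)
            continue
        pos = np.stack([m.position for m in cl.members])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        kept = [m for m, dist in zip(cl.members, nn) if dist <= thresh]
        out.append(FeatureCluster(members=kept, animal=cl.animal))
    return out


def compute_centroids(clusters: list[FeatureCluster]) -> list[np.ndarray | None]:
    """Arithmetic mean of member positions; None for an empty cluster."""
    return [cl.centroid for cl in clusters]


def link_identities(
    per_frame_centroids: list[list[np.ndarray]],
    max_jump: float = 100.0,
    n_tracks: int = 2,
) -> list[CentroidTrack]:
    """Assign temporally consistent identities to per-frame centroids.

    Greedy-over-time optimal assignment: each frame's detections are matched
    to the tracks' last valid positions by minimum summed displacement
    (Hungarian); matches with displacement above ``max_jump`` are refused and
    the track marked missing for that frame.  Exact ties resolve to the
    lower track index.
    """
    T = len(per_frame_centroids)
    if T == 0:
        raise ValueError("need at least one frame")
    dim = 2
    for dets in per_frame_centroids:
        for d in dets:
            dim = len(d)
            break
    positions = np.full((n_tracks, T, dim), np.nan)
    valid = np.zeros((n_tracks, T), dtype=bool)
    last = [None] * n_tracks

    for t, dets in enumerate(per_frame_centroids):
        dets = [np.asarray(d, dtype=float) for d in dets if d is not None]
        if not dets:
            continue
        if all(l is None for l in last):
            for i, d in enumerate(dets[:n_tracks]):
                positions[i, t] = d
                valid[i, t] = True
                last[i] = d
            continue
        cost = np.zeros((n_tracks, len(dets)))
        for i in range(n_tracks):
            for j, d in enumerate(dets):
                if last[i] is None:
                    cost[i, j] = 2.0 * max_jump  # new track: admissible but dispreferred
                else:
                    cost[i, j] = np.linalg.norm(d - last[i])
        # bias off-diagonal pairs infinitesimally: equidistant ties keep indices
        cost = cost + 1e-9 * (np.arange(n_tracks)[:, None] != np.arange(len(dets))[None, :])
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            displacement = cost[i, j]
            if last[i] is not None and displacement > max_jump:
                continue
            positions[i, t] = dets[j]
            valid[i, t] = True
            last[i] = dets[j]
    return [CentroidTrack(animal=i, positions=positions[i], valid=valid[i]) for i in range(n_tracks)]


def transfer_identity_cross_view(
    centroids_3d: dict[int, np.ndarray],
    end_camera: Camera,
    clusters: list[FeatureCluster],
    arena_bounds: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
    cluster_positions_3d: list[np.ndarray | None] | None = None,
    match_radius: float = 200.0,
) -> list[FeatureCluster]:
    """Label an end-camera frame's clusters with animal identities.

    The per-animal 3D centroids (triangulated from the single-animal middle
    cameras) are projected into the end camera's image; each projection is
    matched to the nearest unmatched cluster centroid by optimal assignment.
    Clusters whose triangulated 3D position falls outside every admissible
    arena box are excluded.  An animal with no cluster within
    ``match_radius`` is left unmatched (missing in this view).
    """
    usable = []
    for idx, cl in enumerate(clusters):
        if cl.centroid is None:
            continue
        if arena_bounds is not None and cluster_positions_3d is not None:
            p3 = cluster_positions_3d[idx]
            if p3 is not None:
                inside_any = any(
                    np.all(p3 >= lo - 1e-6) and np.all(p3 <= hi + 1e-6)
                    for lo, hi in arena_bounds.values()
                )
                if not inside_any:
                    continue
        usable.append(cl)
    if not usable:
        return []
    animals = sorted(centroids_3d)
    proj = {}
    for a in animals:
        try:
            proj[a] = project(end_camera, centroids_3d[a])
        except Exception:
            pass
    if not proj:
        return usable
    cost = np.zeros((len(proj), len(usable)))
    for i, a in enumerate(sorted(proj)):
        for j, cl in enumerate(usable):
            cost[i, j] = np.linalg.norm(proj[a] - cl.centroid)
    rows, cols = linear_sum_assignment(cost)
    for i, j in zip(rows, cols):
        if cost[i, j] <= match_radius:
            usable[j].animal = sorted(proj)[i]
    return usable


def interpolate_gaps(track: CentroidTrack, max_gap: int = 5) -> CentroidTrack:
    """Fill detection gaps of length <= ``max_gap`` by linear interpolation
    between the nearest valid past and future samples.  Longer gaps and
    leading/trailing gaps stay missing.  Valid samples are untouched."""
    pos = track.positions.copy()
    valid = track.valid.copy()
    idx = np.flatnonzero(track.valid)
    if len(idx) >= 2:
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap:
                for k in range(1, gap + 1):
                    frac = k / (b - a)
                    pos[a + k] = (1 - frac) * track.positions[a] + frac * track.positions[b]
                    valid[a + k] = True
    return CentroidTrack(animal=track.animal, positions=pos, valid=valid)


def interpolate_gaps_array(positions: np.ndarray, valid: np.ndarray, max_gap: int = 5):
    """Array-level convenience wrapper around :func:`interpolate_gaps`."""
    tr = interpolate_gaps(CentroidTrack(animal=0, positions=positions, valid=valid), max_gap=max_gap)
    return tr.positions, tr.valid


# ---------------------------------------------------------------------------
# keypoint table IO (DLC-compatible dialect)

KEYPOINT_COLUMNS = ["frame", "camera", "bodypart", "x", "y", "likelihood"]


def load_keypoints(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keypoint table missing column(s): {', '.join(missing)}")
    bad = set(df["bodypart"]) - set(FEATURE_ORDER)
    if bad:
        raise ValueError(f"unknown bodypart value(s): {sorted(bad)}")
    return df[KEYPOINT_COLUMNS].copy()


def save_keypoints(df: pd.DataFrame, path) -> None:
    df[KEYPOINT_COLUMNS].to_csv(path, index=False)
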