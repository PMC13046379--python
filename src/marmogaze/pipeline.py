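"""End-to-end pipeline: keypoint tables -> 3D face frames -> gaze events.

Stages mirror the acquisition design.  Middle cameras see exactly one
animal, so their per-frame feature centroid is triangulated to an
unambiguous 3D animal position.  These 3D centroids are projected into the
monitor-end cameras (which see both animals) to transfer identities onto
the two-cluster segmentation there.  Each animal's six features are then
triangulated from all four cameras of its own group (all camera pairs,
averaged), gaps interpolated, and the resulting face frames feed the gaze
geometry, stable-epoch segmentation and state classification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .camera import CameraRig, load_calibration, merge_world_frames, project, rmse, triangulate_multiview
from .gaze import (
    FEATURE_ORDER,
    FaceFrame3D,
    face_norm,
    gaze_cone,
    head_gaze_velocity,
    stable_epochs,
    velocity_magnitude,
)
from .intersections import FacialTriangle
from .mixstats import MixtureComponent, MixtureSpec, fit_mixture, sarle_bc
from .states import (
    EpochState,
    GazeState,
    bin_distance,
    classify_epochs,
    classify_frame,
    social_distance,
    transition_matrix,
)
from .synthetic import ArenaGeometry
from .tracking import (
    Candidate,
    cluster_features,
    interpolate_gaps_array,
    load_keypoints,
    remove_outliers,
    transfer_identity_cross_view,
)

GROUP_TO_ANIMAL = {"left_arena": 0, "right_arena": 1}


@dataclass
class PipelineConfig:
    """Every printed analysis constant, with its default value."""

    detection_threshold: float = 0.95
    max_candidates_per_label: int = 2
    outlier_sd_multiplier: float = 2.0
    velocity_threshold: float = 0.05
    min_epoch_length: int = 3
    cone_half_angle_deg: float = 10.0
    triangle_grid_n: int = 25
    volume_grid_n: int = 40
    max_jump_px: float = 100.0
    max_gap_frames: int = 5
    frame_rate: float = 30.0
    match_radius_px: float = 300.0
    seed: int = 0
    units: str = "mm"  # arena dimensions unit; 'cm' converts on load
    arena_length: float = 609.6
    arena_width: float = 304.8
    arena_height: float = 304.8
    arena_separation: float = 304.8
    bin_boundaries: tuple[float, float] | None = None  # None -> fit from data
    exclude_reciprocal_transitions: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must be in (0, 1)")
        if not 0.0 < self.cone_half_angle_deg < 90.0:
            raise ValueError("cone_half_angle_deg must be in (0, 90)")
        if self.min_epoch_length < 1 or self.max_candidates_per_label < 1:
            raise ValueError("counts must be positive")
        if self.units not in ("mm", "cm"):
            raise ValueError("units must be 'mm' or 'cm'")
        if self.units == "cm":
            for f in ("arena_length", "arena_width", "arena_height", "arena_separation"):
                setattr(self, f, getattr(self, f) * 10.0)
            self.units = "mm"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "bin_boundaries" in data and data["bin_boundaries"] is not None:
            data["bin_boundaries"] = tuple(data["bin_boundaries"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if data["bin_boundaries"] is not None:
            data["bin_boundaries"] = list(data["bin_boundaries"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def arena(self) -> ArenaGeometry:
        return ArenaGeometry(
            length=self.arena_length,
            width=self.arena_width,
            height=self.arena_height,
            separation=self.arena_separation,
        )


# ---------------------------------------------------------------------------
# stage 1: per-camera 2D clustering with identities


def _frame_candidates(group: pd.DataFrame, camera: str) -> list[Candidate]:
    out = []
    for row in group.itertuples(index=False):
        out.append(
            Candidate(
                label=row.bodypart,
                position=np.array([row.x, row.y]),
                confidence=row.likelihood,
                camera=camera,
                frame=int(row.frame),
            )
        )
    return out


def track2d(keypoints: pd.DataFrame, rig: CameraRig, config: PipelineConfig) -> pd.DataFrame:
    """Cluster per-frame candidates per camera and assign animal identities.

    Returns a tidy table (frame, camera, animal, bodypart, x, y).
    Middle-camera clusters take their group's animal directly; end-camera
    clusters are labeled by cross-view transfer of the middle-camera
    triangulated 3D centroids.
    """
    rig = merge_world_frames(rig)
    kp = keypoints[keypoints["likelihood"] > config.detection_threshold]
    frames = range(int(keypoints["frame"].min()), int(keypoints["frame"].max()) + 1)
    n_frames = len(frames)
    by_cam_frame = {k: g for k, g in kp.groupby(["camera", "frame"])}

    # middle-camera single-animal clusters -> per-animal 3D centroid tracks
    mid_clusters: dict[tuple[str, int], list] = {}
    centroids3d = {a: np.full((n_frames, 3), np.nan) for a in (0, 1)}
    valid3d = {a: np.zeros(n_frames, dtype=bool) for a in (0, 1)}
    for group_name, animal in GROUP_TO_ANIMAL.items():
        mids = [c for c in rig.group_cameras(group_name) if not c.sees_both_animals]
        for t in frames:
            obs = []
            for cam in mids:
                g = by_cam_frame.get((cam.id, t))
                if g is None:
                    continue
                cands = _frame_candidates(g, cam.id)
                if not cands:
                    continue
                cls = cluster_features(cands, n_clusters=1, seed=config.seed)
                cls = remove_outliers(cls, sd_multiplier=config.outlier_sd_multiplier)
                if cls and cls[0].members:
                    cls[0].animal = animal
                    mid_clusters[(cam.id, t)] = cls
                    obs.append((cam, cls[0].centroid))
            if len(obs) >= 2:
                p3 = triangulate_multiview(obs)
                lo, hi = config.arena.box(animal)
                pad = 50.0  # mm tolerance on the arena constraint
                if p3 is not None and np.all(p3 >= lo - pad) and np.all(p3 <= hi + pad):
                    centroids3d[animal][t - frames.start] = p3
                    valid3d[animal][t - frames.start] = True
    for a in (0, 1):
        centroids3d[a], valid3d[a] = interpolate_gaps_array(
            centroids3d[a], valid3d[a], max_gap=config.max_gap_frames
        )

    # end-camera two-animal clusters with transferred identities
    rows = []
    end_cams = [c for c in rig.cameras if c.sees_both_animals]
    for cam in end_cams:
        for t in frames:
            g = by_cam_frame.get((cam.id, t))
            if g is None:
                continue
            cands = _frame_candidates(g, cam.id)
            if not cands:
                continue
            clusters = cluster_features(cands, n_clusters=2, seed=config.seed)
            clusters = remove_outliers(clusters, sd_multiplier=config.outlier_sd_multiplier)
            cents = {
                a: centroids3d[a][t - frames.start]
                for a in (0, 1)
                if valid3d[a][t - frames.start]
            }
            labeled = transfer_identity_cross_view(
                cents, cam, clusters, match_radius=config.match_radius_px
            )
            for cl in labeled:
                if cl.animal is None:
                    continue
                for m in cl.members:
                    rows.append((t, cam.id, cl.animal, m.label, m.position[0], m.position[1]))
    for (cam_id, t), cls in mid_clusters.items():
        for cl in cls:
            for m in cl.members:
                rows.append((t, cam_id, cl.animal, m.label, m.position[0], m.position[1]))
    return pd.DataFrame(rows, columns=["frame", "camera", "animal", "bodypart", "x", "y"]).sort_values(
        ["frame", "camera", "animal", "bodypart"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# stage 2: 3D reconstruction


def reconstruct3d(tracked: pd.DataFrame, rig: CameraRig, config: PipelineConfig) -> pd.DataFrame:
    """Triangulate each animal's features from its own group's four cameras
    (all camera pairs averaged) and interpolate short gaps.

    Returns (frame, animal, bodypart, X, Y, Z, interpolated).
    """
    rig = merge_world_frames(rig)
    cams = {c.id: c for c in rig.cameras}
    if tracked.empty:
        return pd.DataFrame(columns=["frame", "animal", "bodypart", "X", "Y", "Z", "interpolated"])
    t0, t1 = int(tracked["frame"].min()), int(tracked["frame"].max())
    n_frames = t1 - t0 + 1
    group_cams = {a: [c.id for c in rig.group_cameras(g)] for g, a in ((g, a) for g, a in GROUP_TO_ANIMAL.items())}
    rows = []
    indexed = {k: g for k, g in tracked.groupby(["animal", "bodypart"])}
    for animal in (0, 1):
        for label in FEATURE_ORDER:
            pos = np.full((n_frames, 3), np.nan)
            valid = np.zeros(n_frames, dtype=bool)
            g = indexed.get((animal, label))
            if g is not None:
                for t, sub in g.groupby("frame"):
                    obs = [
                        (cams[r.camera], np.array([r.x, r.y]))
                        for r in sub.itertuples(index=False)
                        if r.camera in group_cams[animal]
                    ]
                    if len(obs) >= 2:
                        p3 = triangulate_multiview(obs)
                        if p3 is not None:
                            pos[int(t) - t0] = p3
                            valid[int(t) - t0] = True
            before = valid.copy()
            pos, valid = interpolate_gaps_array(pos, valid, max_gap=config.max_gap_frames)
            for i in range(n_frames):
                if valid[i]:
                    rows.append(
                        (t0 + i, animal, label, pos[i, 0], pos[i, 1], pos[i, 2], not before[i])
                    )
    return pd.DataFrame(rows, columns=["frame", "animal", "bodypart", "X", "Y", "Z", "interpolated"])


def faces_from_table(features3d: pd.DataFrame) -> dict[int, dict[int, FaceFrame3D]]:
    """Assemble per-animal, per-frame face frames; frames missing any of the
    six landmarks are omitted (invalid)."""
    faces: dict[int, dict[int, FaceFrame3D]] = {0: {}, 1: {}}
    for (animal, frame), g in features3d.groupby(["animal", "frame"]):
        lm = {r.bodypart: np.array([r.X, r.Y, r.Z]) for r in g.itertuples(index=False)}
        if set(lm) == set(FEATURE_ORDER):
            faces[int(animal)][int(frame)] = FaceFrame3D(
                animal=int(animal), frame=int(frame), landmarks=lm
            )
    return faces


# ---------------------------------------------------------------------------
# stage 3: gaze events


@dataclass
class GazeEvents:
    frame_states: list  # GazeState | None, indexed from frame 0
    epochs: dict[int, list]  # animal -> stable epochs
    epoch_states: list[EpochState]
    distances: np.ndarray  # per-frame social distance (mm), NaN where missing
    events: pd.DataFrame


def gaze_events(faces: dict[int, dict[int, FaceFrame3D]], config: PipelineConfig) -> GazeEvents:
    n_frames = max((max(d) + 1 for d in faces.values() if d), default=0)
    bounds = config.arena.overall_bounds()

    norms = {a: np.full((n_frames, 3), np.nan) for a in (0, 1)}
    cones = {a: [None] * n_frames for a in (0, 1)}
    tris = {a: [None] * n_frames for a in (0, 1)}
    for a in (0, 1):
        for t, face in faces[a].items():
            try:
                norms[a][t] = face_norm(face)
                cones[a][t] = gaze_cone(face, theta=config.cone_half_angle_deg)
                tris[a][t] = FacialTriangle.from_face(face)
            except ValueError:
                continue

    frame_states = []
    distances = np.full(n_frames, np.nan)
    for t in range(n_frames):
        frame_states.append(
            classify_frame(
                cones[0][t],
                tris[0][t],
                cones[1][t],
                tris[1][t],
                search_bounds=bounds,
                grid_n=config.volume_grid_n,
                tri_grid_n=config.triangle_grid_n,
            )
        )
        fa, fb = faces[0].get(t), faces[1].get(t)
        distances[t] = social_distance(fa, fb)

    epochs = {}
    for a in (0, 1):
        if n_frames >= 5:
            v = head_gaze_velocity(norms[a])
            epochs[a] = stable_epochs(
                velocity_magnitude(v),
                animal=a,
                threshold=config.velocity_threshold,
                min_length=config.min_epoch_length,
            )
        else:
            epochs[a] = []
    epoch_states = classify_epochs(epochs[0], epochs[1], frame_states)

    boundaries = config.bin_boundaries or distance_bin_boundaries(
        distances[np.isfinite(distances)], seed=config.seed
    )
    rows = []
    for ep in epoch_states:
        d = distances[ep.start : ep.end + 1]
        d = d[np.isfinite(d)]
        mean_d = float(d.mean()) if len(d) else float("nan")
        ep.mean_distance_mm = mean_d
        if np.isfinite(mean_d) and boundaries is not None:
            ep.distance_bin = bin_distance(mean_d, boundaries).value
        rows.append((ep.start, ep.end, ep.state.value, mean_d, ep.distance_bin))
    events = pd.DataFrame(
        rows, columns=["start_frame", "end_frame", "state", "mean_distance_mm", "bin"]
    )
    return GazeEvents(
        frame_states=frame_states,
        epochs=epochs,
        epoch_states=epoch_states,
        distances=distances,
        events=events,
    )


def distance_bin_boundaries(distances: np.ndarray, seed: int = 0) -> tuple[float, float] | None:
    """Near/Intermediate/Far boundaries as the intersections of adjacent
    components of a tri-Gaussian mixture fitted to the social-distance
    sample; falls back to terciles when the fit is not feasible."""
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 10:
        return None
    try:
        q = np.quantile(d, [0.2, 0.5, 0.8])
        spec = MixtureSpec(
            [
                MixtureComponent("gaussian", {"mean": q[0], "sd": d.std() / 3 + 1e-6}),
                MixtureComponent("gaussian", {"mean": q[1], "sd": d.std() / 3 + 1e-6}),
                MixtureComponent("gaussian", {"mean": q[2], "sd": d.std() / 3 + 1e-6}),
            ]
        )
        fit = fit_mixture(d, spec, seed=seed)
        comps = sorted(zip(fit.weights, fit.components), key=lambda wc: wc[1].mean)
        bnds = []
        for (w1, c1), (w2, c2) in zip(comps[:-1], comps[1:]):
            m1, m2 = c1.mean, c2.mean
            if not m1 < m2:
                raise RuntimeError
            f = lambda x: w1 * c1.pdf(np.array([x]))[0] - w2 * c2.pdf(np.array([x]))[0]
            if f(m1) * f(m2) < 0:
                bnds.append(brentq(f, m1, m2))
            else:
                bnds.append(0.5 * (m1 + m2))
        b1, b2 = bnds
        if not b1 < b2:
            raise RuntimeError
        return (float(b1), float(b2))
    except Exception:
        q = np.quantile(d, [1 / 3, 2 / 3])
        if q[0] < q[1]:
            return (float(q[0]), float(q[1]))
        return None


# ---------------------------------------------------------------------------
# stage 4: transitions and summary statistics


def transitions_report(events: pd.DataFrame, exclude_reciprocal: bool = True) -> dict:
    seq = [GazeState(s) for s in events["state"]]
    if exclude_reciprocal:
        seq = [s for s in seq if s is not GazeState.reciprocal]
    states = [s.value for s in GazeState if not (exclude_reciprocal and s is GazeState.reciprocal)]
    if len(seq) < 2:
        return {"states": states, "counts": None, "probs": None}
    tm = transition_matrix(seq, states=states)
    return {
        "states": tm.states,
        "counts": tm.counts.tolist(),
        "probs": [[None if np.isnan(p) else float(p) for p in row] for row in tm.probs],
    }


def stats_report(ev: GazeEvents, faces: dict, config: PipelineConfig) -> dict:
    d = ev.distances[np.isfinite(ev.distances)]
    out: dict = {
        "n_frames": len(ev.frame_states),
        "n_epochs": len(ev.epoch_states),
        "state_frame_counts": {
            s.value: sum(1 for x in ev.frame_states if x is s) for s in GazeState
        },
        "social_distance_mm": {
            "mean": float(d.mean()) if len(d) else None,
            "min": float(d.min()) if len(d) else None,
            "max": float(d.max()) if len(d) else None,
        },
        "seed": config.seed,
    }
    for a in (0, 1):
        z = np.array([f.centroid[2] for f in faces[a].values()])
        if len(z) >= 4 and np.std(z) > 0:
            bc = sarle_bc(z)
            out[f"animal{a}_z_bimodality"] = {"bc": bc.bc, "is_bimodal": bc.is_bimodal}
    return out


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    keypoints_path,
    calibration_path,
    config: PipelineConfig | None = None,
    outdir=None,
) -> dict:
    """Full pipeline: keypoint CSV + calibration YAML -> features3d.csv,
    events.csv, transitions.json, stats.json.  Deterministic given the
    config seed."""
    config = config or PipelineConfig()
    keypoints = load_keypoints(keypoints_path)
    rig = merge_world_frames(load_calibration(calibration_path))
    tracked = track2d(keypoints, rig, config)
    features3d = reconstruct3d(tracked, rig, config)
    faces = faces_from_table(features3d)
    ev = gaze_events(faces, config)
    trans = transitions_report(ev.events, exclude_reciprocal=config.exclude_reciprocal_transitions)
    stats = stats_report(ev, faces, config)
    result = {
        "tracked": tracked,
        "features3d": features3d,
        "events": ev.events,
        "gaze": ev,
        "transitions": trans,
        "stats": stats,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features3d.to_csv(outdir / "features3d.csv", index=False)
        ev.events.to_csv(outdir / "events.csv", index=False)
        with open(outdir / "transitions.json", "w") as fh:
            json.dump(trans, fh, indent=2)
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2)
    return result


def validate(features3d: pd.DataFrame, ground_truth: pd.DataFrame) -> dict:
    """3D RMSE and per-feature error quantiles of reconstructed features
    against a ground-truth landmark table (matched on frame/animal/bodypart)."""
    merged = features3d.merge(
        ground_truth, on=["frame", "animal", "bodypart"], suffixes=("", "_gt")
    )
    if merged.empty:
        raise ValueError("no overlapping (frame, animal, bodypart) rows to validate")
    est = merged[["X", "Y", "Z"]].to_numpy()
    gt = merged[["X_gt", "Y_gt", "Z_gt"]].to_numpy()
    err = np.linalg.norm(est - gt, axis=1)
    report = {
        "rmse_mm": rmse(gt, est),
        "n": int(len(merged)),
        "per_feature_quantiles_mm": {},
    }
    for label, g in merged.assign(err=err).groupby("bodypart"):
        q = np.quantile(g["err"], [0.5, 0.9, 0.99])
        report["per_feature_quantiles_mm"][label] = {
            "q50": float(q[0]),
            "q90": float(q[1]),
            "q99": float(q[2]),
        }
    return report
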