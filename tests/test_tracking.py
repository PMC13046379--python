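"""Candidate selection, constrained clustering, outlier removal, identity
linking, cross-view transfer, gap interpolation."""

import itertools

import numpy as np
import pytest

from marmogaze.tracking import (
    Candidate,
    CentroidTrack,
    FeatureCluster,
    cluster_features,
    compute_centroids,
    interpolate_gaps,
    link_identities,
    load_keypoints,
    remove_outliers,
    select_candidates,
    transfer_identity_cross_view,
)
from marmogaze.gaze import FEATURE_ORDER
from conftest import make_camera


def face_candidates(center, labels=FEATURE_ORDER, spread=15.0, conf=0.99):
    offsets = {
        "right_eye": (-spread, 0),
        "left_eye": (spread, 0),
        "central_blaze": (0, -spread),
        "mouth": (0, spread),
        "right_tuft": (-2 * spread, -5),
        "left_tuft": (2 * spread, -5),
    }
    return [
        Candidate(label=l, position=np.asarray(center) + offsets[l], confidence=conf)
        for l in labels
    ]


class TestSelectCandidates:
    def test_top_two_retained(self):
        peaks = {"left_eye": [((0, 0), 0.99), ((5, 5), 0.97), ((9, 9), 0.96)]}
        out = select_candidates(peaks)
        assert [c.confidence for c in out] == [0.99, 0.97]

    def test_all_below_threshold_empty(self):
        assert select_candidates({"mouth": [((0, 0), 0.95), ((1, 1), 0.5)]}) == []

    def test_single_peak_above(self):
        out = select_candidates({"mouth": [((3, 4), 0.96), ((9, 9), 0.90)]})
        assert len(out) == 1 and np.allclose(out[0].position, [3, 4])


def total_within_cluster_distance(clusters):
    total = 0.0
    for cl in clusters:
        if not cl.members:
            continue
        cen = cl.centroid
        total += sum(np.linalg.norm(m.position - cen) for m in cl.members)
    return total


def brute_force_oracle(candidates):
    """Minimal total within-cluster distance over all feasible 2-cluster
    assignments (each cluster at most one candidate per label)."""
    best = np.inf
    n = len(candidates)
    for mask in itertools.product([0, 1], repeat=n):
        clusters = [FeatureCluster(), FeatureCluster()]
        for c, m in zip(candidates, mask):
            clusters[m].members.append(c)
        if any(cl.has_duplicate_labels() for cl in clusters):
            continue
        best = min(best, total_within_cluster_distance(clusters))
    return best


class TestClusterFeatures:
    def test_well_separated_faces(self):
        cands = face_candidates((100, 100)) + face_candidates((500, 100))
        clusters = cluster_features(cands, seed=0)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [6, 6]
        assert not any(c.has_duplicate_labels() for c in clusters)

    def test_uniqueness_after_repair(self):
        """A stray duplicate near the wrong face is moved or dropped."""
        cands = face_candidates((100, 100)) + face_candidates((500, 100))
        cands.append(Candidate("left_eye", (130, 95), 0.97))  # dup near face 1
        clusters = cluster_features(cands, seed=0)
        assert not any(c.has_duplicate_labels() for c in clusters)

    def test_matches_exhaustive_oracle(self):
        cands = face_candidates((100, 100), FEATURE_ORDER[:4]) + face_candidates(
            (400, 100), FEATURE_ORDER[:4]
        )
        clusters = cluster_features(cands, seed=0)
        got = total_within_cluster_distance(clusters)
        assert np.isclose(got, brute_force_oracle(cands), atol=1e-9)

    def test_single_animal_one_empty_cluster(self):
        clusters = cluster_features(face_candidates((200, 200)), seed=0)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [0, 6]


class TestRemoveOutliers:
    def test_far_point_removed(self):
        pts = [(0, 0), (5, 0), (0, 5), (5, 5), (2, 2), (200, 200)]
        cl = FeatureCluster(
            members=[Candidate(l, p, 0.99) for l, p in zip(FEATURE_ORDER, pts)]
        )
        out = remove_outliers([cl])
        positions = [tuple(m.position) for m in out[0].members]
        assert (200.0, 200.0) not in positions and len(out[0].members) == 5

    def test_coincident_points_kept(self):
        cl = FeatureCluster(
            members=[Candidate(l, (10, 10), 0.99) for l in FEATURE_ORDER[:4]]
        )
        out = remove_outliers([cl])
        assert len(out[0].members) == 4

    def test_small_cluster_passthrough(self):
        cl = FeatureCluster(members=[Candidate("mouth", (0, 0), 0.99), Candidate("left_eye", (500, 500), 0.99)])
        out = remove_outliers([cl])
        assert len(out[0].members) == 2

    def test_equal_distances_never_removed(self):
        # equilateral triangle: all pairwise distances equal -> SD 0, keep all
        pts = [(0, 0), (10, 0), (5, 10 * np.sin(np.pi / 3))]
        cl = FeatureCluster(members=[Candidate(l, p, 0.99) for l, p in zip(FEATURE_ORDER, pts)])
        out = remove_outliers([cl])
        assert len(out[0].members) == 3


class TestComputeCentroids:
    def test_mean_and_single(self):
        cl = FeatureCluster(members=[Candidate("mouth", (0, 0), 1.0), Candidate("left_eye", (10, 10), 1.0)])
        single = FeatureCluster(members=[Candidate("mouth", (7, 3), 1.0)])
        cents = compute_centroids([cl, single, FeatureCluster()])
        assert np.allclose(cents[0], [5, 5])
        assert np.allclose(cents[1], [7, 3])
        assert cents[2] is None

    def test_six_member_hand_mean(self):
        pts = [(0, 0), (6, 0), (0, 6), (6, 6), (3, 3), (3, 0)]
        cl = FeatureCluster(members=[Candidate(l, p, 1.0) for l, p in zip(FEATURE_ORDER, pts)])
        assert np.allclose(cl.centroid, [3.0, 2.5])


class TestLinkIdentities:
    def test_smooth_tracks_no_swaps(self):
        t = np.arange(300)
        a = np.column_stack([100 + 0.5 * t, 100 + 10 * np.sin(t / 30)])
        b = np.column_stack([800 - 0.5 * t, 500 + 10 * np.cos(t / 30)])
        frames = [[a[i], b[i]] for i in t]
        tracks = link_identities(frames, max_jump=100.0)
        assert np.allclose(tracks[0].positions, a)
        assert np.allclose(tracks[1].positions, b)

    def test_identity_preserved_across_gap(self):
        t = np.arange(60)
        a = np.column_stack([100 + t, np.full(60, 100.0)])
        b = np.column_stack([800 - t, np.full(60, 500.0)])
        frames = []
        for i in t:
            dets = [b[i]] if 20 <= i <= 22 else [a[i], b[i]]  # a missing 3 frames
            frames.append(dets)
        tracks = link_identities(frames, max_jump=100.0)
        assert not tracks[0].valid[20:23].any()
        assert np.allclose(tracks[0].positions[23:], a[23:])
        assert tracks[1].valid.all()

    def test_jump_gate_refuses_assignment(self):
        frames = [[np.array([0.0, 0.0])], [np.array([500.0, 0.0])]]
        tracks = link_identities(frames, max_jump=100.0)
        assert tracks[0].valid[0] and not tracks[0].valid[1]

    def test_equidistant_tie_keeps_indices(self):
        frames = [
            [np.array([0.0, 0.0]), np.array([10.0, 0.0])],
            [np.array([5.0, 1.0]), np.array([5.0, -1.0])],  # equidistant to both
        ]
        tracks = link_identities(frames, max_jump=100.0)
        assert np.allclose(tracks[0].positions[1], [5.0, 1.0])
        assert np.allclose(tracks[1].positions[1], [5.0, -1.0])


class TestTransferIdentity:
    def setup_method(self):
        self.cam = make_camera([-400.0, 150.0, 150.0], [300.0, 150.0, 150.0], "ML1")

    def _cluster_at(self, px):
        return FeatureCluster(members=[Candidate("mouth", px, 0.99)])

    def test_nearest_cluster_inherits_label(self):
        p3 = {0: np.array([200.0, 150.0, 150.0])}
        from marmogaze.camera import project

        px = project(self.cam, p3[0])
        near = self._cluster_at(px + [8.0, 0.0])
        far = self._cluster_at(px + [300.0, 0.0])
        out = transfer_identity_cross_view(p3, self.cam, [near, far])
        assert near.animal == 0 and far.animal is None

    def test_out_of_arena_cluster_excluded(self):
        p3 = {0: np.array([200.0, 150.0, 150.0])}
        from marmogaze.camera import project

        px = project(self.cam, p3[0])
        cl = self._cluster_at(px)
        bounds = {0: (np.zeros(3), np.full(3, 300.0))}
        out = transfer_identity_cross_view(
            p3, self.cam, [cl], arena_bounds=bounds, cluster_positions_3d=[np.array([900.0, 0, 0])]
        )
        assert out == []

    def test_contended_projection_resolved_by_assignment(self):
        from marmogaze.camera import project

        p3 = {0: np.array([200.0, 140.0, 150.0]), 1: np.array([200.0, 160.0, 150.0])}
        px0 = project(self.cam, p3[0])
        px1 = project(self.cam, p3[1])
        # both clusters closest to projection 0, but optimal 2x2 assignment
        # pairs each with its own
        c_a = self._cluster_at(px0 + [1.0, 0.0])
        c_b = self._cluster_at(0.7 * px0 + 0.3 * px1)
        out = transfer_identity_cross_view(p3, self.cam, [c_a, c_b])
        assert {cl.animal for cl in out} == {0, 1}
        assert c_a.animal == 0


class TestInterpolateGaps:
    def _track(self, valid_frames, T=20):
        pos = np.full((T, 3), np.nan)
        valid = np.zeros(T, dtype=bool)
        for f in valid_frames:
            pos[f] = [float(f), 2.0 * f, 0.0]
            valid[f] = True
        return CentroidTrack(animal=0, positions=pos, valid=valid)

    def test_linear_fill(self):
        tr = interpolate_gaps(self._track([10, 13]))
        assert tr.valid[11] and tr.valid[12]
        assert np.allclose(tr.positions[11], [11.0, 22.0, 0.0])
        assert np.allclose(tr.positions[12], [12.0, 24.0, 0.0])

    def test_long_gap_left_missing(self):
        tr = interpolate_gaps(self._track([0, 7]), max_gap=5)
        assert not tr.valid[1:7].any()

    def test_leading_trailing_not_extrapolated(self):
        tr = interpolate_gaps(self._track([5, 6]))
        assert not tr.valid[:5].any() and not tr.valid[7:].any()

    def test_valid_samples_bit_identical(self):
        base = self._track([3, 5, 9])
        tr = interpolate_gaps(base)
        for f in (3, 5, 9):
            assert np.array_equal(tr.positions[f], base.positions[f])


class TestKeypointIO:
    def test_missing_column_named(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"frame": [0], "camera": ["ML1"], "bodypart": ["mouth"], "x": [1.0], "y": [2.0]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="likelihood"):
            load_keypoints(path)

    def test_unknown_bodypart_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad2.csv"
        pd.DataFrame(
            {
                "frame": [0],
                "camera": ["ML1"],
                "bodypart": ["tail"],
                "x": [1.0],
                "y": [2.0],
                "likelihood": [0.99],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="tail"):
            load_keypoints(path)
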