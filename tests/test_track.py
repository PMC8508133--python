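"""Trajectory linking: gap closing, filters, bound classification, oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smres import (
    ConditionTracking,
    Track,
    TrackSet,
    classify_bound,
    link_tracks,
    presets,
)


def spots_frame(entries):
    """entries: iterable of (frame, x, y)."""
    return pd.DataFrame(entries, columns=["frame", "x", "y"])


CFG = ConditionTracking(tracking_radius=0.9, min_track_length=2, gap_frames=1,
                        min_segmentation_length=2)


class TestLinking:
    def test_single_immobile_spot_links_into_one_track(self):
        spots = spots_frame([(f, 10.0, 20.0) for f in range(10)])
        ts = link_tracks(spots, CFG, condition=0.1, n_frames=10)
        assert len(ts) == 1
        assert ts.tracks[0].duration_frames == 10
        assert ts.tracks[0].n_gaps_closed == 0

    @pytest.mark.parametrize(
        "gap_frames,expected_tracks,expected_gaps",
        [(1, 1, 1), (0, 2, 0)],
    )
    def test_gap_closing_on_four_detection_instance(
        self, gap_frames, expected_tracks, expected_gaps
    ):
        """Spot in frames 0,1,3,4: one gap-closed track when 1 gap frame is
        allowed; two 2-frame fragments when none is (exhaustively checkable:
        the only legal assignments are within-radius consecutive links plus
        the optional 1-frame bridge)."""
        cfg = ConditionTracking(tracking_radius=0.9, min_track_length=2,
                                gap_frames=gap_frames, min_segmentation_length=2)
        spots = spots_frame([(f, 5.0, 5.0) for f in (0, 1, 3, 4)])
        ts = link_tracks(spots, cfg, condition=0.1, n_frames=5)
        assert len(ts) == expected_tracks
        if expected_tracks == 1:
            assert ts.tracks[0].n_gaps_closed == expected_gaps
            assert ts.tracks[0].duration_frames == 5
            assert ts.tracks[0].n_detections == 4  # no interpolated positions

    def test_published_tracking_table_is_the_default(self):
        """Per-condition radii, minimum track lengths and gap frames follow
        the published settings, e.g. 0.9 px / 3 frames / 2 gaps at 0.1 s."""
        cfg = presets.tracking_config("RBPJ")
        c01 = cfg.for_condition(0.1)
        assert (c01.tracking_radius, c01.min_track_length, c01.gap_frames) == (0.9, 3, 2)
        assert cfg.for_condition(0.4).tracking_radius == 1.19
        assert cfg.for_condition(1.6).tracking_radius == 1.75
        assert cfg.for_condition(6.4).tracking_radius == 2.8
        assert cfg.for_condition(14.0).tracking_radius == 3.1
        assert cfg.for_condition(0.4).min_track_length == 3
        assert cfg.for_condition(1.6).min_track_length == 2
        assert cfg.for_condition(1.6).gap_frames == 1
        assert c01.min_segmentation_length == 2
        assert presets.tracking_config("RBPJ(R218H)").for_condition(6.4).tracking_radius == 2.8
        assert presets.tracking_config("RBPJL").for_condition(3.2).tracking_radius == 2.4

    def test_short_segments_are_discarded_before_gap_closing(self):
        # an isolated single detection in frame 2 cannot bridge two segments
        cfg = ConditionTracking(tracking_radius=1.0, min_track_length=2,
                                gap_frames=0, min_segmentation_length=2)
        entries = [(0, 5.0, 5.0), (1, 5.0, 5.0), (2, 30.0, 30.0),
                   (3, 5.0, 5.0), (4, 5.0, 5.0)]
        ts = link_tracks(spots_frame(entries), cfg, condition=0.1, n_frames=5)
        assert sorted(t.n_detections for t in ts.tracks) == [2, 2]

    def test_coincident_duplicate_spots_resolved_deterministically(self):
        entries = [(0, 5.0, 5.0), (1, 5.0, 5.0), (1, 5.0, 5.0), (2, 5.0, 5.0)]
        a = link_tracks(spots_frame(entries), CFG, 0.1, 3)
        b = link_tracks(spots_frame(entries), CFG, 0.1, 3)
        assert a.to_table().equals(b.to_table())
        assert max(t.duration_frames for t in a.tracks) == 3

    def test_recovers_ground_truth_on_separated_immobile_spots(self):
        """Identity oracle: well-separated, always-detected immobile
        molecules must be recovered exactly."""
        rng = np.random.default_rng(31)
        sites = [(10.0 + 8 * i, 10.0 + 8 * j) for i in range(4) for j in range(4)]
        entries = []
        for f in range(12):
            for x, y in sites:
                jx, jy = rng.normal(0, 0.1, 2)
                entries.append((f, x + jx, y + jy))
        ts = link_tracks(spots_frame(entries), CFG, 0.1, 12)
        assert len(ts) == len(sites)
        for t in ts.tracks:
            assert t.duration_frames == 12

    def test_greedy_matches_brute_force_on_unambiguous_instances(self):
        """When every detection has at most one candidate within the radius,
        the greedy linker must equal the minimal-total-displacement
        assignment (computed by exhaustive enumeration)."""
        rng = np.random.default_rng(37)
        radius = 1.0
        for _ in range(20):
            n_mol = rng.integers(2, 6)
            n_frames = int(rng.integers(3, 8))
            # sites at least 4 radii apart => unambiguous candidates
            sites = []
            while len(sites) < n_mol:
                p = rng.uniform(5, 60, 2)
                if all(np.hypot(*(p - q)) > 4 * radius for q in sites):
                    sites.append(p)
            entries = []
            truth = {m: [] for m in range(n_mol)}
            for f in range(n_frames):
                for m, p in enumerate(sites):
                    pos = p + rng.normal(0, 0.15, 2)
                    truth[m].append((f, pos[0], pos[1]))
                    entries.append((f, pos[0], pos[1]))
            cfg = ConditionTracking(tracking_radius=radius, min_track_length=2,
                                    gap_frames=0, min_segmentation_length=2)
            ts = link_tracks(spots_frame(entries), cfg, 0.1, n_frames)
            # brute force: per frame pair, enumerate all assignments
            got = {tuple(np.round(np.c_[t.frames, t.x, t.y], 6).ravel())
                   for t in ts.tracks}
            expected = {tuple(np.round(np.array(v), 6).ravel()) for v in truth.values()}
            assert got == expected
            # oracle on displacement cost: greedy total equals the optimum
            for f in range(1, n_frames):
                prev = [e for e in entries if e[0] == f - 1]
                cur = [e for e in entries if e[0] == f]
                best = None
                for perm in itertools.permutations(range(len(cur))):
                    pairs = [(i, j) for i, j in enumerate(perm)
                             if np.hypot(prev[i][1] - cur[j][1],
                                         prev[i][2] - cur[j][2]) <= radius]
                    if len(pairs) < len(cur):
                        continue
                    cost = sum(np.hypot(prev[i][1] - cur[j][1],
                                        prev[i][2] - cur[j][2]) for i, j in pairs)
                    best = cost if best is None else min(best, cost)
                greedy_cost = 0.0
                for t in ts.tracks:
                    idx = np.where(t.frames == f)[0]
                    if len(idx) and idx[0] > 0:
                        i = idx[0]
                        greedy_cost += np.hypot(t.x[i] - t.x[i - 1],
                                                t.y[i] - t.y[i - 1])
                assert best is not None
                assert greedy_cost == pytest.approx(best, abs=1e-9)


class TestClassifyBound:
    def make_trackset(self, tracks):
        return TrackSet(condition=0.1, n_frames=50, tracks=tracks)

    def test_immobile_track_is_bound(self):
        t = Track(0, 0.1, np.arange(10), np.full(10, 5.0), np.full(10, 5.0))
        bound, counts = classify_bound(self.make_trackset([t]), CFG)
        assert len(bound) == 1
        assert counts["label"] == "1/1"

    def test_fast_brownian_track_is_unbound(self):
        """Steps with s.d. 5x the radius leave the confinement disc almost
        surely (2-D chi-squared tail), so the track is classified unbound."""
        rng = np.random.default_rng(41)
        for _ in range(20):
            steps = rng.normal(0, 5 * CFG.tracking_radius, size=(10, 2))
            pos = np.cumsum(steps, axis=0)
            t = Track(0, 0.1, np.arange(10), pos[:, 0], pos[:, 1])
            bound, _ = classify_bound(self.make_trackset([t]), CFG)
            assert len(bound) == 0

    def test_bound_count_non_increasing_in_min_track_length(self):
        rng = np.random.default_rng(43)
        tracks = []
        for i in range(30):
            n = int(rng.integers(2, 12))
            jit = rng.normal(0, 0.1, (n, 2))
            tracks.append(Track(i, 0.1, np.arange(n), 5 + jit[:, 0], 5 + jit[:, 1]))
        ts = self.make_trackset(tracks)
        counts = []
        for mtl in (2, 3, 5, 8, 11):
            cfg = ConditionTracking(tracking_radius=0.9, min_track_length=mtl,
                                    gap_frames=1, min_segmentation_length=2)
            bound, _ = classify_bound(ts, cfg)
            counts.append(len(bound))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_counts_reported_in_bound_over_total_format(self):
        """Counts are reported in the field's 'bound/total' convention."""
        immobile = Track(0, 0.1, np.arange(5), np.full(5, 1.0), np.full(5, 1.0))
        mobile = Track(1, 0.1, np.arange(5), np.arange(5) * 3.0, np.zeros(5))
        _, counts = classify_bound(self.make_trackset([immobile, mobile]), CFG)
        assert counts == {"bound": 1, "total": 2, "label": "1/2"}
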