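"""Linking of per-frame localizations into single-molecule trajectories.

The linker is a deterministic radius-gated greedy nearest-pair assignment:

1. *Segmentation* — consecutive-frame detections are joined by repeatedly
   linking the closest unmatched (track end, new spot) pair whose distance
   is within the tracking radius.
2. Contiguous segments shorter than the minimum segmentation length are
   discarded (spurious one-off detections).
3. *Gap closing* — a segment start may be connected to a segment end up to
   ``gap_frames`` frames earlier, again closest pair first, within the same
   radius.  Gap-closed frames contribute to a track's duration but add no
   positions.
4. Tracks spanning fewer frames than the minimum track length are dropped.

Bound molecules are then selected by confinement: every detection must stay
within the tracking radius of the track's first detection for at least the
minimum track length.  Freely diffusing molecules exceed the radius within a
frame or two and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionTracking",
    "TrackingConfig",
    "Track",
    "TrackSet",
    "link_tracks",
    "classify_bound",
]


@dataclass(frozen=True)
class ConditionTracking:
    """Linker settings for one time-lapse condition."""

    tracking_radius: float
    min_track_length: int = 2
    gap_frames: int = 1
    min_segmentation_length: int = 2
    #: whether min_track_length counts frames spanned (including gap-closed
    #: frames) rather than detections only
    count_gap_frames: bool = True

    def __post_init__(self) -> None:
        if self.tracking_radius <= 0:
            raise ValueError("tracking_radius must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.gap_frames < 0:
            raise ValueError("gap_frames must be >= 0")
        if self.min_segmentation_length < 1:
            raise ValueError("min_segmentation_length must be >= 1")


@dataclass(frozen=True)
class TrackingConfig:
    """Per-condition linker settings keyed by frame cycle time (s)."""

    per_condition: dict[float, ConditionTracking]

    def for_condition(self, cycle_time: float) -> ConditionTracking:
        for tau, cfg in self.per_condition.items():
            if math.isclose(tau, cycle_time, rel_tol=1e-9):
                return cfg
        raise KeyError(f"no tracking settings for cycle time {cycle_time} s")

    def to_dict(self) -> dict:
        return {
            str(tau): {
                "tracking_radius": c.tracking_radius,
                "min_track_length": c.min_track_length,
                "gap_frames": c.gap_frames,
                "min_segmentation_length": c.min_segmentation_length,
                "count_gap_frames": c.count_gap_frames,
            }
            for tau, c in self.per_condition.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        return cls(
            {
                float(tau): ConditionTracking(
                    tracking_radius=c["tracking_radius"],
                    min_track_length=c.get("min_track_length", 2),
                    gap_frames=c.get("gap_frames", 1),
                    min_segmentation_length=c.get("min_segmentation_length", 2),
                    count_gap_frames=c.get("count_gap_frames", True),
                )
                for tau, c in d.items()
            }
        )


@dataclass
class Track:
    track_id: int
    condition: float  # frame cycle time, s
    frames: np.ndarray  # detection frames, strictly increasing (gaps allowed)
    x: np.ndarray
    y: np.ndarray
    n_gaps_closed: int = 0

    @property
    def duration_frames(self) -> int:
        """Frames spanned from first to last detection, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def n_detections(self) -> int:
        return len(self.frames)

    def duration_seconds(self, cycle_time: float | None = None) -> float:
        tau = self.condition if cycle_time is None else cycle_time
        return (self.duration_frames - 1) * tau


@dataclass
class TrackSet:
    """Linked trajectories of one time-lapse condition."""

    condition: float
    n_frames: int
    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def durations_frames(self) -> np.ndarray:
        return np.array([t.duration_frames for t in self.tracks], dtype=np.int64)

    def to_table(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x": t.x,
                    "y": t.y,
                    "condition": self.condition,
                }
            )
            for t in self.tracks
        ]
        if not parts:
            return pd.DataFrame(columns=["track_id", "frame", "x", "y", "condition"])
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, condition: float, n_frames: int,
        id_column: str = "track_id",
    ) -> "TrackSet":
        tracks = []
        for tid, grp in table.groupby(id_column, sort=True):
            grp = grp.sort_values("frame")
            tracks.append(
                Track(
                    track_id=int(tid),
                    condition=condition,
                    frames=grp["frame"].to_numpy(dtype=np.int64),
                    x=grp["x"].to_numpy(dtype=np.float64),
                    y=grp["y"].to_numpy(dtype=np.float64),
                )
            )
        return cls(condition=condition, n_frames=n_frames, tracks=tracks)


class _Segment:
    __slots__ = ("frames", "x", "y")

    def __init__(self, frame: int, x: float, y: float):
        self.frames = [frame]
        self.x = [x]
        self.y = [y]


def _greedy_pairs(
    ends: np.ndarray, starts: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy closest-pair matching under a distance gate.

    Candidate pairs are ordered by (distance, end index, start index) so ties
    — including exactly coincident duplicate spots — resolve by input order.
    """
    if len(ends) == 0 or len(starts) == 0:
        return []
    d = np.hypot(
        ends[:, None, 0] - starts[None, :, 0], ends[:, None, 1] - starts[None, :, 1]
    )
    ei, si = np.nonzero(d <= radius)
    order = np.lexsort((si, ei, d[ei, si]))
    used_e: set[int] = set()
    used_s: set[int] = set()
    pairs = []
    for idx in order:
        e, s = int(ei[idx]), int(si[idx])
        if e in used_e or s in used_s:
            continue
        used_e.add(e)
        used_s.add(s)
        pairs.append((e, s))
    return pairs


def link_tracks(
    spots: pd.DataFrame,
    config: ConditionTracking,
    condition: float,
    n_frames: int | None = None,
) -> TrackSet:
    """Link a spots table (columns frame, x, y) into trajectories."""
    for col in ("frame", "x", "y"):
        if col not in spots.columns:
            raise ValueError(f"spots table lacks column {col!r}")
    if n_frames is None:
        n_frames = int(spots["frame"].max()) + 1 if len(spots) else 0

    by_frame: dict[int, np.ndarray] = {
        int(f): grp[["x", "y"]].to_numpy(dtype=np.float64)
        for f, grp in spots.sort_values(["frame"]).groupby("frame")
    }

    # stage 1: consecutive-frame segments
    open_segs: list[_Segment] = []
    closed: list[_Segment] = []
    for f in sorted(by_frame):
        pts = by_frame[f]
        still_open = [s for s in open_segs if s.frames[-1] == f - 1]
        closed.extend(s for s in open_segs if s.frames[-1] != f - 1)
        ends = np.array([[s.x[-1], s.y[-1]] for s in still_open]).reshape(-1, 2)
        pairs = _greedy_pairs(ends, pts, config.tracking_radius)
        matched_spots = set()
        next_open = []
        for e, s in pairs:
            seg = still_open[e]
            seg.frames.append(f)
            seg.x.append(float(pts[s, 0]))
            seg.y.append(float(pts[s, 1]))
            matched_spots.add(s)
            next_open.append(seg)
        closed.extend(
            seg for i, seg in enumerate(still_open) if i not in {p[0] for p in pairs}
        )
        for s in range(len(pts)):
            if s not in matched_spots:
                next_open.append(_Segment(f, float(pts[s, 0]), float(pts[s, 1])))
        open_segs = next_open
    closed.extend(open_segs)

    # stage 2: minimum segmentation length
    segs = [s for s in closed if len(s.frames) >= config.min_segmentation_length]
    segs.sort(key=lambda s: (s.frames[0], s.x[0], s.y[0]))

    # stage 3: gap closing between segments
    n = len(segs)
    succ = [-1] * n
    pred = [-1] * n
    cand = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            gap = segs[b].frames[0] - segs[a].frames[-1] - 1
            if 1 <= gap <= config.gap_frames:
                d = math.hypot(
                    segs[a].x[-1] - segs[b].x[0], segs[a].y[-1] - segs[b].y[0]
                )
                if d <= config.tracking_radius:
                    cand.append((d, segs[a].frames[-1], a, b))
    cand.sort()
    for d, _, a, b in cand:
        if succ[a] == -1 and pred[b] == -1:
            succ[a] = b
            pred[b] = a

    # stage 4: assemble chains and filter by minimum track length
    tracks: list[Track] = []
    tid = 0
    for i in range(n):
        if pred[i] != -1:
            continue
        frames: list[int] = []
        xs: list[float] = []
        ys: list[float] = []
        gaps = 0
        j = i
        while j != -1:
            frames.extend(segs[j].frames)
            xs.extend(segs[j].x)
            ys.extend(segs[j].y)
            if succ[j] != -1:
                gaps += 1
            j = succ[j]
        track = Track(
            track_id=tid,
            condition=condition,
            frames=np.array(frames, dtype=np.int64),
            x=np.array(xs),
            y=np.array(ys),
            n_gaps_closed=gaps,
        )
        length = (
            track.duration_frames if config.count_gap_frames else track.n_detections
        )
        if length >= config.min_track_length:
            track.track_id = tid
            tracks.append(track)
            tid += 1
    return TrackSet(condition=condition, n_frames=n_frames, tracks=tracks)


def classify_bound(
    trackset: TrackSet, config: ConditionTracking
) -> tuple[TrackSet, dict]:
    """Select chromatin-bound molecules by confinement.

    A track is bound when every detection lies within the tracking radius of
    its first detection and the track persists for at least the minimum
    track length.  Returns the bound subset and a counts dict in the
    ``bound/total`` reporting convention.
    """
    bound = []
    for t in trackset.tracks:
        r = np.hypot(t.x - t.x[0], t.y - t.y[0])
        length = t.duration_frames if config.count_gap_frames else t.n_detections
        if np.all(r <= config.tracking_radius) and length >= config.min_track_length:
            bound.append(t)
    counts = {
        "bound": len(bound),
        "total": len(trackset.tracks),
        "label": f"{len(bound)}/{len(trackset.tracks)}",
    }
    return (
        TrackSet(condition=trackset.condition, n_frames=trackset.n_frames, tracks=bound),
        counts,
    )
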