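"""Fluorescence survival-time distributions.

For each time-lapse condition the observed (bound) track durations are
assembled into an empirical survival function: for every duration t, the
number of tracks lasting at least t.  A track detected in m frames spans
(m - 1) frame cycles, so its duration is (m - 1) * tau — a two-detection
track evidences one cycle of persistence.

Distributions are kept as exact step functions; the spectrum fit consumes
them directly without binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import ImagingScheme
from .track import TrackSet

__all__ = ["SurvivalDistribution", "build_survival", "build_survivals"]


@dataclass
class SurvivalDistribution:
    """Empirical survival function of one condition's track durations.

    ``counts[i]`` is the number of tracks with duration >= ``durations[i]``;
    durations are the sorted unique observed values in seconds.  ``n_frames``
    (movie length in frames) is carried along so that downstream fitting can
    undo the finite-movie observation window.
    """

    cycle_time: float
    durations: np.ndarray
    counts: np.ndarray
    n_tracks: int
    n_frames: int

    def __post_init__(self) -> None:
        if len(self.durations) != len(self.counts):
            raise ValueError("durations and counts must have equal length")
        if len(self.counts) and (
            np.any(np.diff(self.counts) > 0) or self.counts[0] != self.n_tracks
        ):
            raise ValueError("survival counts must be non-increasing from n_tracks")

    @property
    def empty(self) -> bool:
        return self.n_tracks == 0

    def survival_at(self, t: np.ndarray | float) -> np.ndarray:
        """Right-continuous step evaluation: number of tracks with duration >= t."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        if self.empty:
            return np.zeros_like(t)
        idx = np.searchsorted(self.durations, t, side="left")
        ext = np.concatenate([self.counts, [0]])
        below = t <= self.durations[0]
        out = ext[np.minimum(idx, len(self.counts))].astype(np.float64)
        out[below] = self.n_tracks
        return out

    @classmethod
    def from_durations_frames(
        cls, spans: np.ndarray, cycle_time: float, n_frames: int
    ) -> "SurvivalDistribution":
        """Build from per-track frame spans (number of frames covered)."""
        spans = np.asarray(spans, dtype=np.int64)
        if spans.size == 0:
            return cls(cycle_time, np.array([]), np.array([], dtype=np.int64), 0, n_frames)
        secs = np.sort((spans - 1) * cycle_time)
        uniq = np.unique(secs)
        # tracks with duration >= each unique value
        counts = secs.size - np.searchsorted(secs, uniq, side="left")
        return cls(cycle_time, uniq, counts, int(spans.size), n_frames)

    def frame_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Survival sampled at every whole frame-cycle duration.

        Returns (n, S) where n runs from the smallest observed span - 1 to
        the largest, duration = n * cycle_time, and S is the survival count.
        """
        if self.empty:
            return np.array([], dtype=np.int64), np.array([])
        n_min = int(round(self.durations[0] / self.cycle_time))
        n_max = int(round(self.durations[-1] / self.cycle_time))
        n = np.arange(n_min, n_max + 1)
        return n, self.survival_at(n * self.cycle_time)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"duration_s": self.durations, "survival_count": self.counts}
        )


def build_survival(trackset: TrackSet) -> SurvivalDistribution:
    """Assemble the survival distribution of one condition's bound tracks."""
    return SurvivalDistribution.from_durations_frames(
        trackset.durations_frames(), trackset.condition, trackset.n_frames
    )


def build_survivals(
    tracksets: list[TrackSet], scheme: ImagingScheme | None = None
) -> list[SurvivalDistribution]:
    """Assemble one survival distribution per condition.

    Conditions with zero bound tracks yield empty distributions; callers
    (the spectrum fit) exclude them with a warning.  If a scheme is given,
    every trackset's condition must appear in it.
    """
    out = []
    for ts in tracksets:
        if scheme is not None:
            scheme.condition_index(ts.condition)  # raises if unknown
        out.append(build_survival(ts))
    return out
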