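"""Time-lapse imaging schemes.

A time-lapse acquisition keeps the camera integration time fixed (so every
frame collects the same illumination dose) and varies the dark period between
frames.  Each (frame cycle time, movie duration) pair is one *condition*.
Because photobleaching accrues only while the laser is on, acquiring the same
process at several cycle times lets true dissociation be separated from
bleaching downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Condition:
    """One time-lapse condition: frame cycle time and total movie length (s)."""

    cycle_time: float
    movie_duration: float

    @property
    def n_frames(self) -> int:
        # tolerant floor: 0.3 / 0.1 is 2.999... in binary floating point
        return int(math.floor(self.movie_duration / self.cycle_time + 1e-9))


@dataclass(frozen=True)
class ImagingScheme:
    """Temporal skeleton of a time-lapse experiment.

    Parameters
    ----------
    integration_time:
        Camera integration (illumination) time per frame, seconds.
    conditions:
        Time-lapse conditions, cycle times strictly increasing.
    pixel_size:
        Length per pixel, recorded for provenance; all positions and radii
        in this package are handled in pixel units.
    """

    integration_time: float = 0.05
    conditions: tuple[Condition, ...] = field(default_factory=tuple)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.integration_time <= 0:
            raise ValueError("integration_time must be positive")
        if not self.conditions:
            raise ValueError("scheme needs at least one condition")
        taus = [c.cycle_time for c in self.conditions]
        for c in self.conditions:
            if c.cycle_time < self.integration_time:
                raise ValueError(
                    f"cycle time {c.cycle_time} s shorter than integration "
                    f"time {self.integration_time} s"
                )
            if c.n_frames < 2:
                raise ValueError(
                    f"movie duration {c.movie_duration} s covers fewer than "
                    f"2 frames at cycle time {c.cycle_time} s"
                )
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("condition cycle times must be strictly increasing")

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[float, float]],
        integration_time: float = 0.05,
        pixel_size: float = 1.0,
    ) -> "ImagingScheme":
        return cls(
            integration_time=integration_time,
            conditions=tuple(Condition(t, d) for t, d in pairs),
            pixel_size=pixel_size,
        )

    @property
    def cycle_times(self) -> tuple[float, ...]:
        return tuple(c.cycle_time for c in self.conditions)

    def condition_index(self, cycle_time: float) -> int:
        for i, c in enumerate(self.conditions):
            if math.isclose(c.cycle_time, cycle_time, rel_tol=1e-9):
                return i
        raise KeyError(f"no condition with cycle time {cycle_time} s")

    def to_dict(self) -> dict:
        return {
            "integration_time": self.integration_time,
            "pixel_size": self.pixel_size,
            "conditions": [
                {"cycle_time": c.cycle_time, "movie_duration": c.movie_duration}
                for c in self.conditions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingScheme":
        return cls(
            integration_time=d.get("integration_time", 0.05),
            pixel_size=d.get("pixel_size", 1.0),
            conditions=tuple(
                Condition(c["cycle_time"], c["movie_duration"])
                for c in d["conditions"]
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ImagingScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
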