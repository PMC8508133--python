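"""Published study settings for the RBPJ / RBPJ(R218H) / RBPJL experiments.

Time-lapse schedules (50 ms integration; cycle times between 0.1 s and 14 s
with condition-specific movie durations) and the per-condition tracking
settings used for those acquisitions.  The 14 s condition is absent from the
DNA-binding-defective mutant's scheme because long binding events were too
rare to analyze there.
"""

from __future__ import annotations

from .scheme import ImagingScheme
from .track import ConditionTracking, TrackingConfig

#: movie duration (s) per frame cycle time (s)
MOVIE_DURATIONS = {0.1: 30.0, 0.4: 120.0, 1.6: 480.0, 3.2: 960.0, 6.4: 960.0, 14.0: 1400.0}

#: per-condition tracking radius in pixels
TRACKING_RADII = {0.1: 0.9, 0.4: 1.19, 1.6: 1.75, 3.2: 2.4, 6.4: 2.8, 14.0: 3.1}

#: minimum track length: 3 frames for the two fastest conditions, else 2
MIN_TRACK_LENGTHS = {0.1: 3, 0.4: 3, 1.6: 2, 3.2: 2, 6.4: 2, 14.0: 2}

#: allowed gap frames: 2 at 0.1 s, 1 otherwise
GAP_FRAMES = {0.1: 2, 0.4: 1, 1.6: 1, 3.2: 1, 6.4: 1, 14.0: 1}

MIN_SEGMENTATION_LENGTH = 2

INTEGRATION_TIME = 0.05

CYCLE_TIMES = {
    "RBPJ": (0.1, 0.4, 1.6, 6.4, 14.0),
    "RBPJ(R218H)": (0.1, 0.4, 1.6, 6.4),
    "RBPJL": (0.1, 0.4, 3.2, 14.0),
}


def imaging_scheme(construct: str = "RBPJ") -> ImagingScheme:
    """Time-lapse scheme for one construct ('RBPJ', 'RBPJ(R218H)', 'RBPJL')."""
    try:
        taus = CYCLE_TIMES[construct]
    except KeyError:
        raise KeyError(
            f"unknown construct {construct!r}; one of {sorted(CYCLE_TIMES)}"
        ) from None
    return ImagingScheme.from_pairs(
        [(tau, MOVIE_DURATIONS[tau]) for tau in taus],
        integration_time=INTEGRATION_TIME,
    )


def tracking_config(construct: str = "RBPJ") -> TrackingConfig:
    """Per-condition tracking settings for one construct's cycle times."""
    taus = CYCLE_TIMES[construct]
    return TrackingConfig(
        {
            tau: ConditionTracking(
                tracking_radius=TRACKING_RADII[tau],
                min_track_length=MIN_TRACK_LENGTHS[tau],
                gap_frames=GAP_FRAMES[tau],
                min_segmentation_length=MIN_SEGMENTATION_LENGTH,
            )
            for tau in taus
        }
    )
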