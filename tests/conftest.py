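"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from smres import Condition, ImagingScheme, SurvivalDistribution


@pytest.fixture
def small_scheme() -> ImagingScheme:
    """Two-condition time-lapse scheme at desk scale."""
    return ImagingScheme(
        integration_time=0.05,
        conditions=(Condition(0.1, 30.0), Condition(1.0, 120.0)),
    )


def exact_survival(
    rates,
    weights,
    bleach_number: float,
    cycle_time: float,
    n_frames: int,
    n_min: int = 1,
    n_tracks: float = 1e6,
    window: bool = False,
) -> SurvivalDistribution:
    """Noiseless survival distribution from the closed-form decay model.

    S(n * tau) proportional to sum_i w_i exp(-k_i n tau) exp(-a n), for n from
    n_min to n_frames - 1, scaled so the first point equals ``n_tracks``.
    ``window=True`` additionally applies the finite-movie factor (N - n)/N.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = np.arange(n_min, n_frames)
    s = (weights[None, :] * np.exp(-np.outer(n * cycle_time, rates)
                                   - bleach_number * n[:, None])).sum(axis=1)
    if window:
        s = s * (n_frames - n) / n_frames
    counts = s / s[0] * n_tracks
    keep = counts > n_tracks * 1e-12
    return SurvivalDistribution(
        cycle_time, (n * cycle_time)[keep], counts[keep], n_tracks, n_frames
    )


def cluster_mean_rate(spectrum, lo: float, hi: float) -> float:
    """State-weighted mean dissociation rate between borders (test oracle)."""
    k = spectrum.grid.rates
    s = spectrum.state_weights
    m = (k >= lo) & (k <= hi)
    return float((s[m] * k[m]).sum() / s[m].sum())
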