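"""Synthetic single-molecule time-lapse data.

Generates ground-truth binding kinetics, per-condition track tables and
(optionally) rendered movies that emulate a live-cell chromatin-binding
experiment: sparse bound molecules with multi-exponential dwell times,
freely diffusing unbound molecules, and per-illumination photobleaching.

The observation process per bound molecule is the one a variable-dark-period
design is built to disentangle: dwell times are exponential in wall-clock
time, while bleaching is a per-illuminated-frame coin flip with survival
probability exp(-k_b * t_int) — independent of the dark period length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scheme import ImagingScheme

__all__ = [
    "BoundState",
    "GroundTruth",
    "TruthTrack",
    "simulate_tracks",
    "simulate_track_tables",
    "render_movie",
    "tracks_to_table",
]


@dataclass(frozen=True)
class BoundState:
    """One binding state: dissociation rate (1/s) and the probability that a
    binding event belongs to this state (the event weight of the spectrum)."""

    k_off: float
    weight: float


@dataclass(frozen=True)
class GroundTruth:
    """True kinetic and photophysical parameters of a simulation.

    Parameters
    ----------
    bound_states:
        Binding states; weights must sum to 1, rates must be distinct and
        non-negative.  A rate of 0 means permanent binding.
    bleach_rate:
        Photobleaching rate per second of *illuminated* time (k_b).  The
        per-frame bleach number is ``a = k_b * integration_time``.
    diffusion_coefficient:
        2-D Brownian coefficient of unbound molecules, pixel^2/s.
    bound_fraction:
        Fraction of simulated molecules that are chromatin-bound.
    labeling_density:
        Expected visible spots per nucleus per frame (rendering guidance).
    localization_sd:
        Per-frame localization jitter of bound molecules, pixels.
    """

    bound_states: tuple[BoundState, ...]
    bleach_rate: float = 0.0
    diffusion_coefficient: float = 50.0
    bound_fraction: float = 1.0
    labeling_density: float = 6.0
    localization_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.bound_states:
            raise ValueError("at least one bound state is required")
        ks = [s.k_off for s in self.bound_states]
        ws = [s.weight for s in self.bound_states]
        if any(k < 0 for k in ks):
            raise ValueError("dissociation rates must be non-negative")
        if len(set(ks)) != len(ks):
            raise ValueError("dissociation rates must be distinct")
        if any(w < 0 for w in ws) or not math.isclose(sum(ws), 1.0, abs_tol=1e-9):
            raise ValueError("state weights must be non-negative and sum to 1")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")

    @property
    def rates(self) -> np.ndarray:
        return np.array([s.k_off for s in self.bound_states])

    @property
    def event_weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.bound_states])

    @property
    def state_weights(self) -> np.ndarray:
        """Occupancy probabilities: event weights divided by rate, normalized.

        Undefined (raises) if a state with positive weight never dissociates.
        """
        k, w = self.rates, self.event_weights
        if np.any((k == 0) & (w > 0)):
            raise ValueError("state spectrum undefined for a permanent state")
        occ = np.divide(w, k, out=np.zeros_like(w), where=k > 0)
        return occ / occ.sum()

    def slowest_binding_time(self) -> float:
        """1 / (smallest positive dissociation rate with positive weight)."""
        k, w = self.rates, self.event_weights
        pos = k[(k > 0) & (w > 0)]
        if pos.size == 0:
            return math.inf
        return 1.0 / pos.min()

    def to_dict(self) -> dict:
        return {
            "bound_states": [[s.k_off, s.weight] for s in self.bound_states],
            "bleach_rate": self.bleach_rate,
            "diffusion_coefficient": self.diffusion_coefficient,
            "bound_fraction": self.bound_fraction,
            "labeling_density": self.labeling_density,
            "localization_sd": self.localization_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            bound_states=tuple(BoundState(k, w) for k, w in d["bound_states"]),
            bleach_rate=d.get("bleach_rate", 0.0),
            diffusion_coefficient=d.get("diffusion_coefficient", 50.0),
            bound_fraction=d.get("bound_fraction", 1.0),
            labeling_density=d.get("labeling_density", 6.0),
            localization_sd=d.get("localization_sd", 0.15),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TruthTrack:
    """One simulated molecule's observed trajectory."""

    molecule_id: int
    state_index: int  # -1 for unbound molecules
    appearance_time: float
    true_dwell: float
    frames: np.ndarray  # strictly increasing frame indices
    x: np.ndarray
    y: np.ndarray
    end_cause: str  # dissociated | bleached | movie_end

    @property
    def span_frames(self) -> int:
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def bound(self) -> bool:
        return self.state_index >= 0


def _bleach_spans(rng: np.random.Generator, n: int, k_b: float, t_int: float) -> np.ndarray:
    """Number of frames each molecule is visible before bleaching.

    A molecule is always visible in its first frame; after each illuminated
    frame it survives with probability exp(-k_b * t_int).
    """
    if k_b == 0.0:
        return np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    p_bleach = -np.expm1(-k_b * t_int)  # 1 - exp(-k_b t_int)
    return rng.geometric(p_bleach, size=n).astype(np.int64)


def simulate_tracks(
    truth: GroundTruth,
    scheme: ImagingScheme,
    condition_index: int,
    n_molecules: int,
    field_size: tuple[int, int] = (128, 128),
    seed: int | np.random.Generator = 0,
) -> tuple[list[TruthTrack], dict]:
    """Simulate one condition's molecules and return their truth tracks.

    Bound molecules draw a state (by event weight) and an exponential dwell,
    appear at a uniformly random frame, and are observed each frame while
    bound; independently each illuminated frame bleaches them with
    probability 1 - exp(-k_b * t_int).  Observation ends at dissociation,
    bleaching or movie end, whichever is first.  Unbound molecules perform
    2-D Brownian motion (reflected at the field border) for the whole movie,
    subject to the same bleaching.

    Returns the tracks plus a metadata dict (counts by end cause etc.).
    Deterministic given the seed.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not 0 <= condition_index < len(scheme.conditions):
        raise ValueError(f"condition_index {condition_index} out of range")
    h, w = field_size
    if h <= 0 or w <= 0:
        raise ValueError("field_size must have positive area")

    rng = np.random.default_rng(seed)
    cond = scheme.conditions[condition_index]
    tau, n_frames = cond.cycle_time, cond.n_frames
    t_int = scheme.integration_time

    n_bound = int(round(n_molecules * truth.bound_fraction))
    n_free = n_molecules - n_bound
    tracks: list[TruthTrack] = []

    # --- bound molecules ---------------------------------------------------
    if n_bound:
        k = truth.rates
        states = rng.choice(len(k), size=n_bound, p=truth.event_weights)
        dwell = np.where(
            k[states] > 0,
            rng.exponential(1.0, size=n_bound) / np.where(k[states] > 0, k[states], 1.0),
            np.inf,
        )
        f0 = rng.integers(0, n_frames, size=n_bound)
        span_dwell = np.full(n_bound, np.iinfo(np.int64).max, dtype=np.int64)
        finite = np.isfinite(dwell)
        span_dwell[finite] = np.floor(dwell[finite] / tau).astype(np.int64) + 1
        span_bleach = _bleach_spans(rng, n_bound, truth.bleach_rate, t_int)
        span_movie = n_frames - f0
        span = np.minimum(np.minimum(span_dwell, span_bleach), span_movie)

        sites = np.column_stack(
            [rng.uniform(1.0, w - 1.0, n_bound), rng.uniform(1.0, h - 1.0, n_bound)]
        )
        for i in range(n_bound):
            m = int(span[i])
            frames = np.arange(f0[i], f0[i] + m)
            jit = rng.normal(0.0, truth.localization_sd, size=(m, 2))
            xs = np.clip(sites[i, 0] + jit[:, 0], 0.0, w - 1.0)
            ys = np.clip(sites[i, 1] + jit[:, 1], 0.0, h - 1.0)
            if span_movie[i] < min(span_dwell[i], span_bleach[i]):
                cause = "movie_end"
            elif span_dwell[i] <= span_bleach[i]:
                cause = "dissociated"
            else:
                cause = "bleached"
            # a molecule truncated exactly at the last frame while still alive
            if cause != "movie_end" and span[i] == span_movie[i] and span_dwell[i] > span[i] and span_bleach[i] > span[i]:
                cause = "movie_end"
            tracks.append(
                TruthTrack(
                    molecule_id=i,
                    state_index=int(states[i]),
                    appearance_time=float(f0[i] * tau),
                    true_dwell=float(dwell[i]),
                    frames=frames,
                    x=xs,
                    y=ys,
                    end_cause=cause,
                )
            )

    # --- unbound molecules -------------------------------------------------
    if n_free:
        step_sd = math.sqrt(2.0 * truth.diffusion_coefficient * tau)
        span_bleach = _bleach_spans(rng, n_free, truth.bleach_rate, t_int)
        for j in range(n_free):
            m = int(min(n_frames, span_bleach[j]))
            steps = rng.normal(0.0, step_sd, size=(m, 2))
            steps[0] = [rng.uniform(0, w - 1), rng.uniform(0, h - 1)]
            pos = np.cumsum(steps, axis=0)
            # reflect into the field
            xs = np.abs(np.mod(pos[:, 0], 2 * (w - 1)) - (w - 1)) * -1 + (w - 1)
            ys = np.abs(np.mod(pos[:, 1], 2 * (h - 1)) - (h - 1)) * -1 + (h - 1)
            cause = "movie_end" if m == n_frames else "bleached"
            tracks.append(
                TruthTrack(
                    molecule_id=n_bound + j,
                    state_index=-1,
                    appearance_time=0.0,
                    true_dwell=math.inf,
                    frames=np.arange(m),
                    x=xs,
                    y=ys,
                    end_cause=cause,
                )
            )

    causes = [t.end_cause for t in tracks]
    meta = {
        "cycle_time": tau,
        "n_frames": n_frames,
        "n_molecules": n_molecules,
        "n_bound": n_bound,
        "n_unbound": n_free,
        "n_dissociated": causes.count("dissociated"),
        "n_bleached": causes.count("bleached"),
        "n_movie_end": causes.count("movie_end"),
    }
    return tracks, meta


def simulate_track_tables(
    truth: GroundTruth,
    scheme: ImagingScheme,
    n_molecules: int | list[int],
    field_size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> dict[float, pd.DataFrame]:
    """Simulate every condition of a scheme; one track table per cycle time.

    ``n_molecules`` may be a single count applied to all conditions or one
    count per condition.  Child seeds are spawned deterministically.
    """
    if isinstance(n_molecules, int):
        n_molecules = [n_molecules] * len(scheme.conditions)
    if len(n_molecules) != len(scheme.conditions):
        raise ValueError("need one molecule count per condition")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scheme.conditions))
    out = {}
    for ci, (cond, n, child) in enumerate(
        zip(scheme.conditions, n_molecules, children)
    ):
        tracks, _ = simulate_tracks(
            truth, scheme, ci, n, field_size, np.random.default_rng(child)
        )
        out[cond.cycle_time] = tracks_to_table(tracks, cond.cycle_time)
    return out


def tracks_to_table(tracks: list[TruthTrack], condition: float) -> pd.DataFrame:
    """Flatten truth tracks to the track-table CSV layout."""
    if not tracks:
        return pd.DataFrame(
            columns=["molecule_id", "frame", "x", "y", "condition"]
        )
    parts = [
        pd.DataFrame(
            {
                "molecule_id": t.molecule_id,
                "frame": t.frames,
                "x": t.x,
                "y": t.y,
                "condition": condition,
            }
        )
        for t in tracks
    ]
    return pd.concat(parts, ignore_index=True)


def render_movie(
    tracks: list[TruthTrack],
    scheme: ImagingScheme,
    condition_index: int,
    field_size: tuple[int, int] = (128, 128),
    psf_sigma: float = 1.2,
    amplitude: float = 50.0,
    background_level: float = 10.0,
    noise_model: str = "poisson",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render tracks as a frame stack (float32, TIFF-writable).

    Each visible molecule becomes a 2-D Gaussian of width ``psf_sigma`` and
    peak ``amplitude`` on a flat background; per-pixel Poisson shot noise is
    applied unless ``noise_model='none'``.  Frame count is the floor of
    movie_duration / cycle_time.  Deterministic given the seed.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if background_level <= 0:
        raise ValueError("background_level must be positive")
    if noise_model not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    h, w = field_size
    n_frames = scheme.conditions[condition_index].n_frames
    movie = np.full((n_frames, h, w), float(background_level), dtype=np.float64)

    half = max(1, int(math.ceil(4 * psf_sigma)))
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            if f >= n_frames:
                continue
            x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
            y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
            x0c, x1c = max(x0, 0), min(x1, w)
            y0c, y1c = max(y0, 0), min(y1, h)
            if x0c >= x1c or y0c >= y1c:
                continue
            xs = np.arange(x0c, x1c)
            ys = np.arange(y0c, y1c)
            gx = np.exp(-0.5 * ((xs - x) / psf_sigma) ** 2)
            gy = np.exp(-0.5 * ((ys - y) / psf_sigma) ** 2)
            movie[int(f), y0c:y1c, x0c:x1c] += amplitude * np.outer(gy, gx)

    if noise_model == "poisson":
        rng = np.random.default_rng(seed)
        movie = rng.poisson(movie).astype(np.float64)
    return movie.astype(np.float32)
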