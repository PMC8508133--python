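"""Global inverse-Laplace dissociation-rate spectra (the GRID step).

The observed survival of bound-molecule tracks in a time-lapse condition
with frame cycle time tau is a superposition of exponentials: a molecule in
a state with dissociation rate k_i survives n frame cycles with probability
exp(-k_i * n * tau) * exp(-a * n), where the *bleach number* a = k_b * t_int
is the per-frame photobleaching contribution — identical in every condition
because the integration time is fixed, while its per-second cost a/tau falls
as dark periods lengthen.  Fitting all conditions jointly with shared rate
weights and a shared bleach number therefore separates true dissociation
from photobleaching.

The inversion places non-negative weights on a fixed log-spaced grid of
candidate rates (non-negative least squares; sparsity emerges from the
non-negativity constraint, no smoothness penalty).  The bleach number is
found by an outer bounded 1-D minimization.  Each condition receives a free
positive amplitude: tracks shorter than the minimum track length are never
observed, so each condition's empirical survival is a *conditional*
distribution whose mixture composition differs from the global one by a
single common factor — exactly a per-condition scale.

The fitted *event spectrum* w_i (how frequently dissociation from state i
occurs) is converted to a *state spectrum* s_i = (w_i / k_i) / sum_j
(w_j / k_j) — the probability of finding a molecule in state i at a random
time snapshot, which is what gets reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .survival import SurvivalDistribution

__all__ = [
    "RateGrid",
    "RateSpectrum",
    "model_survival",
    "fit_event_spectrum",
    "event_to_state",
]

#: fraction of the movie beyond which window-corrected survival points are
#: dropped (the correction factor diverges as durations approach the movie
#: length and the few surviving counts become dominated by noise)
WINDOW_CORRECTION_CUTOFF = 0.8


@dataclass(frozen=True)
class RateGrid:
    """Fixed log-spaced grid of candidate dissociation rates (1/s)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=np.float64)
        if r.ndim != 1 or len(r) < 2:
            raise ValueError("grid needs at least two rates")
        if r[0] <= 0 or np.any(np.diff(r) <= 0):
            raise ValueError("rates must be positive and strictly increasing")
        object.__setattr__(self, "rates", r)

    @classmethod
    def log_spaced(
        cls, k_min: float = 1e-4, k_max: float = 1e2, n_points: int = 200
    ) -> "RateGrid":
        """Default grid: 200 points spanning 1e-4 .. 1e2 /s, bracketing both
        many-minute chromatin residences and frame-rate-limited fast rates."""
        if k_min <= 0 or k_max <= k_min:
            raise ValueError("need 0 < k_min < k_max")
        return cls(np.logspace(np.log10(k_min), np.log10(k_max), n_points))

    def __len__(self) -> int:
        return len(self.rates)

    @property
    def step_factor(self) -> float:
        return float(self.rates[1] / self.rates[0])


@dataclass
class RateSpectrum:
    """Result of a global spectrum fit."""

    grid: RateGrid
    event_weights: np.ndarray  # w_i >= 0, sum 1
    bleach_number: float  # a = k_b * t_int, per frame
    fit_residual: float  # summed weighted squared residual of the fit
    amplitudes: dict[float, float] = field(default_factory=dict)  # per tau

    @property
    def state_weights(self) -> np.ndarray:
        return event_to_state(self.event_weights, self.grid.rates)

    def model_survival(self, cycle_time: float, t: np.ndarray) -> np.ndarray:
        return model_survival(
            self.event_weights, self.grid.rates, self.bleach_number, cycle_time, t
        )

    def to_dict(self) -> dict:
        return {
            "rates": self.grid.rates.tolist(),
            "event_weights": self.event_weights.tolist(),
            "state_weights": self.state_weights.tolist(),
            "bleach_number": self.bleach_number,
            "residual": self.fit_residual,
            "amplitudes": {str(k): v for k, v in self.amplitudes.items()},
        }


def model_survival(
    event_weights: np.ndarray,
    rates: np.ndarray,
    bleach_number: float,
    cycle_time: float,
    t: np.ndarray | float,
) -> np.ndarray:
    """Forward model: S_tau(t) = sum_i w_i exp(-(k_i + a/tau) t).

    Each state decays with effective rate k_i + a/tau; the bleaching term
    shrinks as the dark period lengthens — the time-lapse principle.
    """
    if cycle_time <= 0:
        raise ValueError("cycle_time must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    k_eff = np.asarray(rates) + bleach_number / cycle_time
    return np.exp(-np.outer(t, k_eff)) @ np.asarray(event_weights)


def event_to_state(event_weights: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Convert event weights to occupancy (state) probabilities.

    s_i = (w_i / k_i) / sum_j (w_j / k_j): dividing each event weight by its
    rate weights states by mean dwell time, turning event frequency into the
    probability of occupying the state at a random snapshot.
    """
    w = np.asarray(event_weights, dtype=np.float64)
    k = np.asarray(rates, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("event weights must be non-negative")
    if np.any((k == 0) & (w > 0)):
        raise ValueError("state spectrum undefined: zero rate with positive weight")
    occ = np.divide(w, k, out=np.zeros_like(w), where=k > 0)
    tot = occ.sum()
    if tot == 0:
        raise ValueError("all event weights are zero")
    return occ / tot


def _prepare_condition(
    dist: SurvivalDistribution,
    window_correction: bool,
    max_points: int,
    weighting: str,
    weight_floor_counts: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float] | None:
    """Extract (n, y, wt, tau) for fitting: frame-cycle indices, normalized
    (optionally window-corrected) survival fractions, and residual weights."""
    if dist.empty:
        return None
    n, s = dist.frame_grid()
    y = s / dist.n_tracks
    if window_correction:
        keep = n <= WINDOW_CORRECTION_CUTOFF * dist.n_frames
        if keep.sum() < 2:
            keep = np.ones_like(n, dtype=bool)
        n, y = n[keep], y[keep]
        y = y * dist.n_frames / (dist.n_frames - n)
    y = y / y[0]
    if len(n) > max_points:
        idx = np.unique(np.round(np.linspace(0, len(n) - 1, max_points)).astype(int))
        n, y = n[idx], y[idx]
    if weighting == "poisson":
        # counting noise on S(t) is ~ Poisson: var(y) ~ y / n_tracks, floored
        # so a handful of noisy tail counts cannot dominate the objective
        wt = 1.0 / np.sqrt(np.maximum(y, weight_floor_counts / dist.n_tracks))
    elif weighting == "equal":
        wt = np.ones(len(n))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    # each condition contributes equal total weight so long movies do not
    # dominate the global objective
    wt = wt / np.sqrt((wt**2).sum())
    return n, y, wt, dist.cycle_time


def fit_event_spectrum(
    survivals: list[SurvivalDistribution],
    grid: RateGrid | None = None,
    bleach_bounds: tuple[float, float] = (0.0, 2.0),
    a_tol: float = 1e-5,
    window_correction: bool = True,
    fixed_bleach: float | None = None,
    max_points_per_condition: int = 120,
    max_als_iter: int = 25,
    weighting: str = "poisson",
    weight_floor_counts: float = 20.0,
) -> RateSpectrum:
    """Globally fit a dissociation-rate spectrum to multi-condition survivals.

    Minimizes the summed squared difference between normalized empirical and
    modeled survival functions over all conditions jointly.  Residuals are
    weighted by approximate inverse counting noise (``weighting='poisson'``:
    1/sqrt(y) floored at ``weight_floor_counts`` surviving tracks, so the
    informative low-count tail matters without letting single-count noise
    dominate; ``weighting='equal'``: flat), and each condition's weight
    vector is normalized to unit total so long movies do not dominate.

    Both the empirical and the modeled survival of each condition are
    normalized at the first observed duration (the model's amplitude is
    anchored there); this makes the per-condition amplitude explicit while
    keeping the weight solve a plain NNLS.  For each candidate bleach number
    the anchored system is iterated to a fixed point (the anchor depends on
    the weights); the bleach number itself is found by a bounded 1-D search.

    ``window_correction`` divides the empirical survival by the known
    finite-movie window factor (N - n)/N that naive track-length collection
    imposes when molecules appear uniformly during the movie.

    A single-condition input cannot separate the bleach number from slow
    rates and is refused unless ``fixed_bleach`` is given.
    """
    if grid is None:
        grid = RateGrid.log_spaced()
    prepped = []
    for dist in survivals:
        p = _prepare_condition(
            dist, window_correction, max_points_per_condition,
            weighting, weight_floor_counts,
        )
        if p is None:
            warnings.warn(
                f"condition {dist.cycle_time} s has no tracks; excluded from fit",
                stacklevel=2,
            )
            continue
        prepped.append(p)
    taus = {round(tau, 12) for *_, tau in prepped}
    if len(taus) < 2 and fixed_bleach is None:
        raise ValueError(
            "need >= 2 conditions with distinct cycle times to separate "
            "bleaching from slow dissociation; pass fixed_bleach to override"
        )

    k = grid.rates
    # per condition: frame index n, data y, exp(-k_i * n * tau) design block
    blocks = []
    for n, y, wt, tau in prepped:
        E = np.exp(-np.outer(n * tau, k))
        blocks.append((n.astype(np.float64), y, tau, E, wt))

    n_rows = sum(len(b[0]) for b in blocks)
    target = np.concatenate([y * wt for _, y, _, _, wt in blocks])
    w_warm = np.full(len(k), 1.0 / len(k))

    def solve_at(a: float, w0: np.ndarray) -> tuple[float, np.ndarray]:
        """Fixed-point iteration: anchor amplitudes at the current weights'
        first-point model value, then re-solve the NNLS for the weights."""
        mats = [E * np.exp(-a * n)[:, None] for n, _, _, E, _ in blocks]
        w = w0
        stacked = np.empty((n_rows, len(k)))
        prev = None
        obj = np.inf
        for _ in range(max_als_iter):
            row = 0
            for A, (n, y, tau, E, wt) in zip(mats, blocks):
                anchor = float(A[0] @ w)
                c = 1.0 / anchor if anchor > 1e-300 else 0.0
                stacked[row : row + len(n)] = (c * wt[:, None]) * A
                row += len(n)
            w_new, rnorm = nnls(stacked, target)
            if w_new.sum() > 0:
                w = w_new
            obj = rnorm**2
            if prev is not None and abs(prev - obj) <= 1e-11 * max(prev, 1e-30):
                break
            prev = obj
        return obj, w

    if fixed_bleach is not None:
        a_best = float(fixed_bleach)
    else:
        def objective(a: float) -> float:
            obj, w = solve_at(a, w_warm.copy())
            if w.sum() > 0:
                w_warm[:] = w / w.sum()
            return obj

        res = minimize_scalar(
            objective, bounds=bleach_bounds, method="bounded",
            options={"xatol": a_tol},
        )
        a_best = float(res.x)

    obj, w = solve_at(a_best, w_warm.copy())
    total = w.sum()
    if total <= 0:
        raise RuntimeError("fit collapsed: all weights zero")
    w_norm = w / total
    amplitudes = {}
    for n, y, tau, E, wt in blocks:
        anchor = float((E[0] * np.exp(-a_best * n[0])) @ w_norm)
        amplitudes[tau] = 1.0 / anchor if anchor > 1e-300 else 0.0
    return RateSpectrum(
        grid=grid,
        event_weights=w_norm,
        bleach_number=a_best,
        fit_residual=float(obj),
        amplitudes=amplitudes,
    )
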