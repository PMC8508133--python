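# Methods

## The measurement problem

A chromatin-binding protein observed by live-cell single-molecule imaging
stays bound for an exponentially distributed dwell time, but the
fluorophore also photobleaches, and a camera can only watch for as long as
the movie lasts.  The observed track duration is therefore the minimum of
three clocks — dissociation, photobleaching, and movie end — and a naive
exponential fit of track durations reports photobleaching, not binding.

Time-lapse illumination breaks the degeneracy.  The camera integration time
t_int is fixed (50 ms by default), so every acquired frame deposits the same
light dose, while the frame cycle time τ (integration plus dark period)
varies between movies.  A molecule in binding state i with dissociation rate
k_i that is observed for n frame cycles survives with probability

    S_τ(nτ) = exp(−k_i · nτ) · exp(−a · n),

where a = k_b · t_int is the *bleach number* — the per-frame bleaching
contribution, identical in every condition because the light dose per frame
is fixed.  Expressed per unit time the effective decay rate is k_i + a/τ:
the bleaching term shrinks as dark periods lengthen.  Fitting several cycle
times jointly with shared k_i and a therefore separates dissociation from
bleaching.

## Synthetic data generator

Because no raw movies are available, every stage is validated on synthetic
data.  Per bound molecule the generator draws a binding state (by event
weight), an exponential dwell time, and a uniformly random appearance frame;
the molecule is observed each frame while bound and independently survives
each illuminated frame with probability exp(−k_b · t_int).  Observation ends
at dissociation, bleaching, or movie end, whichever comes first, and the end
cause is recorded so censoring conventions can be compared.  Bound positions
jitter with a configurable localization s.d. (default 0.15 px) around a
fixed site; unbound molecules perform 2-D Brownian motion (default
50 px²/s, reflected at the field border) and are subject to the same
bleaching.  Movies, when rendered, place a Gaussian PSF (default σ = 1.2 px)
per visible molecule on a flat background with per-pixel Poisson shot noise.

Simplifications relative to real data: one bleaching step (no blinking or
dye re-activation), no state switching within a binding event (states are
independent decay channels, as the spectrum model assumes), no nuclear
boundary or cell-cycle structure, no drift, a flat background, and
localization noise that is Gaussian and amplitude-independent.  Passing
recovery tests therefore demonstrates that the *analysis chain* is unbiased
under its own model assumptions at realistic statistics — not that those
assumptions hold in any particular microscope.

Bleaching is applied only during illuminated intervals, never during dark
periods; that asymmetry is precisely the mechanism the variable-dark-period
design exploits, so the generator must realize it exactly.

## Movie-end censoring and the window correction

Track durations are collected naively (censored tracks included, flagged).
With appearance frames uniform over an N-frame movie, a track spanning
m frames is observable only if it starts early enough, which multiplies the
true span distribution by the exact window factor (N − m + 1)/N.  The
spectrum fit divides this factor out of the empirical survival before
fitting (`window_correction=True`).  Without it the slowest rate is biased
upward by roughly 1/T_movie — at a 1400 s movie that is ~7×10⁻⁴/s, which
would corrupt a ~10⁻³/s rate by almost a factor of two.  Corrected points
beyond 0.8 N are dropped: there the factor exceeds 5 and one or two
surviving counts dominate the corrected value.  The correction is exact
under the generator's uniform-appearance process; on real data it holds
whenever molecules bind at a stationary rate during the movie.

## Detection and tracking

Spot detection matched-filters each frame with a Gaussian (σ = 1 px by
default) — single-pixel shot-noise extremes over a full field defeat any
raw-pixel threshold — then accepts local maxima whose SNR exceeds 4.5,
with SNR defined as the filtered peak minus the local annulus median,
divided by a robust frame-wide noise scale (1.4826 × MAD of the filtered
frame).  Positions are refined by an intensity-weighted centroid of the raw
frame (sufficient for linking radii ≥ 0.9 px and much faster than Gaussian
fitting).  The exact SNR estimator of the original tracking software is not
public; this definition is validated by recall/precision on rendered movies
and by end-to-end parameter recovery, not by spot-level identity.

Linking is a deterministic radius-gated greedy closest-pair assignment:
consecutive-frame segments first, segments shorter than the minimum
segmentation length (2) discarded, then gap closing (closest pair first,
same radius) across up to the allowed number of gap frames.  Gap-closed
frames count toward a track's duration but contribute no positions.  The
per-condition tracking radii (0.9–3.1 px), minimum track lengths (3 frames
at the two fastest conditions, else 2) and gap frames (2 at 0.1 s, else 1)
default to the published settings.  Bound molecules are tracks confined
within the tracking radius of their first detection for at least the
minimum track length; freely diffusing molecules exceed the radius within a
frame or two.

## Survival distributions

A track detected over m frames spans m − 1 frame cycles, so its duration is
(m − 1)·τ — a two-detection track evidences one cycle of persistence.  The
per-condition survival function (number of tracks with duration ≥ t) is
kept as an exact step function; the fit consumes it sampled at every whole
frame cycle.

## Global spectrum inversion

Candidate rates live on a fixed log-spaced grid of 200 points spanning
10⁻⁴–10² /s, bracketing many-minute chromatin residences and
frame-rate-limited fast rates.  The fit minimizes the summed squared
difference between normalized empirical and modeled survival functions over
all conditions jointly, with:

- **Non-negative weights, no smoothness penalty.**  Sparsity emerges from
  the non-negativity constraint; uncertainty comes from resampling rather
  than regularization tuning.
- **Anchored per-condition amplitudes.**  Tracks shorter than the minimum
  track length are never observed, so each condition's empirical survival is
  a conditional distribution; conditioning rescales the mixture by a single
  common factor per condition.  The model's amplitude is anchored so the
  conditional curve passes through the first observed point — the same
  point at which the data are normalized — and the weight solve stays a
  plain NNLS, iterated to a fixed point (the anchor depends weakly on the
  weights; convergence takes a few dozen iterations).  A least-squares
  amplitude update was tried and rejected: the resulting alternating scheme
  has severe local minima.
- **Poisson-style residual weights.**  Counting noise on a survival count S
  is ≈ √S, so residuals are weighted by 1/√y with y floored at 20 surviving
  tracks; the informative low-count tail then constrains slow rates without
  letting single-count fluctuations dominate.  Each condition's weight
  vector is normalized to unit total so long movies do not dominate.
- **Bounded 1-D search for the bleach number** a ∈ [0, 2] per frame
  (`scipy.optimize.minimize_scalar`, xatol 10⁻⁵ — accurate to far below one
  grid step).  A single condition cannot separate a from slow rates and is
  refused unless a is fixed explicitly.

The fitted *event* weights (how often dissociation from each state occurs)
are converted to the reported *state* spectrum by dwell weighting,
s_i ∝ w_i/k_i.

## Resampling and the slowest cluster

The fit is repeated 499 times on 80% of the tracks (drawn without
replacement per condition); the resampled state spectra are averaged into a
merged spectrum.  The published procedure sets cluster borders by eye "to
cover the resampled data"; the automatic default reproduces that judgment:
the dominant *interior* mode of the merged spectrum is located (the first
and last grid points collect mass from rates slower or faster than any
movie can resolve — artifacts a human ignores) and the cluster is grown
outward while weights exceed max(10⁻³, 2% of the mode).  The reported
binding time is the inverse of the mass-weighted mean rate within the
borders; the reported s.d. is the mass-weighted rate spread of the merged
cluster, propagated to time.  This width convention reproduces the relative
error magnitudes the experiment reported (13–28%); the much smaller
center-jitter of per-resample cluster means is exported alongside
(`resample_mean_rate`, `resample_sd_rate`).

## Recovery studies and what they show

The three study designs (`smres.studies`) use each construct's published
cycle times and movie durations, a two-state truth (slow state at the
published binding time with 30% of binding events; fast state at 0.5 /s
with 70%), bleach number 0.05 per frame (k_b = 1 /s of illuminated time — a
photostable far-red dye under deliberately limited laser power), and
molecule counts sized so per-condition bound-track counts land near the
upper end of the published per-condition ranges (≈2500 / ≈1800 / ≈1000 for
the three designs) for statistical power.

In the noiseless limit the pipeline recovers all three truths and the
bleach number exactly (the round-trip and two-state recovery tests check
this).  At finite study-scale statistics the estimator inherits a
small-sample tendency of sparse non-negative least squares to place the
slow atoms slightly fast of truth, visible in the recovery runs that
`scripts/acceptance.py` performs (of order −15% on the 910 s design at the
default seed, within that design's resampling s.d.); the effect shrinks as
track counts grow.  The 910 s design is intrinsically the hardest: at its
slowest usable condition (14 s cycle) the dissociation contribution to the
per-frame decay (k·τ ≈ 0.015) is a third of the bleach number, so most of
the observed decay is bleaching, and a rough Cramér–Rao argument at these
track counts puts the attainable relative s.d. in the 15% range — the
resampling s.d. the runs report is of that order.  The cluster-width s.d.
convention can understate the full run-to-run spread of the estimate
(subsampling 80% of the data without replacement explores only part of the
sampling variability); the per-resample center-jitter exported alongside
can be scaled by √(f/(1−f)) = 2 for a delete-d-jackknife-style estimate of
that spread.

## Numerical choices and degenerate inputs

- Rates at which exp(−k·t_min) underflows in every condition are
  unobservable; their NNLS columns are numerically ~0 and the grid edges
  absorb unresolvable mass — which is why cluster borders exclude boundary
  grid points (with a warning fallback when *all* mass is boundary-bound,
  e.g. a truth that never dissociates: the recovered time is then
  resolution-limited, bounded below by the longest movie).
- Survival points per condition are thinned to ≤120 (even stride) before
  fitting; beyond that the objective gains no information and the NNLS cost
  grows linearly.
- Empty conditions are excluded from the fit with a warning; a resample
  that empties a condition is skipped and counted.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations and seeds produce
  byte-identical track tables, spectra and reports.
- Ties in linking (coincident spots) resolve by input order; candidate
  pairs sort by (distance, earlier frame, lower index).

## Known limitations

- The duration convention (m − 1)·τ and the inclusion of movie-end-censored
  tracks are configurable but the defaults are one specific reading of the
  published pipeline; both choices are recorded and testable.
- The window correction assumes stationary binding during the movie.
- The SNR definition and the greedy linker are this package's own
  constructions, equivalent in spirit but not in implementation to the
  original tracking software; validation is at the pipeline level.
- The state spectrum is undefined for a permanently bound state (zero
  rate); the generator allows such truths but the spectrum stage reports
  them only as resolution-limited slow mass.
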