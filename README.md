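# smres — single-molecule residence-time spectra

`smres` measures how long chromatin-binding proteins stay bound in living
cells from time-lapse single-molecule tracking data.  It implements the
full analysis chain around the transcription factor RBPJ and its pancreatic
paralog RBPJL: synthetic movie/track simulation, spot detection, trajectory
linking, fluorescence survival-time distributions, global inverse-Laplace
dissociation-rate spectra with photobleaching correction, and resampled
slowest-cluster binding-time estimates.

## Who it is for

Anyone analyzing (or planning) time-lapse single-molecule tracking
experiments of the "fixed integration time, variable dark period" design —
and anyone who wants to test, at realistic statistics, whether that design
recovers known binding kinetics.

## The model

An observed bound-molecule track ends at dissociation, photobleaching or
movie end, whichever is first.  With integration time t_int fixed and frame
cycle time τ varying between movies, a molecule in state *i* (dissociation
rate k_i) survives *n* frame cycles with probability

    S_τ(nτ) = Σ_i w_i · exp(−(k_i + a/τ) · nτ),        a = k_b · t_int

where *a* is the per-frame bleach number, shared by all conditions.  Fitting
all conditions jointly — non-negative weights w_i on a log-spaced grid of
200 candidate rates (10⁻⁴–10² /s), plus one bleach number — separates true
dissociation from bleaching.  The event weights w_i are converted to the
reported state spectrum by dwell weighting, s_i ∝ w_i / k_i, and the
slowest cluster of the spectrum, resampled 499 times with 80% of the
tracks, gives the long-lived binding time 1/k̄ ± s.d.

See `docs/methods.md` for the estimator details, assumptions and known
limitations.

## Worked example

Simulate an RBPJ-like experiment (five time-lapse conditions, 0.1–14 s; a
910 s slow state carrying 30% of binding events; bleach number 0.05/frame),
then recover the binding time end to end:

```python
from smres import run_pipeline
from smres.studies import recovery_config

config = recovery_config("RBPJ", seed=1, n_resamples=499)
report = run_pipeline(config, outdir="out/")
print(report["slowest_cluster"]["label"])
for tau, counts in report["counts"].items():
    print(f"  {tau} s time-lapse: bound/total = {counts['label']}")
print(report["recovery"])
```

Output from this exact run:

```
765 s (±153 s, mean ± s.d. from resampling)
  0.1 s time-lapse: bound/total = 2527/3000
  0.4 s time-lapse: bound/total = 2518/3625
  1.6 s time-lapse: bound/total = 2541/4290
  6.4 s time-lapse: bound/total = 2489/8090
  14.0 s time-lapse: bound/total = 2397/8575
{'true_slowest_binding_time_s': 910.0, 'estimated_binding_time_s': 765.3, ...}
```

The headline number is the slowest-cluster binding time with its resampling
s.d., printed in the field's reporting convention.  The `bound/total` lines
give, per condition, the number of confined (bound) tracks over the number
of simulated molecules.  The recovery block compares the estimate against
the simulation's ground truth: here 765 s vs 910 s, within this run's
resampling s.d. — the slowest design recovers with a known small-sample low
bias, discussed in `docs/methods.md`.

Every stage is also a CLI subcommand operating on plain files
(TIFF/CSV/JSON), so a pipeline can restart from any artifact:

```bash
smres simulate --config cfg.json --out sim/ --seed 7
smres detect   --movie sim/movie_tl0.1s.tif --snr 4.5 --out spots.csv
smres track    --spots spots.csv --condition 0.1 --config cfg.json --out tracks.csv
smres survive  --tracks tracks.csv --condition 0.1 --n-frames 300 \
               --out sim/survival_tl0.1s.csv
smres grid     --survivals sim/ --kmin 1e-4 --kmax 1e2 --npoints 200 --out spec.json
smres resample --tracks sim/ --n 499 --fraction 0.8 --seed 7 --out res.json
smres run-all  --config cfg.json --out out/
```

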