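# stereomotion

Imaging statistics, model observers and psychometric analyses for
motion-in-depth cue integration.

An object moving along the line of sight produces two image signals: a
change in binocular disparity (CD, the difference of vergence-defined
disparity angles) and a change in image size (CS, the ratio of angular
subtenses). Both depend jointly on viewing distance, distance moved and
physical surface size, so neither maps one-to-one onto the motion that
caused it. This package:

- simulates large ensembles of rigid linear motions and tabulates the
  binned joint posteriors `p(v, m | CD)`, `p(v, m | CS)` and the signal
  co-occurrence distribution `p(CS ∩ CD)` (`image_statistics`);
- recovers scene parameters for held-out motions from those tables
  (per-cue and combined-cue marginal means);
- implements the noisy-measurement integration model for speed-in-depth:
  per-segment Gaussian disparity noise and ratio-of-Gaussians size noise,
  measurement-weighted posterior mixtures, renormalised cue products, and
  `sum |M| / t` speed read-out (`cue_integration`);
- provides model observers for two 2IFC tasks — speed discrimination under
  amplitude cue conflict, and conflict detection via inter-cue
  distance-moved differences, recovered surface sizes, or co-occurrence
  probabilities with inhibitory thresholds (`observers`);
- fits cumulative-Gaussian psychometric functions (binomial ML), derives
  implied single-cue uncertainties from PSEs and combined-cue JNDs, and
  re-expresses conflict thresholds as equivalent physical size ratios
  (`psychometrics`);
- fits observer-model parameters by common-random-numbers MSE minimisation
  and runs parameter-recovery studies (`model_fitting`);
- generates synthetic trial datasets (known psychometric curves, ideal
  linear integrators, or the full model) so every analysis stage is
  testable without human data (`synthetic`).

## CLI

All functionality is reachable through one entry point:

```sh
# Monte Carlo tables (1e6 motions) and the 10,000-motion recovery check
stereomotion build-distributions --n 1000000 --seed 1 --out tables.h5
stereomotion evaluate-recovery --tables tables.h5 --n-test 10000 --seed 2

# model-observer trial tables for either experiment design
stereomotion build-distributions --n 1000000 --seed 1 --observer-resolution --out obs.h5
stereomotion simulate-experiment --design exp1 --tables obs.h5 \
    --n-disparity 0.35 --n-size 3.0 --trials-per-level 200 --seed 3 --out trials.csv

# psychometric fits and derived analyses
stereomotion analyze --task speed --trials trials.csv --out fits.csv
stereomotion implied-uncertainty --fits fits.csv
stereomotion analyze --task conflict --trials conflict_trials.csv --out cfits.csv
stereomotion equivalent-size --fits cfits.csv --n-sims 1000 --seed 4

# synthetic observers and observer-model fitting
stereomotion synth --task exp1 --generator linear-mle --params p.yaml --seed 5 --out synth.csv
stereomotion fit --task speed --trials trials.csv --tables obs.h5 --seed 6 --out fit.json
```

## Layout

```
src/stereomotion/
  geometry.py          closed-form imaging equations, trajectories, conflicts
  image_statistics.py  Monte Carlo tables and scene-parameter recovery
  cue_integration.py   noisy measurement weights, weighted posteriors, speed
  observers.py         2IFC model observers for both tasks
  psychometrics.py     curve fitting, implied uncertainty, equivalent sizes
  model_fitting.py     MSE fitting and parameter recovery
  synthetic.py         synthetic trial-table generators
  io.py, cli.py        HDF5 persistence and the command line
```
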