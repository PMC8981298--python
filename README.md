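# freegait

Lab and free-living gait analysis from a single lower-back accelerometer,
for people working on digital mobility outcomes in Parkinson's disease
(PD): walking-bout detection, wavelet gait-event detection,
inverted-pendulum step length, fourteen spatiotemporal gait
characteristics, aggregation by walking-bout duration, group statistics,
and PD-versus-healthy-control (HC) machine-learning classification —
exercised end to end on a synthetic cohort generator with per-step ground
truth, so every stage is testable without clinical recordings.

## The method

A tri-axial accelerometer (100 Hz, ±8 g) on the lower back records a
2-minute continuous lab walk and multi-day free-living activity. After
gravity alignment and zero-phase 20 Hz Butterworth filtering:

- **Walking bouts** (≥ 3 steps) are found from the moving-window SD of the
  band-passed acceleration magnitude; bouts are never merged across a rest
  gap.
- **Gait events**: initial contacts (IC, heel strike) are minima of a
  first-derivative-of-Gaussian CWT of the integrated vertical acceleration;
  final contacts (FC, toe-off) are maxima of the second-derivative
  transform; the wavelet scale tracks each bout's cadence.
- **Temporal parameters**: step time `IC_{i+1} − IC_i`; stance to the same
  foot's toe-off; swing = stride − stance.
- **Step length** from the inverted pendulum: double-integrate the vertical
  acceleration per step, take the detrended excursion `h`, then
  `SL = 2·sqrt(2lh − h²)` with pendulum length `l`; velocity = length/time.
- **Fourteen characteristics** over five domains (pace, rhythm,
  variability, asymmetry, postural control): five step-level means, five
  standard deviations, four asymmetries (|mean(even steps) − mean(odd
  steps)|).
- **Aggregation** bout → day → week, separately for fourteen bout-duration
  conditions (e.g. ≤10 s, 10–30 s, >60 s, >120 s) plus all-bout and lab.
- **Statistics**: Shapiro-Wilk-gated Welch t / Mann-Whitney U tests with
  AUC = normalised U; mixed (split-plot) ANOVA with partial η²; lab vs
  real-world Pearson correlations.
- **Classification**: RF, SVM and a soft-voting ensemble trained on pooled
  condition rows with participant-level 70/30 splits, grouped 10-fold CV
  grid search, 10 seed repeats, per-condition testing, RF-importance and
  RFE-SVM feature rankings.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (10 PD + 10 HC, one free-living day, ~400–470 bouts/day):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_gait.py
python analysis/03_aggregate.py
python analysis/04_group_stats.py
python analysis/05_classify.py
```

`02_extract_gait.py` reports how the extraction recovers the generator's
ground truth:

```
7993 real-world bouts, 225336 steps extracted
IC recovery: 99.78% of 225351 true contacts within 50 ms
step-time MAE: 8.0 ms | step-length error: 1.84%
```

`03_aggregate.py` prints mean step velocity (m/s) per condition — gait is
slowest in the very short bouts that dominate daily life, fastest in long
bouts, and PD walks slower than HC throughout:

```
condition     HC     PD
lab        1.263  1.095
all_wb     1.012  0.926
le10       0.984  0.910
gt30le60   1.274  1.095
gt60       1.316  1.075
gt120      1.324  1.072
```

`04_group_stats.py` shows the central pattern — discrimination grows with
bout duration (step-velocity AUC 0.70 for ≤10 s bouts rising to 0.95 for
>120 s, versus 0.89 in the lab), i.e. long real-world walking bouts
separate the groups better than short ones. `05_classify.py` reports the
per-condition random-forest accuracy over the seed repeats and the
consensus top features.

The same pipeline is available as a library (`freegait.*` modules), via a
single orchestrator (`freegait.pipeline.run_all`, configured by one YAML
file), and as a CLI (`freegait simulate|extract|aggregate|stats|classify|
run-all`).

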