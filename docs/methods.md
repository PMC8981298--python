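# Methods

`freegait` re-implements, end to end, a free-living digital-gait analysis
for Parkinson's disease (PD) versus healthy controls (HC): a lower-back
tri-axial accelerometer (100 Hz, ±8 g) records a 2-minute continuous lab
walk and multi-day free-living activity; walking bouts are detected, heel
strikes (initial contacts, IC) and toe-offs (final contacts, FC) are located
with a Gaussian continuous wavelet transform, step length comes from an
inverted-pendulum model, fourteen spatiotemporal characteristics are
aggregated over walking-bout-duration conditions, and the aggregated table
feeds a statistical battery and a repeated-seed machine-learning protocol.
Because the corresponding clinical recordings are not publicly available,
every stage is exercised against a synthetic cohort generator with per-step
ground truth.

## Synthetic cohort generator

**Per-step model.** Steps alternate left/right. Step time and step length
are Gaussian around participant-level means, with a systematic left/right
offset (half added to one side, subtracted from the other) producing
controllable asymmetry. The FC of the foot striking at `IC_i` falls at
`IC_i + (2 − swing_fraction)·T`, so a configured swing fraction (swing
time / step time, default 0.76 HC / 0.74 PD) holds per step. Velocity is
length/time by construction (exact, used as an internal consistency check).

**Signal model.** During each step the centre of mass follows an inverted
pendulum: vertical excursion `h = l − sqrt(l² − (SL/2)²)` for step length
`SL` and sensor height `l`. The vertical channel is the second derivative
of a sinusoidal excursion of peak-to-peak `h` per step, plus 1 g gravity,
plus 80-ms Mexican-hat (Ricker) transients at each IC (negative, 0.6 g) and
FC (positive, 0.35 g). The Ricker pulse was chosen over a raised cosine
because it has zero integral and zero net displacement contribution, so the
impact transients leave the double-integration step-length path unbiased
while still giving the wavelet detector a sharp landmark. Anteroposterior
and mediolateral channels carry small locomotor oscillations (0.12 g at
step frequency, 0.06 g at stride frequency). The whole vector is rotated by
a static sagittal tilt (default 5°), white Gaussian noise is added (default
0.05 g) and samples are clipped to ±8 g. Rest is gravity plus noise.

**Bout schedule.** Free-living walking is dominated by very short bouts.
Durations follow a *shifted* lognormal, `D = 2 s + LogNormal(μ, σ)`, with
(μ, σ) solved in closed form so that P(D ≤ 10 s) and P(D > 120 s) equal the
configured tail fractions (defaults 87%/1.8% for PD, 85%/1.9% for HC); the
2-s shift guarantees room for three steps, and durations are capped at
1800 s. A plain lognormal cannot satisfy both tail constraints once
durations are bounded below — the quantile-ratio equation has no solution —
hence the shift. Bout counts per day are Poisson (defaults 408/day PD,
468/day HC, the deposited per-participant weekly totals divided by seven);
rest gaps are 1 s + exponential (mean 6 s). Scheduled bouts are packed from
the start of each calendar day; the recording covers the active window of
the day, and the untracked remainder is rest.

**Context model.** Very short bouts (≤ 10 s, fading out by 30 s) emulate
constrained indoor walking: step velocity is scaled by 0.85, participant
step length is blended 60:40 toward a common 0.60 m, and participant-level
short-bout idiosyncrasies (SD 0.05 m, 0.03 s) decouple short-bout gait from
the participant's steady-state signature. Long bouts (ramping in over
30–120 s) apply a group-specific boost (+5% length HC, −2% PD), emulating
purposeful outdoor walking in which the group contrast is fullest. The
net effect — group discrimination concentrated in long bouts — is the
generative assumption under test in the long-versus-short-bout experiment;
the magnitudes are free choices exposed in `GroupParams`, since per-bin
effect sizes are not published.

**Reproducibility.** Every participant draws from an independent
`SeedSequence(master_seed, (participant_index, stream))` substream, so
enlarging a cohort never perturbs existing participants.

**What the generator does not emulate.** Turning, stairs, running, non-gait
activity, medication on/off fluctuation, device non-wear, soft-tissue
artefact spectra, and gait initiation/termination transients (first and
last steps carry full amplitude). Passing tests therefore demonstrate
algorithmic correctness under this model, not clinical performance on real
recordings.

## Extraction pipeline

**Orientation.** The gravity direction is the mean 0.5 Hz low-passed
vector; the minimal rotation maps it onto the vertical axis. Recordings
shorter than 5 s or with a near-zero gravity vector are rejected.

**Filtering.** Vertical acceleration is low-passed at 20 Hz with a 4th
order Butterworth filter applied forward-backward; zero phase lag keeps
event times unbiased.

**Bout detection.** The vector magnitude is band-passed to 0.5–3 Hz (the
human step-frequency band; this keeps broadband sensor noise below
threshold) and a moving-window SD (0.8 s window, 50% overlap) is compared
with a 0.05 g threshold. Contiguous active windows become candidates;
candidates overlapping after a ±0.4 s margin are one active region.
Candidates are kept only when the event detector finds ≥ 3 ICs, and bout
boundaries snap to the first and last detected contact so durations reflect
walking time. Two signal-level guards were calibrated on the simulator
(the upstream threshold values are not published): (1) detected contacts
that are quiet on *both* sides (band-passed RMS below threshold within
±0.3 s) are wavelet edge artefacts and are pruned; (2) an inter-contact gap
longer than 1.05 s whose centre is quiet is a rest gap and splits the
candidate — walking leaves band energy throughout a gap, a genuine rest
does not. Gaps above 2.5 s always split. Consecutive bouts are never merged
across a rest gap, however short. Lab sessions bypass detection: the whole
2-min walk is one bout.

**Gait events.** McCamley-style: the gravity-removed vertical signal is
cumulatively integrated; a first-derivative-of-Gaussian CWT of the integral
is minimised at ICs, and a second-derivative-of-Gaussian CWT is maximised
near FCs. The wavelet scale tracks the bout's cadence, estimated as the FFT
peak of the *detrended acceleration* in 0.5–3 Hz — estimating it from the
integrated signal (the cited convention) tilts the spectrum toward
low-frequency envelope content and mis-scales the wavelet whenever a
candidate contains more than one bout, so the acceleration spectrum is used
instead. Events are forced to alternate IC, FC, IC, FC …, keeping the more
extreme of adjacent same-kind events; sub-sample positions come from
parabolic interpolation. Note that n steps produce n+1 heel strikes — the
terminal contact that ends the last step is a genuine landmark and is
counted as such when judging false positives.

**Temporal parameters.** `step_time_i = IC_{i+1} − IC_i`; the foot striking
at `IC_i` lifts off at the second FC after it, so `stance_i = FC* − IC_i`
and `swing_i = (IC_{i+2} − IC_i) − stance_i` (swing + stance = stride by
construction). Edge steps lacking events carry NaN.

**Step length.** Per consecutive-IC window the vertical acceleration is
doubly integrated; linear detrending of the displacement removes
integration drift (deterministic and parameter-free, preferred over a
high-pass filter because steps are short); `h` is the peak-to-peak
detrended displacement and `SL = 2·sqrt(2lh − h²)`. Steps with `h ≥ l` are
rejected as artifacts. Sensor height defaults to 0.53 × body height when
height metadata exists, else the generator profile's value.

## Characteristics and aggregation

Fourteen characteristics in five domains: pace (step velocity, step length,
swing time variability), rhythm (step time, swing time, stance time),
variability (SD over all steps of the five base quantities, n−1
denominator — small-n bouts dominate and the estimator must be consistent
everywhere), asymmetry (step time, swing time, stance time) and postural
control (step length asymmetry). Swing time variability conventionally
appears in both pace and variability; it is stored once. Asymmetry is the
absolute difference of the two alternation-parity class means — the
per-pair variant (mean absolute consecutive difference, available via
`asym_method="pair"`) conflates step-to-step variability with systematic
asymmetry, whereas the class-mean form recovers an injected systematic
offset exactly. Absolute left/right labels are unobservable from a single
lumbar sensor; parity suffices for these definitions. Insufficient inputs
yield NaN, never zero.

Aggregation follows bout → day → week: per condition, the day's qualifying
bouts are averaged unweighted (a step-weighted variant sits behind a flag),
then daily means are averaged over contributing days; days without
qualifying bouts contribute nothing. Fourteen duration conditions (half-open
`(lower, upper]` bins: six cumulative `≤X`, six ranges, `>60`, `>120`) plus
all-bout and lab. The five bins {≤10, 10–30, 30–60, 60–120, >120} partition
all durations, giving an exact conservation identity (bout-count-weighted
recombination equals the all-bout daily mean) that the tests assert to
1e-9.

## Statistics

Shapiro-Wilk (α = 0.05, per group) gates Welch's t-test versus
Mann-Whitney U; Welch is used where group sizes and variances differ (a
pooled-variance flag exists). The discriminative AUC is always the
normalised U statistic, oriented ≥ 0.5 with the PD shift direction
recorded. The mixed (split-plot) ANOVA — one between factor (group), one
within factor (condition) — is computed from explicit sums of squares on
complete-case participants, with classical degrees of freedom and partial
η² = SS_effect/(SS_effect + SS_error-for-effect); no sphericity correction
by default (the synthetic within-participant covariance is exchangeable by
construction), with Greenhouse-Geisser-corrected p-values for the within
effects available behind a flag and reported alongside the classical ones.
The within-factor level list is a parameter. No
multiple-comparison adjustment anywhere (exploratory battery). Pearson
correlations between lab and each real-world condition are
pairwise-complete, per group.

## Classification

One pooled design matrix (row = participant × condition, 14 features;
missing cells stay NaN). Per seed: a participant-level, group-stratified
70/30 split — pooling conditions means row-level splitting would leak a
test participant's other rows into training, so the split is by participant
(a deliberate choice; the protocol source does not state it). Median
imputation and standardisation live inside the model pipeline, fitted on
training folds only. Hyperparameters come from grid search with
participant-grouped 10-fold CV on the 70% (folds shrink to the participant
count when fewer than ten are available); the refit models are tested
separately on each condition's 30% rows. SVM probabilities use
cross-validated Platt calibration on the training partition; the ensemble
averages RF and SVM probabilities (soft voting, threshold 0.5). PD is the
positive class. Metrics (accuracy, F1, AUC, sensitivity, specificity, in %)
are reported as mean ± SD over the seed repeats; conditions whose test rows
hold one class are excluded from that seed's mean with a count. Feature
rankings: RF impurity importance and RFE with a linear SVM (one feature per
round), plus the top-5 intersection. Reports are byte-identical across
reruns with fixed seeds.

## Problem sizes

Desk-scale runs use cohorts of 8–10 participants per group with one
monitored day: ~400–470 bouts/day reproduces the study's bout economy at
roughly 200 000 ground-truth contacts per 16–20-participant cohort, which
is ample for the recovery statistics. The long-versus-short-bout experiment
repeats 8-per-group cohorts at 120 bouts/day over ≥ 8 master seeds and
compares the gt60 and le10 conditions; the reduced bout rate keeps ~3–4
long bouts per participant-day, enough to fill the gt60 condition for most
participants. Null calibrations use 2000 replicates at n = 40.

## Known limitations

- Detector constants (SD threshold, rest-gap and artefact-pruning rules)
  are calibrated on the simulator and are not claims about the thresholds
  used on the original clinical data.
- FC localisation carries a small systematic bias (~20 ms, the rising-edge
  offset of the smoothed transient), visible in stance/swing but not in
  step time or length.
- Inverted-pendulum lengths degrade for very short bouts (few complete
  steps between contacts) and are rejected rather than extrapolated.
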