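# Methods

`ctgforesee` implements an integrated predictive fetal-monitoring method:
clinical feature extraction from cardiotocography (CTG) signals, abstaining
ensemble classification of fetal acidosis against umbilical-cord pH, LSTM
forecasting of both signal channels, and classification of the forecasted
future to anticipate the fetus's upcoming state. This note documents the
model choices, the tunable parameters, what the synthetic-data generator
does and does not emulate, and the numerical decisions taken where the
method left the design open.

## Signals and conditioning

A CTG recording is a pair of series sampled at 4 Hz: fetal heart rate (FHR,
beats/min, physiological range 30–250) and uterine activity (UC, arbitrary
monitor units ≥ 0), optionally tagged with the cord pH measured at delivery.
An FHR reading of 0 is the conventional transducer-loss sentinel; loss is
carried as an explicit per-sample mask.

Conditioning applies three primitives in order:

- **Gap repair** — signal-loss runs no longer than `max_gap_seconds`
  (default 15 s) are filled by linear interpolation between their endpoints;
  longer runs stay masked and are excluded from baseline and feature
  computation. 15 s equals the minimum event duration, so a repaired gap can
  never fabricate a qualifying event on its own.
- **Smoothing** — centered moving average; the window in seconds is rounded
  to an odd sample count for symmetry (default 4 s → 17 samples). 4 s
  suppresses beat-level jitter while leaving 15 s events, the shortest the
  taxonomy recognises, essentially intact. Edges use a shrinking, still
  centered window, so output length equals input length and a constant
  series maps to itself.
- **Standardization** — exact z-scoring `(x − μ)/σ` with caller-supplied
  moments, used by the forecaster with training-split statistics only.

## Baseline estimation

The FHR baseline is a fixed point of an iterative loop: start from the mean
of all non-missing samples (M); detect accelerations/decelerations against
M; recompute the mean N over event-free samples; while `|N − M| > 0.5` bpm
set `M ← N` and repeat. The loop is capped at 50 iterations and
non-convergence is reported in the result rather than raised — oscillation
is possible on pathological inputs. Event removal during iteration uses
*untyped* excursions (typing needs the contraction channel, which the
baseline does not). At least 2 minutes of non-missing signal are required.

## Event detection and taxonomy

An *excursion* is a maximal run of the smoothed FHR on one side of the
baseline. Literally delimiting excursions at baseline crossings degenerates
when the event-free signal sits at a small constant offset from the
estimated baseline (there are then no crossings at all), so excursions are
delimited by crossings of a ±0.5 bpm dead band around the baseline — the
same 0.5 bpm as the baseline convergence tolerance, so the dead band can
never hide a qualifying 15 bpm event. An excursion qualifies as an event if
its peak deviation is at least 15 bpm in magnitude and it lasts at least
15 s.

Typing is a deterministic decision list. Durations use the bands
[15 s, 120 s), [120 s, 300 s], (300 s, ∞):

1. positive events: under 2 min → *acceleration*; otherwise → *prolonged
   acceleration* (the taxonomy defines no "severe acceleration"; positive
   excursions over 5 min are also typed prolonged);
2. negative events over 5 min → *severe deceleration*; 2–5 min →
   *prolonged deceleration*;
3. else, if the onset lies strictly inside (paired contraction's peak, its
   offset) and the event lasts more than 15 s → *late deceleration*. The
   paired contraction is the one with maximal overlap;
4. else, if the nadir is reached within 30 s of onset → *variable
   deceleration* ("abrupt onset" operationalised as time-to-nadir);
5. else → *light deceleration*.

The late-before-variable precedence and the light fall-through make the
partition exhaustive and deterministic: every deceleration gets exactly one
subtype, and subtype counts sum to the deceleration count.

Uterine contractions are maximal intervals where the smoothed UC signal
exceeds the resting tone by more than 10 units for 20–240 s; the peak is
the sample of maximal elevation. Resting tone is the rolling 10th
percentile of the UC series over a 10-minute window, computed on a 1 Hz
decimated copy and re-expanded (tone varies over minutes, so decimation is
inconsequential and keeps the filter cheap).

## Per-recording features

The 18-element feature vector: baseline (bpm); counts of accelerations,
decelerations, contractions, variable/severe/late/prolonged/light
decelerations and prolonged accelerations; FHR histogram width, minimum,
maximum, number of peaks, mean, median, mode; and variability. The
histogram uses 1 bpm bins (matching FHR quantization); the mode is the
center of the most populated bin; peaks are local maxima of the
3-bin-smoothed histogram holding at least 5% of total mass. Variability is
the mean absolute successive difference of the smoothed FHR over
event-free, non-missing samples — a short-term-variability style statistic
with a closed form that makes it directly testable. The class label is
`1{pH < 7.2}` with a strict inequality: pH exactly 7.2 is non-acidotic.

Count features that are nonzero in fewer than `min_support = 3` cohort rows
are pruned before classification; features that fire in only a couple of
recordings cannot influence the classifier. Pearson correlation of the
feature table is available for inspection, with constant columns flagged as
undefined rather than silently zeroed.

## Synthetic cohort

Real intrapartum CTG with pH outcomes is hospital data; the generator
stands in for it with recordings whose *statistical shape* matches: a
stable baseline with a bounded slow drift, band-limited variability wander
(Gaussian noise convolved with a ~5 s Hann kernel, scaled so ~4 sd equals
the requested bandwidth, clipped at ±8 bpm so it can neither mask nor
fabricate a 15 bpm event), raised-cosine accelerations/decelerations —
variable decelerations use a steep piecewise-linear drop reaching nadir
within 20 s — quasi-periodic raised-cosine contractions on a tone of 8
units, white sensor noise, exponential-length signal-loss gaps, and pH
drawn from class-dependent normals truncated to keep the label consistent
with the regime.

Default regimes (chosen once as clinically plausible): non-acidotic —
baseline 140 bpm, variability 10 bpm, 12 accelerations/hr, 2 light
decelerations/hr, pH ~ N(7.30, 0.06) truncated to [7.2, 7.5]; acidotic —
baseline 135 bpm, variability 4 bpm, 2 accelerations/hr, 8 decelerations/hr
with a mix favouring late (0.40) and variable (0.35), pH ~ N(7.10, 0.06)
truncated to [6.8, 7.2). Cohorts use one root seed with per-record streams
derived by index, so they are reproducible and insensitive to generation
order. Default recording length is 30 min.

Planted events keep margin over every detection threshold (peaks ≥ 25 bpm
against the 15 bpm floor; durations at least 10 s inside their band; late
decelerations onset 10 s after their contraction's peak, which also lies
inside the *detected* suprathreshold contraction interval; non-late
decelerations avoid the post-peak windows of all contractions; 45 s
minimum spacing). Consequently, with the stochastic nuisances disabled
(zero noise, drift, wander and dropout) the detectors recover the planted
annotation set *exactly* — the generator and detectors close over each
other, which is what makes the extraction algorithm testable without real
data. With nuisances at their defaults, recovery is no longer exact by
design; classes remain separable through the planted late-deceleration and
variability contrast.

What the generator does not emulate: physiologic mechanisms (it is
phenomenological), sinusoidal patterns, maternal-signal crosstalk,
autocorrelated monitor artefacts, or any dependence of pH on the planted
morphology beyond the regime's class. Passing tests therefore demonstrate
the *algorithmic* correctness of extraction, classification and
forecasting under the stated signal model — not clinical performance on
hospital recordings.

## Classification

Four base learners over the z-scored feature table (scaling learned on
training folds only, inside each CV split, to avoid leakage):

- **SVM** — kernels linear, RBF and polynomial (degree 2, 3); grid over
  γ ∈ {0.01, 0.1, 1} and penalty C ∈ {0.1, 1, 10};
- **random forest** — trees ∈ {50, 100, 200}, depth ∈ {∞, 3, 5};
- **neural network** — one hidden layer ∈ {4, 8, 16}, learning rate
  ∈ {0.001, 0.01}, activation ∈ {relu, tanh}, solver ∈ {lbfgs, adam};
- **k-means (k = 2)** — clusters fit on features only, each cluster mapped
  to its majority training label, ties breaking toward acidotic (a false
  alarm is safer than a miss in monitoring); best inertia of 10 restarts.

Grid selection maximises mean stratified 5-fold CV accuracy; ties go to the
simpler model (fewer trees / smaller layer / smaller γ·C), then to grid
order, so selection is deterministic given the seed. The train/test split
is stratified with a fixed test-set size (default 24 of 94).

The **abstaining ensemble** emits a class only when every member agrees and
"unsure" otherwise; "unsure" is a first-class output, never dropped. Each
membership (all subsets of size ≥ 2) is scored by *coverage* (samples
classified) and *accuracy on the classified subset*; the two-objective
Pareto front keeps a point iff no other is ≥ in both coordinates and > in
at least one. Coverage is antitone in membership — unanimity only gets
harder — which is verified as a property.

**Gaussian-noise oversampling** augments small cohorts: each synthetic row
is a real row plus N(0, (σ_frac · column sd)²) noise per column with its
source label, count columns re-rounded and clipped at zero, originals kept
first.

## Forecasting

One forecaster is trained per recording and channel. The architecture
feeds each lookback window to an LSTM layer as a *single* timestep whose
feature vector is the whole window (input shape `(batch, 1, lookback)`),
followed by optional dropout (rate 0.1) and an affine dense head ending in
one unit. The cell follows the standard gate equations with input matrices
U and recurrent matrices W and no gate biases; with one timestep and zero
initial state the forget gate multiplies a zero cell state and the
recurrent matrices multiply a zero output, so the trainable set is U^i,
U^g, U^o and the dense head — backpropagation is exact and cheap, with no
unrolling. The four per-recording reference architectures (lookbacks 1500
and 2000 for the acidotic FHR/UC models, 1000 and 800 for the
non-acidotic ones, all with 10 LSTM cells) are available as presets; the
desk-scale `fast` profile uses lookback 64 with one dense layer and is
what the experiment driver and test suite run.

Protocol: the final 480 samples (2 min) are the validation hold-out; the
remaining prefix splits 80/20 chronologically into train/test targets
(test windows may begin before the boundary — their context precedes the
target, so there is no leakage). The series is smoothed and standardized
with training-split moments (σ < 1e-8 falls back to centering only, so
constant series are well defined). Training is mini-batch SGD on MSE —
learning rate 0.01, momentum 0.9, batch 64, up to 30 epochs with early
stopping (patience 5) on the one-step test loss, restoring the best
weights. Momentum 0.9 is this package's default on top of plain SGD:
momentum-free SGD at this learning rate converges too slowly for the small
epoch budget of the fast profile. Divergence (non-finite loss) raises with
the epoch named.

Reported errors are in original units, against the conditioned
(smoothed) series the model is fitted to: *testing* RMSE/MAE are one-step;
*validation* RMSE/MAE are **recursive** — the model rolls 480 steps
feeding each prediction back into its window, the same regime used in
deployment. RMSE ≥ MAE is asserted structurally in the report. Smoothing
is an option of the forecaster (default on); it is disabled when probing
the white-noise floor, since smoothed white noise is partly predictable
and the floor argument only holds on the raw series.

## Future-state prediction

`predict_future_state` rolls both channel forecasters `h` steps (480 = 2
min, 960 = 4 min), appends the forecasts to the observed series (clipping
to the physiological ranges the record type enforces), extracts features
on the **full extended series**, and lets the configured ensemble members
vote. Extraction on the extended series rather than the forecast window
alone is deliberate: a 2-minute window cannot host 2–5 minute prolonged
events; the `window="forecast-only"` variant is provided for comparison.
The default membership is {RF, NN}; a horizon of 0 is accepted as the
degenerate "classify the observed recording" case used to check
consistency. Outputs use the vocabulary 0 = non-acidosis, 1 = acidosis,
"unsure" for abstention.

`run_experiment` reproduces the full desk-scale study from one seed —
simulate a balanced cohort (default 94 records, 47/47), extract and prune
features, train all learners, evaluate every combination and the Pareto
front, train fast-profile forecasters on one showcase recording per class,
and emit the 2×2 future-state table — with byte-identical JSON on rerun.

## Numerical choices and degenerate inputs

- Dead band ±0.5 bpm for excursion delimitation (see above); NaN samples
  count as "at baseline" and terminate excursions.
- Duration-band edges: exactly 120 s is prolonged, exactly 300 s is
  prolonged (severe requires strictly more than 5 min).
- Histogram span narrower than 1 bpm: a single bin (one peak, width as
  measured).
- Undefined metric ratios (empty denominator) are NaN and flagged by name,
  never zero-filled; a combination that classifies nothing has undefined
  accuracy.
- K-means on fewer distinct rows than k raises; an empty cluster maps to
  the acidotic label by the same safety-first tie rule.
- All randomness flows from explicit integer seeds (cohort streams are
  spawned per record and reduced below 2³¹); repeated runs are identical.

## Problem sizes

The test suite and the experiment driver run at desk scale by choice:
20-minute synthetic recordings for closure checks, 30-minute recordings
for the 94-record cohort, the lookback-64 fast forecaster profile, and
two-hour synthetic series for the forecaster sanity checks. The printed
reference architectures remain available through their spec presets for
longer runs.

## Known limitations

- The feature extractor's subtype rules for variable and light
  decelerations, prolonged accelerations and variability are this
  package's operationalisations; clinical guidelines leave them loose and
  other choices are defensible.
- Per-recording forecasters do not share information across patients; a
  pooled multi-series model is out of scope.
- The synthetic cohort is phenomenological; numbers computed on it
  (accuracies, RMSEs) characterise the implementation, not clinical
  performance. On the default regimes the classes are in fact separated
  well enough that the learners saturate near 100% CV accuracy — real
  cohorts are far harder.
- Forecast quality is only validated on smooth synthetic signals; the
  recursive rollout inherits and compounds any one-step bias.
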