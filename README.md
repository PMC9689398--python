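# ctgforesee

Predictive fetal monitoring from cardiotocography (CTG): extract the
clinical features obstetricians read off a CTG strip, classify fetal
acidosis against umbilical-cord pH with an abstaining ensemble, forecast
both signal channels minutes ahead with small LSTMs, and classify the
forecasted future to anticipate the fetus's upcoming state.

## Who this is for

Researchers in biosignal processing and computerized CTG analysis who need
a complete, testable reference pipeline: a feature extractor with exact
ground-truth closure on synthetic data, an abstention-aware ensemble with
its coverage/accuracy Pareto analysis, and per-recording signal
forecasters — all reproducible from a single seed, with no access to
hospital data required.

## The method

**Signals.** A recording is a pair of 4 Hz series — fetal heart rate
(FHR, beats/min) and uterine activity (UC, monitor units) — optionally
tagged with the cord pH measured at delivery. The class label is
1{pH < 7.2} (acidotic), with pH = 7.2 itself non-acidotic.

**Features.** The FHR baseline is the fixed point of an iterative loop:
start from the trace mean *M*, detect events against *M*, re-mean the
event-free samples to get *N*, and iterate while |N − M| > 0.5 bpm. An
event is a baseline excursion peaking at least 15 bpm away for at least
15 s; decelerations subtype into *severe* (> 5 min), *prolonged*
(2–5 min), *late* (onset strictly after the paired uterine contraction's
peak and before its end), *variable* (nadir within 30 s of onset) and
*light* (the remainder). Contractions are UC excursions > 10 units above
resting tone lasting 20–240 s. Histogram summaries (width, min, max,
peaks, mean, median, mode) and short-term variability complete an
18-element feature vector per recording.

**Classification.** SVM, random forest, a small neural network and a
k-means classifier are grid-tuned under stratified 5-fold CV. The
abstaining ensemble outputs a class only on unanimous agreement and
*unsure* otherwise, trading coverage (samples classified) against accuracy
on the classified subset; all member combinations are scored and the
two-objective Pareto front reported.

**Forecasting.** One LSTM per recording and channel, fed each lookback
window as a single timestep (`(batch, 1, lookback)`), trained with SGD on
MSE. The last 480 samples (2 min) are the validation hold-out, forecast
*recursively* — one-step predictions fed back into the window — and
scored as RMSE/MAE in original units; the remaining prefix splits 80/20
in time into train/test. Future-state prediction appends 480- or 960-step
forecasts (2 or 4 min) to the observed series, re-extracts features on
the extended recording, and lets the ensemble vote: 0, 1, or unsure.

Because real cord-pH-labelled CTG is hospital data, the package ships a
synthetic generator that plants events of every subtype with margins over
the detection thresholds and returns the ground truth, making the whole
pipeline testable end to end (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from ctgforesee import (generate_cohort, feature_table, prune_rare_features,
                        AcidosisEnsemble, LSTMForecaster, fast_spec)
from ctgforesee.features import FEATURE_NAMES

cohort = generate_cohort(94, 0.5, seed=1)          # 47 acidotic / 47 not
table = feature_table(rec for rec, _ in cohort)
labels = table["label"].to_numpy(int)
pruned, dropped = prune_rare_features(table[list(FEATURE_NAMES)], labels)
results = AcidosisEnsemble(pruned, labels, test_size=24, seed=1).fit()
print(results.summary())
```

```
Abstaining acidosis ensemble
============================================================
learner   CV acc  test acc  selected
SVM       100.00    100.00  {'kernel': 'linear', 'gamma': 0.01, 'C': 0.1}
RF        100.00    100.00  {'n_estimators': 50, 'max_depth': 3}
NN        100.00    100.00  {'hidden': 4, 'learning_rate': 0.001, 'activation': 'relu', 'solver': 'lbfgs'}
Clu       100.00    100.00  {}
------------------------------------------------------------
combination        classified  accuracy  front
SVM/RF                     24    100.00      *
...
```

Reading the table: each learner's cross-validated and held-out accuracy
(percent) with the grid point selected for it, then every ensemble
membership with how many of the 24 test recordings it classified
(unanimity required) and its accuracy on those; `*` marks the
coverage/accuracy Pareto front. On the default synthetic regimes the
classes separate cleanly, so the learners saturate — real cohorts are far
harder; the mechanics, not the 100s, are the point.

Forecasting one channel of the first recording:

```python
rec, _ = cohort[0]
fhr = np.nan_to_num(rec.fhr, nan=float(np.nanmean(rec.fhr)))
res = LSTMForecaster(fhr, fast_spec(seed=1)).fit()
print(res.summary())
```

```
LSTM forecaster
================================================
lookback          64
stack             lstm(10) -> dense(1)
optimizer         sgd(lr=0.01, momentum=0.9)
epochs run        30 (batch 64)
testing RMSE      0.2557
testing MAE       0.2016
validation RMSE   0.9726
validation MAE    0.8212
```

Testing errors are one-step-ahead; validation errors are the recursive
480-step (2 min) rollout, both in beats/min. `res.forecast(480)` returns
the 2-minute trajectory itself, and
`predict_future_state(rec, fhr_res, uc_res, models, 480)` turns it into a
future-state vote.

The same study is available from the shell:

```
ctgforesee simulate --n 94 --seed 1 --out-dir data/
ctgforesee extract --in data/synth-000-acidotic.csv --out features.csv
ctgforesee run-experiment --seed 1 --out-dir results/
```

## Layout

- `src/ctgforesee/io.py` — record type, CSV round trip, smoothing, gap
  repair, standardization
- `src/ctgforesee/features.py` — baseline, event taxonomy, contractions,
  histogram/variability, labels, pruning
- `src/ctgforesee/synth.py` — ground-truthed synthetic cohort generator
- `src/ctgforesee/classify.py` — learners, metrics, abstaining ensemble,
  Pareto front, oversampling
- `src/ctgforesee/lstm.py`, `forecast.py` — NumPy LSTM and the
  per-recording forecasters
- `src/ctgforesee/pipeline.py` — future-state prediction and the
  experiment driver
- `docs/methods.md` — full model documentation and design rationale
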