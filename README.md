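# tvrnn — time-varying recurrent networks for early neural decoding

`tvrnn` classifies trial-structured, multi-channel neural time series
('behavior' vs 'control') *sequentially*: it produces a class probability at
every time point using only the data seen so far, and quantifies how early
before behavior onset the decision becomes reliable.  It is aimed at
neural-decoding work on widefield calcium imaging, fMRI region courses and
similar `[trials × time × channels]` data, where the signal statistics
drift across the trial and a single static decoder struggles to be accurate
both early and late.

The core model is the **time-varying RNN (TV-RNN)**: a vanilla tanh
recurrence

    h_t = tanh(W_h^{(k)} h_{t-1} + W_x^{(k)} x_t + b_h^{(k)}),
    y_t = σ(W_y^{(k)} h_t + b_y^{(k)}),      k = ⌈t/w⌉

whose weight bundle switches every `w` time points (one bundle per window)
while the hidden state flows continuously across windows.  All bundles are
trained jointly by backpropagation through time.  Alongside it: static RNNs
trained with the loss on the final output only (**S1**) or aggregated over
all time points (**S2**), a causally-masked Transformer, and sliding
per-window RNN/SVM baselines.  Evaluation uses per-time-point accuracy
under 5-fold cross-validation, the area under the accuracy curve above
chance (**AUAC**), and the **earliest decoding time** (EDT) — the earliest
time from which accuracy stays significantly above chance (one-tailed
t-test over folds, Benjamini–Hochberg corrected) through behavior onset.
Feature importance over (time, channel) comes from integrated-gradient
SHAP approximation, and gradient-stability diagnostics compare recurrent
Jacobian products of static vs time-varying weights.

Everything runs on numpy (forward and backward passes are hand-written and
verified against numerical gradients); no GPU or deep-learning framework is
needed.  A chirp-signal simulator generates ground-truth datasets with the
same kind of temporal distribution shift, so the whole pipeline is testable
offline.

## Worked example

Simulated chirp data (400 trials, 300 time points at 30 Hz, 10 channels;
controls are time-shuffled behavior trials), comparing the static S1-loss
RNN with a TV-RNN (window `w=30` ≙ 1 s), both with 32 hidden units and 200
epochs:

```python
import numpy as np
from tvrnn import (ChirpSpec, generate_chirp_trials, RNNClassifier,
                   TVRNNClassifier, make_cv_splits, temporal_accuracy,
                   earliest_decoding_time, auac)

trials = generate_chirp_trials(ChirpSpec(n_trials=400, seed=0))
split = make_cv_splits(trials.labels, n_folds=5, seed=0)
for name, est in [
    ("RNN-S1", RNNClassifier(strategy="s1", hidden_size=32, epochs=200, random_state=0)),
    ("TV-RNN", TVRNNClassifier(window_size=30, hidden_size=32, epochs=200, random_state=0)),
]:
    probas, labels = [], []
    for f in split.folds:
        fit_idx = np.concatenate([f["train"], f["val"]])
        est.fit(trials.data[fit_idx], trials.labels[fit_idx])
        probas.append(est.predict_proba_trajectory(trials.data[f["test"]]))
        labels.append(trials.labels[f["test"]])
    curve = temporal_accuracy(probas, labels, chance_level=0.5,
                              time_axis_seconds=trials.time_seconds)
    edr = earliest_decoding_time(curve, t_zero_index=trials.t_zero_index)
    edt = "none" if edr.edt_seconds is None else f"{edr.edt_seconds:+.2f} s"
    print(f"{name}: final accuracy {curve.accuracy[-1]:.2f}, "
          f"AUAC {auac(curve):.2f} acc*s, EDT {edt}")
```

prints (a few minutes on one CPU):

```
RNN-S1: final accuracy 0.79, AUAC 0.66 acc*s, EDT -2.93 s
TV-RNN: final accuracy 0.83, AUAC 4.31 acc*s, EDT -4.93 s
```

Reading the numbers: both models classify the full sequence well (final
accuracy at behavior onset, t = 0), but the time-varying model's accuracy
curve is above chance over far more of the trial (AUAC 4.31 vs 0.66
accuracy-seconds over the 10 s trial) and its decoding becomes reliably
significant 4.93 s before onset versus 2.93 s for the static S1 RNN — the
early-decoding advantage that per-window weights buy under distribution
shift.

Estimators follow the scikit-learn contract (`fit`, `predict`,
`predict_proba`, `get_params`/`set_params`, `clone`), with
`predict_proba_trajectory` exposing the full per-time-point output.

## Command line

```bash
tvrnn simulate --spec spec.toml --out data.h5 --seed 7
tvrnn train    --data data.h5 --model tvrnn --config train.toml --out run/
tvrnn evaluate --run run/ --out metrics.csv
tvrnn attribute --run run/ --data data.h5 --output-times "-8,-6,-4,-2,0" --out importance.h5
tvrnn inspect  --run run/ --what weights --out report/
tvrnn run      --config experiment.toml --out run/     # end-to-end
```

Run directories hold per-fold checkpoints (NPZ + JSON sidecar), fold
assignments, gradient traces (CSV), per-time-point metrics, a comparison
table (`Model, Final Accuracy, EDT, AUAC`) and a manifest with config,
seeds and data checksum.  Training presets `wfci-like` (`w=30`, 300-point
trials) and `fmri-like` (`w=2`, 12-point trials) encode the reference
configurations.

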