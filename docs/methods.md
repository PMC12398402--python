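# Methods

## Problem setting

The package addresses early sequential classification of trial-structured,
multi-channel neural time series: given activity `x ∈ R^{R×T}` from `R`
channels (brain regions, imaging components) over `T` time points, decide
at every time point `t` — using only data up to `t` — whether the trial
belongs to the 'behavior' or the 'control' class.  The scientific interest
is in how *early* before behavior onset the decision becomes reliable,
which is hard when the data distribution drifts across the trial (e.g.
signal amplitude and frequency content grow towards onset).

## Models

**Static RNN.** A vanilla tanh recurrence with a per-time-point sigmoid
readout:

    h_t = tanh(W_h h_{t-1} + W_x x_t + b_h),   h_0 = 0
    y_t = σ(W_y h_t + b_y),   class = 1{y_t ≥ 0.5}

Two loss placements train it: **S1**, binary cross-entropy on the final
output `y_T` only (whole-sequence classification), and **S2**,
cross-entropy aggregated over all time points.  We aggregate S2 by the
*mean* over time rather than the sum so the loss scale is independent of
`T`; under Adam this amounts to a learning-rate rescaling and does not
change the optimum.

**Time-varying RNN (TV-RNN).** The same recurrence, but the parameter
bundle `(W_x, W_h, W_y, b_h, b_y)` switches every `w` time points: window
`k = ⌈t/w⌉` owns its own bundle, `⌈T/w⌉` bundles in total, while the hidden
state flows continuously across window boundaries (never reset).  All
bundles are optimized jointly in every batch (end-to-end backpropagation
through time) under the aggregate loss — the natural choice for a model
evaluated at every time point.  An optional warm start first trains a
static RNN under S1 and copies it into every window.  When `w ∤ T` the last
window is truncated rather than padded.

**Causal Transformer baseline.** A pre-norm self-attention encoder whose
attention is masked to past and current steps, with a learned positional
embedding and a per-time-point sigmoid head.  The widths (2 layers, 4
heads, model width 64, feed-forward width 128, dropout 0.1) are baseline
conventions, not tuned values.

**Sliding baselines.** Independent per-window classifiers: a fresh RNN per
window (zero initial hidden state, S1 or S2 loss on the window segment) or
an SVM (RBF kernel by default) on the flattened
`[#trials, #timepoints × #channels]` window array.  Window accuracy is read
at the window's last time point.  These deliberately lack cross-window
state, isolating what the TV-RNN's continuous hidden state adds.

## Training

Glorot-uniform initialization (the original work does not state one), Adam
(lr 1e-4), batch size 64, default 1000 epochs with 64 hidden units; an
internal stratified validation split (rate 0.2) monitors over-fitting and
the kept checkpoint is the epoch with the lowest validation loss
(final-epoch weights are also returned).  No gradient clipping or schedules
— clipping would contaminate the vanishing/exploding-gradient diagnostics.
Every epoch records an example recurrent-weight gradient, a histogram of
`|∂L/∂W_h|`, and counts of entries below 1e-7 (vanishing flag) or above
1e2 (exploding flag); the flags are labels only and never alter training.

All forward/backward passes are hand-written on numpy arrays.  The
sequential inner loops run time-major (`[T, batch, units]`) so each step is
a contiguous BLAS/ufunc call; everything parallel across trials and time is
a single matrix product.  The training path computes in single precision
(the convention for neural-network optimization); parameters, analysis and
inference paths are double precision.  The backward carry loop stops early
once the carried gradient underflows to below 1e-30 with no further loss
injections — mathematically a no-op, numerically it avoids a
subnormal-arithmetic slowdown precisely in the vanishing-gradient regime.
Backward passes (RNN, TV-RNN, Transformer, and all input-gradients) are
verified against central-difference numerical gradients in the test suite.

## Evaluation

**Temporal accuracy.** 5-fold stratified cross-validation; each fold's
remainder splits into train/validation at rate 0.2.  Accuracy at time `t`
is the fold-mean of `(TP+TN)/(TP+TN+FP+FN)` from thresholding `y_t` at 0.5
(a tie counts as class 1, per the threshold rule above).

**AUAC.** Trapezoidal integral of `(accuracy_t − chance)` over a time span
in seconds; negative excursions are included, not clipped.  Chance is 0.5
for balanced classes and the majority-class fraction otherwise.

**Earliest decoding time (EDT).** Per time point, a one-sample one-tailed
t-test of the per-fold accuracies against chance (alternative: greater);
Benjamini–Hochberg correction across the `T` time points of one
model/dataset (never across models); EDT is the earliest `t*` such that
every time point in `[t*, t_zero]` is significant at α = 0.05 after
correction.  A gap tolerance (default 0) can relax the "every" to allow
isolated non-significant points.  Zero fold-variance at a time point gets
p = 0 if the mean beats chance and p = 1 otherwise.  The replicates are the
K fold accuracies — the only replicate structure the CV design defines; a
caller with multi-session data can pass per-session accuracies instead.

## Attribution

Per-feature importance over (time, channel) uses integrated gradients as a
SHAP approximation: the straight path from an all-zeros baseline `x'` to
the trial `x`, trapezoid rule with 128 steps by default, explaining the
sigmoid output at one chosen output time.  The all-zeros baseline satisfies
the `F(x') ≈ 0.5` property of sigmoid heads; a class-mean baseline is
available.  The importance map is the mean *absolute* attribution across
test trials (the signed mean is also exposed).  Completeness
(`Σ IG = F(x) − F(x')`, error O(1/steps)) is checked in the tests, and an
exact Shapley enumeration (≤ 12 features) serves as an independent oracle
on small problems.  For causal models, attributions at input times after
the explained output time are exactly zero.

## Gradient-stability diagnostics

The gradient reaching time `t'` from time `t` in BPTT is proportional to a
product of recurrent matrices over the horizon `t − t'`.  For a static RNN
the product is the matrix power `Ŵ_h^{t−t'}`, whose norm grows or decays
exponentially at a rate set by that single matrix; with per-window matrices
the asymptotic rate is the Lyapunov exponent of the product, which by
submultiplicativity and Jensen's inequality is bounded by the mean log-norm
of one factor — at or below the static rate when both are drawn from the
same ensemble.  The package measures this empirically: products under the
induced 1-norm (max absolute column sum — the submultiplicative reading of
"L1 norm"), the Lyapunov exponent as the least-squares slope of log-norm
against horizon (lower variance than the single-horizon quotient; both
obtainable), and a Monte-Carlo experiment comparing static and time-varying
ensembles (Gaussian entries, sd 1.2/√N by default, one-sided Welch test).
The conclusion is statistical — a tendency over draws — not a per-draw
inequality.

Mechanism analyses: pairwise Frobenius distances between window bundles
(per weight kind), and class-conditional output trajectories with a
divergence time defined as the first `t` where the class means differ by
more than one pooled standard deviation (multiplier configurable; the
original description is only visual).

## Synthetic data

The chirp generator emulates the drift structure of pre-movement neural
recordings without any real data: per behavior trial, every channel carries
the same linear frequency sweep (2 → 30 cycles per trial by default) with a
linearly increasing amplitude envelope (0.2 → 1.0), each channel scaled by
a distinct coefficient from the open interval (1, 4) (evenly spaced
interior points by default — deterministic; uniform draws optional), plus
additive Gaussian noise (sd 0.5).  Each trial gets an independent uniform
initial phase; without it one trial would determine all others up to noise.
Control trials are freshly generated behavior-style trials whose time
indices are permuted — jointly across channels by default, preserving
instantaneous cross-channel structure while destroying temporal order,
which is exactly what a temporal classifier must exploit (per-channel
shuffling is available).  Noise is added after the coefficient scaling
(observation noise); a flag moves it before.  Defaults: 10 channels, 300
time points, 2000 trials, balanced; behavior onset is the last time point.

What this emulates — and what it does not: the generator reproduces the
low→high amplitude/frequency drift visible in widefield recordings before
a lever pull, but has no spatial correlation structure, no hemodynamics,
no session-to-session variability, and a known ground truth.  Tests passing
on it show the machinery is correct and that the early-decoding contrast
between static and time-varying models arises from temporal drift alone;
they do not certify performance numbers on real recordings.

## Desk-scale study conditions

The full-scale recipe (2000 trials, 64 hidden units, 1000 epochs) is
impractical for a routine test run, so the end-to-end checks run a reduced
replica: 400 trials, 32 hidden units, 200 epochs, 5-fold CV, three seeds,
all other settings unchanged.  At this scale single-fold t-tests (K = 5)
are underpowered for the weakly-performing S1 decoder, so the per-fold
accuracies of the three seeds are pooled into 15 replicates per time point
before the EDT analysis.  Under these conditions the S1-trained static RNN
stays within 0.04 of chance for the first ~130 time points and its
sustained above-chance onset lands near time point 160–200 (the drift in
the chirp makes early decoding information-poor), the time-varying model
decodes reliably from the first few time points, and its final accuracy
matches or exceeds the S2 RNN — the same qualitative ordering as the
full-scale experiments.

## Known limitations

- Binary classification only; multi-class heads are out of scope.
- GRU/LSTM cells are not provided; the diagnostics lean on the vanilla
  recurrence's Jacobian structure.
- The Transformer baseline is minimal and CPU-oriented; it exists for
  comparison, not as a tuned competitor.
- Exact Shapley values are exponential in features and capped at 12
  features (test oracle only).
- EDT depends on test power: with few folds/sessions it is conservative
  (later onsets), which is why the desk-scale analysis pools seeds.
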