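# Methods

## Problem and data model

The package classifies three cued mental tasks from precomputed EEG
power-spectral-density (PSD) features: imagined left-hand movement (class
code 2), imagined right-hand movement (3) and covert word generation (7).
The feature stream carries one 96-value frame every 62.5 ms (16 frames/s):
8 centro-parietal electrodes (C3, Cz, C4, CP1, CP2, P3, Pz, P4 in the 10–20
system) × 12 sub-bands of 2 Hz covering 8–30 Hz.  On disk a frame is one
ASCII line of 96 floats, with a 97th integer column carrying the class label
in labelled (training-style) files.  Rows of the in-memory window tensor are
ordered electrode-major (`row = electrode·12 + subband`, sub-bands
ascending); the convention is recorded on every `WindowTensor` so files and
models cannot silently disagree.

The classifier's input unit is a 96×W block of consecutive frames, W = 16
(1 s) by default or 8 (0.5 s).  Windows are cut with stride 1 so that every
frame from the W-th onward is scored exactly once, which makes per-frame
effectiveness against the label column well defined.  The window label
defaults to the *last* frame's label — the causal convention an online BCI
would use; majority-vote and pure-window (drop windows spanning a task
switch) policies are available for experiments.

## Network

Each of the 96 (electrode, sub-band) channels is processed in isolation —
no weights or activations are shared or mixed across channels before the
fully connected stage:

1. **Slicer** — splits the 96×W window into 96 independent 1×W streams.
2. **Conv 1** — per channel, 50 filters of length 5, linear, stride 1.
3. **Conv 2** — per channel, 20 filters of length 3 over the 50 maps,
   linear, stride 1, directly stacked on conv 1 with no pooling between.
4. **Pair-max pooling** — max over *adjacent feature-map pairs* (20 → 10
   maps); the time axis is untouched.  This is deliberately the map-axis
   variant: the layer dimensions it must reproduce are
   (20, 96, 16) → (10, 96, 16).
5. **ReLU**, then concatenation of all 96 channels' activations
   (96·10·W values).
6. **Perceptron layer** — dense to 96 outputs (configurable; 200 is the
   base of the parameter scan), sigmoid activation.
7. **Output layer** — dense to 3, softmax.

Convolutions are the plain dot-product form `f(x,y) = Σ a_ij · b_{x+i,y+j}`.
The default padding is zero-padded *same*-length convolution: the declared
per-layer output dimensions keep the time length at W through both
convolutions, which is only consistent with length-preserving convolution,
so "same" is the default and shrinking "valid" convolution is a config
option.  Even kernel sizes (which the parameter scan generates) are allowed
with a warning; same-padding is then asymmetric (⌊(k−1)/2⌋ left, ⌊k/2⌋
right).

Filter banks are independent per channel, so the default network carries
96·50·5 first-layer filter weights (24 000) and 96·20·50·3 second-layer
weights; a shared-bank option exists for ablation.  `count_parameters`
reports the exact trainable-scalar count (≈1.79 M for the default W=16
network, dominated by the 15 360×96 dense map).

Predicted class on exact probability ties is the lowest class code
(deterministic argmax).

## Training

Loss is softmax cross-entropy, averaged over the minibatch.  Gradients are
analytic and exact for the forward computation — pair-max pooling routes
gradient to the winning map with ties to the lower index, ReLU gates at
zero, the sigmoid is differentiated in closed form — and are validated
against central finite differences (h = 1e−5, relative error < 1e−4) on
every layer type.

**Initialization.**  Filters and the hidden dense map use MSRA (He)
initialization: zero-mean Gaussians with variance 2/fan-in (fan-in = kernel
taps × input maps for convolutions, input width for the dense map).  The
output layer starts at zero so the network opens at the uniform prediction —
the initial loss is exactly ln 3 on any batch — and biases start at zero
throughout.  (With a Gaussian output layer the initial loss sits ≈0.3 nats
above ln 3 because the random logit spread inflates the cross-entropy.)

**Schedules.**  Learning rate over iteration i (one iteration = one
minibatch update), with defaults baseLr = 0.01, gamma = 0.75,
stepsize = 500, maxIter = 15 000, power = 2:

| kind | lr(i) |
|---|---|
| fixed | baseLr |
| step | baseLr · gamma^⌊i/stepsize⌋ |
| exp | baseLr · gamma^i |
| poly | baseLr · (1 − i/maxIter)^power |
| sigmoid | baseLr / (1 + e^(−gamma·(i−stepsize))) |

Two quirks are retained as printed rather than "fixed": with gamma = 0.75
the exp schedule underflows to zero within ~100 iterations (logged at
WARNING), and the sigmoid form *increases* with i toward baseLr rather than
decreasing.  Both schedules are reported to contribute little, which is
consistent with these forms.

**Solvers.**  AdaGrad divides each coordinate's update by the root of its
accumulated squared-gradient history: `w ← w − lr·g/(√Σg² + ε)`, ε = 1e−8
(applied outside the root; the history is accumulated before the update, so
under a constant gradient the t-th step has magnitude exactly lr/√t).
A coordinate whose history is identically zero stays put even with ε = 0.
SGD uses a momentum buffer `b ← μ·b + lr·g`, `w ← w − b`, μ = 0.9 by
default.

**Solver behaviour at small input scale.**  Both solvers start from the
uniform prediction (zero output layer) and must escape a loss plateau at
ln 3 by co-adapting the output layer with the layers beneath it.  Momentum
SGD does this reliably on the synthetic defaults (reaching >95 % held-out
window accuracy within ~300–400 iterations in every draw we measured).
AdaGrad's escape is draw-dependent: its per-coordinate learning rates decay
like 1/√t while the network sits on the plateau, so if the escape has not
begun within roughly the first fifty iterations the effective step sizes are
already too small and the run stays at chance — we observed both outcomes
across data/initialization seeds at several input scales.  For this reason
the learnability tests train with SGD; AdaGrad remains the default solver
elsewhere, matching the method's stated preference, and behaves well once
past the plateau.

**Loop.**  Batch size defaults to 64 windows, shuffled each epoch under the
run seed; all randomness (initialization, shuffling, evaluation subsampling)
derives from a single seed via spawned generator streams, so a run is
bit-reproducible.  Checkpoints every `eval_every` iterations record the
running mean loss and train/test accuracies; to keep checkpointing cheap the
accuracies are measured on fixed random subsamples of at most
`eval_subsample` windows (default 2048 — the binomial standard error at 80%
accuracy is under 1 %), while final per-frame effectiveness is always
computed on the full test session.  The record keeps both the final weights
and the best checkpoint by test accuracy, since held-out accuracy typically
peaks well before the iteration budget is exhausted.  Training arithmetic
runs in single precision by default (the rounding it adds is orders of
magnitude below minibatch gradient noise); `dtype="float64"` is available
and is what the gradient-check tests exercise.

## Parameter scan

`modified_param(x, Δ) = ⌈x·(1+Δ)⌉` with Δ ∈ {−0.50, −0.25, +0.25, +0.50}
perturbs one hyperparameter at a time from its scan base (first-conv kernel
5, second-conv kernel 3, perceptron width 200), giving modified values
{3, 4, 7, 8}, {2, 3, 4, 5} and {100, 150, 250, 300}.  Each cell retrains
with only that parameter changed, seeds matched to the base run so
initialization noise cancels, and is scored by its *accuracy-progress
change*: the mean difference (modified − base) of test-accuracy checkpoints
over matched iterations, in integer-rounded percentage points.  That
curve-level definition was chosen because the scan compares learning
progress, not just final accuracy, and a progress measure is the only
reading under which a "0 %" cell is informative.  Cells that fail to train
are recorded as failures and the scan continues.

## Evaluation

The confusion matrix is oriented predicted-rows × actual-columns, classes
in listed order (2, 3, 7).  The overall success rate (OSR) is trace/N.
Per-class parameters come from the one-vs-rest binarization (TP = diagonal
cell, FP = rest of the predicted row, FN = rest of the actual column,
TN = remainder): ACC, TPR (sensitivity), TNR (specificity), PPV, NPV.  A
zero denominator makes the value undefined (NaN), never 0.  Tabulated
values are rounded half-up to 4 decimals; aggregate standard deviations use
the sample (n−1) convention — both conventions were confirmed by
recomputing the published subject block from its matrix.  Per-frame
effectiveness is 100·correct/scored with the first W−1 frames excluded
(reported), and the generalization error is training-phase accuracy minus
test accuracy in percentage points.

## Synthetic data

The generator emulates the cued-acquisition protocol: 4-minute sessions at
16 frames/s (3840 frames), the subject switching tasks every 15 s (240-frame
blocks, uniform random with no immediate repetition), three labelled
training sessions and one labelled test session per subject by default.

Log band power is `baseline + class_effect + AR(1) noise`; PSD is its
exponential, hence strictly positive.  Defaults:

- `noise_sigma = 0.35` (stationary log-power std — roughly ±40 % power
  fluctuation), `ar_coeff = 0.6` (frame-to-frame correlation, i.e. a drift
  time constant of ~0.1 s).
- Class effects imitate motor-imagery physiology purely to make the classes
  separable: left-hand imagery attenuates mu-band (8–12 Hz) log power by
  0.6 and low-beta (12–16 Hz) by 0.3 over the right sensorimotor sites
  (C4, CP2); right-hand imagery mirrors this over C3/CP1; word generation
  raises parietal (P3, Pz, P4) alpha by 0.5.  These magnitudes make the
  classes strongly separable by design (a nearest-centroid classifier on
  single log-PSD frames exceeds 80 % test accuracy), which is the regime
  the learnability tests assume.
- `baseline ≈ −3` log-power units per channel (PSD ~0.05), declining gently
  with frequency.  The absolute scale is deliberate: the conv layers are
  linear, so O(1) positive inputs would push a large DC component into the
  sigmoid perceptron layer and saturate it, attenuating the class signal by
  more than an order of magnitude; at the physical ≪1 scale the sigmoid
  stays in its linear regime.  This sensitivity to raw input scale is a real
  property of the architecture worth knowing when feeding it unnormalized
  features.

What the generator does **not** model: realistic 1/f spectral shape, raw
multichannel time series, inter-electrode covariance, artifacts, non-
stationarity across sessions, or inter-subject variability.  Passing tests
on this data demonstrate that the pipeline learns class-conditional
band-power structure of the kind the method assumes; they say nothing about
accuracy on real recordings, where effect sizes are far smaller and
noise is structured.

## Problem sizes used in the test suite

The correctness tests run on miniature networks (2–3 channels, 6–8 frame
windows) where brute-force oracles and exhaustive finite differences are
exact and fast.  The learnability tests train the full 96-channel network
(momentum SGD, step schedule) on one default synthetic subject (3 train +
1 test sessions, ~11 500 training windows), stopping at the first
checkpoint reaching the 80 % criterion — typically within a few hundred
iterations on the strongly separable defaults; the chance-level null trains 250 iterations per
permuted run and averages two runs, which keeps the estimate's spread well
inside the ±5-point band while the network is still near its uniform
opening state.

## Known limitations

- The declared "valid" convolution mode of the published layer table is
  inconsistent with its own printed output dimensions; this implementation
  resolves the conflict in favour of the dimensions (same-padding default).
  Results under "valid" padding differ and the flattened feature width
  shrinks accordingly.
- AdaDelta- and Adam-style solvers are out of scope; only AdaGrad and
  momentum SGD are implemented.
- The headline accuracies on the original EEG recordings are not
  reproducible here: they require the original dataset and unrecorded
  seeds.  The evaluation module reproduces the published subject-1 metric
  block exactly from its confusion matrix; the published subject-2/3
  matrices are internally inconsistent with their printed OSRs (sums 3472
  vs 3504; OSR 0.7212 vs 0.7216, 0.5619 vs 0.5571) and are therefore not
  used as verification anchors.
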