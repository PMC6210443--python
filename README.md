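# sbcnn — multi-channel sub-band CNN for EEG mental-task classification

`sbcnn` classifies three cued mental tasks — imagined left-hand movement,
imagined right-hand movement, and covert word generation — from precomputed
EEG power-spectral-density features, the way a brain–computer interface
consumes them: one 96-value frame every 62.5 ms, covering 8 centro-parietal
electrodes (C3, Cz, C4, CP1, CP2, P3, Pz, P4) × 12 frequency sub-bands of
2 Hz spanning 8–30 Hz.  It is aimed at BCI researchers who want a fully
inspectable, dependency-light reference implementation of a frequency-domain
multi-channel CNN pipeline: data I/O, a synthetic-session generator, the
network and its training loop, a hyperparameter scan, and a multi-class
evaluation suite.

## The model

Each of the 96 (electrode, sub-band) channels is treated as an isolated
stream.  A slicer splits the 96×W input window (W = 16 frames ≈ 1 s by
default) into 96 independent 1×W vectors; each passes through its own pair
of directly stacked linear 1-D convolution layers (50 filters of length 5,
then 20 filters of length 3, stride 1, dot-product convolution
f(x,y) = Σᵢⱼ aᵢⱼ·b₍ₓ₊ᵢ,ᵧ₊ⱼ₎), a max pooling over adjacent feature-map
*pairs* (20 → 10 maps, time untouched) and a ReLU.  Nothing crosses
channels until the fully connected stage: all channel activations are
concatenated, mapped through a sigmoid perceptron layer and a linear output
layer, and a softmax yields the three class probabilities.

Training minimizes softmax cross-entropy with exact hand-derived gradients
(verified against finite differences), MSRA/He initialization of the
filters, five learning-rate schedules (fixed, step, exponential,
polynomial, sigmoid; defaults baseLr = 0.01, gamma = 0.75, stepsize = 500,
maxIter = 15 000, power = 2) and a choice of AdaGrad
(w ← w − lr·g/√Σg²) or momentum SGD.

Evaluation reports the multi-class confusion matrix (predicted rows ×
actual columns), the overall success rate OSR = trace/N, per-class
one-vs-rest ACC/TPR/TNR/PPV/NPV, per-frame effectiveness against the test
labels, and the generalization error (training accuracy − test accuracy,
in percentage points).  A one-factor parameter scan perturbs a kernel size
or layer width by ±25 %/±50 % with ceiling rounding, ⌈x·(1+Δ)⌉, and scores
each variant by its accuracy-progress change against the base run.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Generate a synthetic subject (3 labelled training sessions + 1 labelled
test session, 4 minutes each, task switches every 15 s), train the
classifier, and evaluate it:

```sh
sbcnn simulate --seed 7 --out sim/
sbcnn train --train-file sim/train_1.txt --train-file sim/train_2.txt \
            --train-file sim/train_3.txt --test-file sim/test_1.txt \
            --solver sgd --max-iter 400 --eval-every 50 --seed 0 --out trained/
sbcnn evaluate --weights trained/weights_best.npz --test-file sim/test_1.txt \
               --train-accuracy 97.71 --out report/
```

The train step prints a summary (abridged):

```json
{
  "per_run": [0.96923828125],
  "mean": 0.96923828125,
  "final_test_accuracy": 0.96923828125,
  "best_iteration": 400,
  "final_train_accuracy": 0.97705078125
}
```

— window-level accuracies on held-out data (~97 % here: the default
synthetic classes are strongly separable by design).  The evaluate step
writes `report/report.json` with the full confusion matrix and, for this
run, `"osr": 0.9739`, per-frame `"effectiveness_pct": 97.39` over 3825
scored frames (the first 15 frames of the session have no complete 1 s
window and are excluded), a generalization error of 0.32 percentage points
against the supplied training accuracy, and the per-class one-vs-rest
block, e.g. for left-hand imagery (class 2):

```json
{"acc": 0.9791, "tpr": 0.9715, "tnr": 0.9836, "ppv": 0.9729, "npv": 0.9828}
```

`sbcnn lr-table` prints the five schedules over chosen iterations, and
`sbcnn parmod-scan` writes the ceiling-rounded one-factor scan table.

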