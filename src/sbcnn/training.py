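"""Training: initialization, exact gradients, LR schedules, AdaGrad and SGD.

Loss is softmax cross-entropy (mean over the minibatch of the negative log
probability of the true class).  Gradients are analytic and exact for the
forward computation in :mod:`sbcnn.net` — pair-max pooling routes gradient to
the winning map (ties to the lower index), ReLU gates, the perceptron layer's
sigmoid is differentiated in closed form — and are validated against central
finite differences in the test suite.

Learning-rate schedules over iteration i (one iteration = one minibatch
update):

    fixed    lr = baseLr
    step     lr = baseLr * gamma^floor(i / stepsize)
    exp      lr = baseLr * gamma^i
    poly     lr = baseLr * (1 - i/maxIter)^power
    sigmoid  lr = baseLr / (1 + exp(-gamma * (i - stepsize)))

Defaults baseLr=0.01, gamma=0.75, stepsize=500, maxIter=15000, power=2.  Note
two quirks retained deliberately: with gamma=0.75 the exp schedule underflows
to zero within ~100 iterations, and the sigmoid schedule *increases* with i
toward baseLr; both are reported in logs but implemented as written.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .io import Session, session_windows_arrays
from .net import (
    ModelWeights,
    NetworkConfig,
    NumericalError,
    _conv_bank_backward,
    forward,
    predict,
)

logger = logging.getLogger(__name__)

SCHEDULE_KINDS = ("fixed", "step", "exp", "poly", "sigmoid")


@dataclass
class LRSchedule:
    kind: str = "step"
    base_lr: float = 0.01
    gamma: float = 0.75
    stepsize: int = 500
    max_iter: int = 15000
    power: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.base_lr <= 0 or self.gamma <= 0 or self.stepsize < 1 or self.max_iter < 1:
            raise ValueError("invalid schedule parameters")


def lr_at(schedule: LRSchedule, i: int) -> float:
    """Learning rate at iteration i under the given schedule."""
    s = schedule
    if s.kind == "fixed":
        return s.base_lr
    if s.kind == "step":
        return s.base_lr * s.gamma ** math.floor(i / s.stepsize)
    if s.kind == "exp":
        return s.base_lr * s.gamma**i
    if s.kind == "poly":
        return s.base_lr * (1.0 - i / s.max_iter) ** s.power
    return s.base_lr * float(expit(s.gamma * (i - s.stepsize)))


def msra_init(
    shape: tuple[int, ...],
    fan_in: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Zero-mean Gaussian weights with variance 2/fan_in (He initialization)."""
    if fan_in < 1:
        raise ValueError("fan_in must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


def init_weights(config: NetworkConfig, seed: int = 0) -> ModelWeights:
    """MSRA-initialized filters and hidden dense map; output layer zero.

    The output layer starts at zero so the network opens at the uniform
    prediction (loss exactly ln K on any batch) and the logit scale is set by
    learning, not by the draw; all biases start at zero.
    """
    rng = np.random.default_rng(seed)
    w = ModelWeights.zeros(config)
    w.conv1_w = msra_init(w.conv1_w.shape, fan_in=config.conv1_size, rng=rng)
    w.conv2_w = msra_init(
        w.conv2_w.shape, fan_in=config.conv1_filters * config.conv2_size, rng=rng
    )
    w.pl1_w = msra_init(w.pl1_w.shape, fan_in=config.flat_features, rng=rng)
    return w


def loss_and_gradients(
    weights: ModelWeights,
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    config: NetworkConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy loss and its exact gradient for every weight array.

    ``batch_x`` is (B, 96, W); ``batch_y`` holds class codes from
    ``config.classes``.  The gradient dict keys match ModelWeights fields.
    """
    batch_x = np.asarray(batch_x, dtype=weights.pl1_w.dtype)
    if batch_x.ndim == 2:
        batch_x = batch_x[None]
    batch_y = np.atleast_1d(batch_y)
    if len(batch_y) != len(batch_x):
        raise ValueError("batch labels do not match batch size")
    code_to_idx = {c: k for k, c in enumerate(config.classes)}
    try:
        y_idx = np.array([code_to_idx[int(c)] for c in batch_y])
    except KeyError as exc:
        raise ValueError(f"label {exc} outside class set {config.classes}") from None

    probs, cache = forward(batch_x, weights, config, return_cache=True)
    probs = np.atleast_2d(probs)
    batch = len(batch_x)
    p_true = np.clip(probs[np.arange(batch), y_idx].astype(np.float64), 1e-300, None)
    loss = float(-np.log(p_true).mean())
    if not np.isfinite(loss):
        raise NumericalError("non-finite loss")

    onehot = np.zeros_like(probs)
    onehot[np.arange(batch), y_idx] = 1.0
    dz2 = (probs - onehot) / batch

    h1, flat = cache["h1"], cache["flat"]
    grads: dict[str, np.ndarray] = {}
    grads["pl2_w"] = h1.T @ dz2
    grads["pl2_b"] = dz2.sum(axis=0)
    dh1 = dz2 @ weights.pl2_w.T
    dz1 = dh1 * h1 * (1.0 - h1)
    grads["pl1_w"] = flat.T @ dz1
    grads["pl1_b"] = dz1.sum(axis=0)
    dflat = dz1 @ weights.pl1_w.T

    relu, pooled, pool_arg = cache["relu"], cache["pooled"], cache["pool_arg"]
    drelu = dflat.reshape(relu.shape)
    dpooled = drelu * (pooled > 0)
    a2 = cache["a2"]
    b_, c_, f2, length = a2.shape
    pk = config.pool_kernel
    dgrouped = np.zeros((b_, c_, f2 // pk, pk, length), dtype=dpooled.dtype)
    np.put_along_axis(dgrouped, pool_arg[:, :, :, None, :], dpooled[:, :, :, None, :], axis=3)
    da2 = dgrouped.reshape(a2.shape)

    da1, grads["conv2_w"], grads["conv2_b"] = _conv_bank_backward(
        da2, cache["cols2"], weights.conv2_w, cache["a1"].shape, config.padding
    )
    _, dw1, grads["conv1_b"] = _conv_bank_backward(
        da1, cache["cols1"], weights.conv1_w[:, :, None, :], cache["x1"].shape, config.padding
    )
    grads["conv1_w"] = dw1[:, :, 0, :]
    return loss, grads


@dataclass
class SolverState:
    """Per-weight optimizer state.

    For AdaGrad, ``accum`` holds the running sum of squared gradients (the
    update divides by its square root plus ``epsilon``); for SGD, ``buffer``
    holds the momentum-smoothed update.
    """

    solver: str = "adagrad"
    epsilon: float = 1e-8
    momentum: float = 0.9
    accum: dict[str, np.ndarray] = field(default_factory=dict)
    buffer: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0

    def __post_init__(self) -> None:
        if self.solver not in ("adagrad", "sgd"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


def adagrad_step(
    state: SolverState,
    weights: ModelWeights,
    gradients: dict[str, np.ndarray],
    lr: float,
) -> tuple[ModelWeights, SolverState]:
    """One adaptive-gradient update (in place).

    Each coordinate's step is lr * g / (sqrt(sum of past g^2) + epsilon), so
    under a constant gradient the t-th update has magnitude lr / sqrt(t).
    """
    for name, g in gradients.items():
        acc = state.accum.setdefault(name, np.zeros_like(g))
        acc += g * g
        denom = np.sqrt(acc) + state.epsilon
        update = np.zeros_like(g)
        # a zero-history coordinate (g always 0) stays put even with epsilon=0
        np.divide(lr * g, denom, out=update, where=denom > 0)
        getattr(weights, name)[...] -= update
    state.t += 1
    return weights, state


def sgd_step(
    state: SolverState,
    weights: ModelWeights,
    gradients: dict[str, np.ndarray],
    lr: float,
    momentum: Optional[float] = None,
) -> tuple[ModelWeights, SolverState]:
    """One momentum SGD update (in place): buffer <- mu*buffer + lr*g; w -= buffer."""
    mu = state.momentum if momentum is None else momentum
    for name, g in gradients.items():
        buf = state.buffer.setdefault(name, np.zeros_like(g))
        buf *= mu
        buf += lr * g
        getattr(weights, name)[...] -= buf
    state.t += 1
    return weights, state


@dataclass
class TrainRecord:
    """Checkpointed learning curve plus final and best weights."""

    iterations: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    final_weights: Optional[ModelWeights] = None
    best_weights: Optional[ModelWeights] = None
    best_iteration: int = 0
    seed: int = 0

    @property
    def final_test_accuracy(self) -> float:
        return self.test_accuracy[-1] if self.test_accuracy else float("nan")

    @property
    def best_test_accuracy(self) -> float:
        return max(self.test_accuracy) if self.test_accuracy else float("nan")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loss", "train_accuracy", "test_accuracy"])
            for row in zip(self.iterations, self.losses, self.train_accuracy, self.test_accuracy):
                writer.writerow(row)


def _sessions_to_windows(
    sessions: Sequence[Session], width: int
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in sessions:
        if not s.labelled:
            raise ValueError("training/evaluation sessions must be labelled")
        x, y = session_windows_arrays(s, width=width, stride=1)
        xs.append(np.asarray(x))
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


def _subsample_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    weights: ModelWeights,
    config: NetworkConfig,
    idx: Optional[np.ndarray],
) -> float:
    if idx is not None:
        x, y = x[idx], y[idx]
    return float(np.mean(predict(x, weights, config) == y))


def train(
    train_sessions: Sequence[Session],
    test_sessions: Sequence[Session],
    config: NetworkConfig,
    schedule: LRSchedule,
    solver: str = "adagrad",
    max_iter: int = 15000,
    batch_size: int = 64,
    eval_every: int = 500,
    seed: int = 0,
    momentum: float = 0.9,
    epsilon: float = 1e-8,
    target_accuracy: Optional[float] = None,
    eval_subsample: Optional[int] = 2048,
    dtype: str = "float32",
) -> TrainRecord:
    """Minibatch training loop, reproducible under ``seed``.

    Sessions are cut into stride-1 windows of ``config.window`` frames with
    the causal last-frame label.  One iteration is one minibatch update with
    the scheduled learning rate; train/test accuracies are recorded every
    ``eval_every`` iterations (on fixed random subsamples of at most
    ``eval_subsample`` windows, to keep checkpointing cheap).  Returns the
    final weights and the best-checkpoint weights by test accuracy.  If
    ``target_accuracy`` is set, training stops at the first checkpoint
    reaching it.

    ``dtype`` sets the arithmetic precision of the fit (single precision by
    default — the update noise it adds is orders of magnitude below the
    gradient noise of minibatch sampling; pass "float64" for exactness
    studies).
    """
    if not train_sessions:
        raise ValueError("at least one labelled training session is required")
    x_train, y_train = _sessions_to_windows(train_sessions, config.window)
    x_test, y_test = (
        _sessions_to_windows(test_sessions, config.window)
        if test_sessions
        else (None, None)
    )

    seq = np.random.SeedSequence(seed)
    init_seq, shuffle_seq, eval_seq = seq.spawn(3)
    weights = ModelWeights.zeros(config)
    rng_init = np.random.default_rng(init_seq)
    weights.conv1_w = msra_init(weights.conv1_w.shape, config.conv1_size, rng=rng_init)
    weights.conv2_w = msra_init(
        weights.conv2_w.shape, config.conv1_filters * config.conv2_size, rng=rng_init
    )
    weights.pl1_w = msra_init(weights.pl1_w.shape, config.flat_features, rng=rng_init)
    for name, arr in list(weights.items()):
        setattr(weights, name, arr.astype(dtype))

    rng_shuffle = np.random.default_rng(shuffle_seq)
    rng_eval = np.random.default_rng(eval_seq)
    sub_train = (
        rng_eval.choice(len(x_train), eval_subsample, replace=False)
        if eval_subsample and len(x_train) > eval_subsample
        else None
    )
    sub_test = (
        rng_eval.choice(len(x_test), eval_subsample, replace=False)
        if x_test is not None and eval_subsample and len(x_test) > eval_subsample
        else None
    )

    state = SolverState(solver=solver, epsilon=epsilon, momentum=momentum)
    step = adagrad_step if solver == "adagrad" else sgd_step
    record = TrainRecord(seed=seed)
    best_acc = -np.inf
    order = rng_shuffle.permutation(len(x_train))
    cursor = 0
    loss_acc, loss_n = 0.0, 0
    warned_underflow = False

    for i in range(1, max_iter + 1):
        if cursor + batch_size > len(order):
            order = rng_shuffle.permutation(len(x_train))
            cursor = 0
        idx = order[cursor : cursor + batch_size]
        cursor += batch_size
        lr = lr_at(schedule, i - 1)
        if lr == 0.0 and schedule.kind == "exp" and not warned_underflow:
            logger.warning("exp schedule underflowed to lr=0 at iteration %d", i)
            warned_underflow = True
        try:
            loss, grads = loss_and_gradients(weights, x_train[idx], y_train[idx], config)
        except NumericalError as exc:
            raise NumericalError(f"training diverged at iteration {i}: {exc}") from exc
        step(state, weights, grads, lr)
        loss_acc += loss
        loss_n += 1
        logger.debug("iter %d lr %.3g loss %.4f", i, lr, loss)

        if i % eval_every == 0 or i == max_iter:
            train_acc = _subsample_accuracy(x_train, y_train, weights, config, sub_train)
            test_acc = (
                _subsample_accuracy(x_test, y_test, weights, config, sub_test)
                if x_test is not None
                else float("nan")
            )
            record.iterations.append(i)
            record.losses.append(loss_acc / max(loss_n, 1))
            record.train_accuracy.append(train_acc)
            record.test_accuracy.append(test_acc)
            loss_acc, loss_n = 0.0, 0
            logger.info(
                "iter %d loss %.4f train_acc %.4f test_acc %.4f",
                i, record.losses[-1], train_acc, test_acc,
            )
            score = test_acc if x_test is not None else train_acc
            if score > best_acc:
                best_acc = score
                record.best_weights = weights.copy()
                record.best_iteration = i
            if target_accuracy is not None and score >= target_accuracy:
                break

    record.final_weights = weights
    if record.best_weights is None:
        record.best_weights = weights.copy()
    return record


def repeat_and_average(
    run: Callable[[int], "TrainRecord | float"],
    n_repeats: int = 5,
    seeds: Optional[Sequence[int]] = None,
) -> dict:
    """Repeat a training run with distinct seeds and average test effectiveness.

    ``run`` maps a seed to a TrainRecord (its final-checkpoint test accuracy
    is scored) or directly to an accuracy.  Returns per-run accuracies, their
    arithmetic mean, and the seeds used.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    per_run = []
    for s in seeds:
        result = run(int(s))
        acc = result.final_test_accuracy if isinstance(result, TrainRecord) else float(result)
        per_run.append(acc)
    return {"seeds": list(seeds), "per_run": per_run, "mean": float(np.mean(per_run))}
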