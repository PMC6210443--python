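"""Multi-channel CNN forward computation.

The network treats each of the 96 (electrode, sub-band) PSD channels as an
isolated stream: a slicer splits the 96 x W input window into 96 independent
1 x W vectors, each of which passes through its own pair of 1-D convolution
layers (50 filters of length 5, then 20 filters of length 3, both linear),
a max pooling step over the *feature-map* axis (adjacent map pairs, 20 -> 10,
time untouched) and a ReLU.  No information crosses channels until the fully
connected stage, which concatenates all channel activations, maps them
through a sigmoid perceptron layer and a linear output layer, and applies a
softmax over the three task classes.

Convolutions here are the plain dot-product form

    f(x, y) = sum_{i,j} a_ij * b_{x+i, y+j}

with stride 1.  The default padding keeps the time length constant through
both convolutions ("same", zero padding), so a 16-frame window keeps the
shape chain (96,16) -> per channel (50,16) -> (20,16) -> (10,16) -> concat
-> pl1 -> 3; "valid" (shrinking) convolution is available as an option.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.special import expit

from .io import N_CHANNELS, WindowTensor


class NumericalError(FloatingPointError):
    """A non-finite value appeared in a named layer."""


@dataclass
class NetworkConfig:
    """Layer hyperparameters of the classifier."""

    n_channels: int = N_CHANNELS
    window: int = 16
    conv1_filters: int = 50
    conv1_size: int = 5
    conv2_filters: int = 20
    conv2_size: int = 3
    pool_kernel: int = 2
    pool_stride: int = 2
    pl1_outputs: int = 96
    n_classes: int = 3
    padding: str = "same"
    shared_filters: bool = False
    classes: tuple[int, ...] = (2, 3, 7)

    def __post_init__(self) -> None:
        if self.padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {self.padding!r}")
        if self.conv1_size < 1 or self.conv2_size < 1:
            raise ValueError("convolution kernel sizes must be >= 1")
        for name, k in (("conv1_size", self.conv1_size), ("conv2_size", self.conv2_size)):
            if k % 2 == 0:
                warnings.warn(f"{name}={k} is even; same-padding becomes asymmetric")
        if self.pool_kernel != self.pool_stride:
            raise ValueError("pool kernel and stride must match (pair pooling)")
        if self.conv2_filters % self.pool_kernel != 0:
            raise ValueError(
                f"pool kernel {self.pool_kernel} does not divide "
                f"conv2_filters={self.conv2_filters}"
            )
        if 0 < self.pl1_outputs < self.n_classes:
            raise ValueError("pl1_outputs must be >= n_classes")
        if self.padding == "valid" and self.conv_out_len < 1:
            raise ValueError(
                f"window {self.window} too short for valid-mode kernels "
                f"{self.conv1_size} and {self.conv2_size}"
            )
        if len(self.classes) != self.n_classes:
            raise ValueError("classes tuple must have n_classes entries")

    @property
    def conv_out_len(self) -> int:
        """Time length after both convolutions."""
        if self.padding == "same":
            return self.window
        return self.window - (self.conv1_size - 1) - (self.conv2_size - 1)

    @property
    def pooled_maps(self) -> int:
        return self.conv2_filters // self.pool_kernel

    @property
    def flat_features(self) -> int:
        """Concatenated per-channel activations feeding the dense head."""
        return self.n_channels * self.pooled_maps * self.conv_out_len


@dataclass
class ModelWeights:
    """All trainable arrays.

    Convolution banks carry a leading channel axis: one independent filter
    bank per channel (no sharing before the fully connected layer).  With
    ``shared_filters`` the channel axis has extent 1 and broadcasts.
    """

    conv1_w: np.ndarray  # (C|1, F1, k1)
    conv1_b: np.ndarray  # (C|1, F1)
    conv2_w: np.ndarray  # (C|1, F2, F1, k2)
    conv2_b: np.ndarray  # (C|1, F2)
    pl1_w: np.ndarray    # (D, pl1)
    pl1_b: np.ndarray    # (pl1,)
    pl2_w: np.ndarray    # (pl1, n_classes)
    pl2_b: np.ndarray    # (n_classes,)

    def items(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def copy(self) -> "ModelWeights":
        return ModelWeights(**{k: v.copy() for k, v in self.items()})

    @classmethod
    def zeros(cls, config: NetworkConfig) -> "ModelWeights":
        c = 1 if config.shared_filters else config.n_channels
        return cls(
            conv1_w=np.zeros((c, config.conv1_filters, config.conv1_size)),
            conv1_b=np.zeros((c, config.conv1_filters)),
            conv2_w=np.zeros((c, config.conv2_filters, config.conv1_filters, config.conv2_size)),
            conv2_b=np.zeros((c, config.conv2_filters)),
            pl1_w=np.zeros((config.flat_features, config.pl1_outputs)),
            pl1_b=np.zeros(config.pl1_outputs),
            pl2_w=np.zeros((config.pl1_outputs, config.n_classes)),
            pl2_b=np.zeros(config.n_classes),
        )


def slice_window(window: Union[WindowTensor, np.ndarray]) -> np.ndarray:
    """Split a 96 x W window into 96 independent 1 x W channel slices.

    Returns an array of shape (96, 1, W); stacking the slices back in order
    reconstructs the window exactly.
    """
    data = window.data if isinstance(window, WindowTensor) else np.asarray(window)
    if data.ndim != 2 or data.shape[0] != N_CHANNELS:
        raise ValueError(f"expected ({N_CHANNELS}, W) window, got {data.shape}")
    return data[:, None, :]


def _pad_amounts(k: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    return (k - 1) // 2, k // 2


def conv1d(
    maps_in: np.ndarray,
    kernel: np.ndarray,
    bias: Optional[np.ndarray] = None,
    padding: str = "same",
) -> np.ndarray:
    """Single-channel 1-D convolution bank, stride 1.

    ``maps_in`` is (M_in, L); ``kernel`` is (M_out, M_in, k); output is
    (M_out, L') where L' = L for "same" (zero padding) and L - k + 1 for
    "valid".  Each output element is the dot product of the kernel with the
    aligned input region, plus the per-map bias.
    """
    maps_in = np.atleast_2d(np.asarray(maps_in, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 3 or kernel.shape[1] != maps_in.shape[0]:
        raise ValueError(f"kernel {kernel.shape} incompatible with input {maps_in.shape}")
    m_out, m_in, k = kernel.shape
    lo, hi = _pad_amounts(k, padding)
    x = np.pad(maps_in, ((0, 0), (lo, hi)))
    if k > x.shape[1]:
        raise ValueError(f"kernel length {k} exceeds (padded) input length {x.shape[1]}")
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (M_in, L', k)
    out = np.einsum("mlk,omk->ol", cols, kernel)
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)[:, None]
    return out


def pool_feature_maps(maps_in: np.ndarray, kernel: int = 2, stride: int = 2) -> np.ndarray:
    """Max pooling over the feature-map axis; the time axis is untouched.

    Output map m at time t is the max of input maps {m*kernel .. m*kernel +
    kernel-1} at time t, so 20 maps x 16 samples become 10 maps x 16 samples.
    """
    if kernel != stride:
        raise ValueError("only non-overlapping pooling is supported")
    maps_in = np.asarray(maps_in)
    m, length = maps_in.shape
    if m % kernel:
        raise ValueError(f"map count {m} not divisible by pool kernel {kernel}")
    return maps_in.reshape(m // kernel, kernel, length).max(axis=1)


def _check_finite(arr: np.ndarray, layer: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise NumericalError(f"non-finite value in layer {layer!r}")


def _conv_bank_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, padding: str
) -> tuple[np.ndarray, np.ndarray]:
    """Batched per-channel convolution.

    x: (B, C, M_in, L); w: (C|1, M_out, M_in, k); returns output
    (B, C, M_out, L') and the im2col matrix kept for backprop.
    """
    batch, n_ch, m_in, length = x.shape
    m_out, k = w.shape[1], w.shape[3]
    lo, hi = _pad_amounts(k, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (lo, hi)))
    if k > xp.shape[-1]:
        raise ValueError(f"kernel length {k} exceeds (padded) window length {xp.shape[-1]}")
    out_len = xp.shape[-1] - k + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=3)  # (B,C,M_in,L',k)
    cols = np.ascontiguousarray(view.transpose(1, 0, 3, 2, 4)).reshape(
        n_ch, batch * out_len, m_in * k
    )
    wmat = w.reshape(w.shape[0], m_out, m_in * k).transpose(0, 2, 1)  # (C|1, M_in*k, M_out)
    out = np.matmul(cols, wmat)  # (C, B*L', M_out)
    out = out.reshape(n_ch, batch, out_len, m_out).transpose(1, 0, 3, 2)
    out = out + b[None, :, :, None]
    return out, cols


def _conv_bank_backward(
    d_out: np.ndarray,
    cols: np.ndarray,
    w: np.ndarray,
    in_shape: tuple[int, ...],
    padding: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a batched conv bank: (d_x, d_w, d_b)."""
    batch, n_ch, m_in, length = in_shape
    m_out, k = w.shape[1], w.shape[3]
    lo, hi = _pad_amounts(k, padding)
    out_len = d_out.shape[3]
    dmat = np.ascontiguousarray(d_out.transpose(1, 0, 3, 2)).reshape(
        n_ch, batch * out_len, m_out
    )
    d_wmat = np.matmul(cols.transpose(0, 2, 1), dmat)  # (C, M_in*k, M_out)
    d_w = d_wmat.transpose(0, 2, 1).reshape(n_ch, m_out, m_in, k)
    if w.shape[0] == 1:  # shared bank: accumulate over channels
        d_w = d_w.sum(axis=0, keepdims=True)
    d_b = d_out.sum(axis=(0, 3))
    if w.shape[0] == 1:
        d_b = d_b.sum(axis=0, keepdims=True)
    wmat = w.reshape(w.shape[0], m_out, m_in * k)
    d_cols = np.matmul(dmat, wmat)  # (C, B*L', M_in*k)
    d_view = d_cols.reshape(n_ch, batch, out_len, m_in, k).transpose(1, 0, 3, 2, 4)
    d_xp = np.zeros((batch, n_ch, m_in, length + lo + hi), dtype=d_out.dtype)
    for t in range(k):
        d_xp[..., t : t + out_len] += d_view[..., t]
    return d_xp[..., lo : lo + length], d_w, d_b


def forward(
    window: Union[WindowTensor, np.ndarray],
    weights: ModelWeights,
    config: NetworkConfig,
    return_cache: bool = False,
):
    """Class probabilities for one window or a batch.

    Accepts a (96, W) window or a (B, 96, W) batch; returns probabilities of
    shape (n_classes,) or (B, n_classes) summing to 1.  With ``return_cache``
    also returns the intermediate activations needed for backpropagation.
    """
    wdtype = weights.pl1_w.dtype  # compute in the precision of the weights
    data = window.data if isinstance(window, WindowTensor) else window
    data = np.asarray(data, dtype=wdtype)
    single = data.ndim == 2
    if single:
        data = data[None]
    if data.shape[1] != config.n_channels or data.shape[2] != config.window:
        raise ValueError(
            f"expected (B, {config.n_channels}, {config.window}) input, got {data.shape}"
        )
    _check_finite(data, "input")

    x1 = data[:, :, None, :]  # (B, C, 1, W): each channel one input map
    w1 = weights.conv1_w[:, :, None, :]  # single input map
    a1, cols1 = _conv_bank_forward(x1, w1, weights.conv1_b, config.padding)
    _check_finite(a1, "conv1")
    a2, cols2 = _conv_bank_forward(a1, weights.conv2_w, weights.conv2_b, config.padding)
    _check_finite(a2, "conv2")

    batch, n_ch, f2, length = a2.shape
    pk = config.pool_kernel
    grouped = a2.reshape(batch, n_ch, f2 // pk, pk, length)
    pool_arg = grouped.argmax(axis=3)  # ties -> lower map index
    pooled = np.take_along_axis(grouped, pool_arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    _check_finite(pooled, "pool")
    relu = np.maximum(pooled, 0.0)

    flat = relu.reshape(batch, -1)
    z1 = flat @ weights.pl1_w + weights.pl1_b
    _check_finite(z1, "pl1")
    h1 = expit(z1)
    z2 = h1 @ weights.pl2_w + weights.pl2_b
    _check_finite(z2, "pl2")
    shifted = z2 - z2.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    _check_finite(probs, "softmax")

    if not return_cache:
        return probs[0] if single else probs
    cache = {
        "input": data, "x1": x1, "a1": a1, "cols1": cols1, "a2": a2, "cols2": cols2,
        "pool_arg": pool_arg, "pooled": pooled, "relu": relu, "flat": flat,
        "h1": h1, "probs": probs,
    }
    return (probs[0] if single else probs), cache


def predict(
    x: np.ndarray,
    weights: ModelWeights,
    config: NetworkConfig,
    chunk: int = 128,
) -> np.ndarray:
    """Predicted class codes for a (B, 96, W) batch, evaluated in chunks.

    Exact probability ties resolve to the lowest class code (deterministic
    argmax; ``config.classes`` is listed in ascending code order).
    """
    x = np.asarray(x, dtype=weights.pl1_w.dtype)
    out = np.empty(len(x), dtype=int)
    codes = np.array(config.classes)
    for start in range(0, len(x), chunk):
        probs = forward(x[start : start + chunk], weights, config)
        out[start : start + chunk] = codes[np.argmax(probs, axis=1)]
    return out


def parameter_breakdown(config: NetworkConfig) -> dict[str, int]:
    """Trainable scalar count per layer, biases included.

    Counts follow this module's conventions: independent per-channel filter
    banks (the channel factor drops to 1 under ``shared_filters``).
    """
    c = 1 if config.shared_filters else config.n_channels
    return {
        "conv1_w": c * config.conv1_filters * config.conv1_size,
        "conv1_b": c * config.conv1_filters,
        "conv2_w": c * config.conv2_filters * config.conv1_filters * config.conv2_size,
        "conv2_b": c * config.conv2_filters,
        "pl1_w": config.flat_features * config.pl1_outputs,
        "pl1_b": config.pl1_outputs,
        "pl2_w": config.pl1_outputs * config.n_classes,
        "pl2_b": config.n_classes,
    }


def count_parameters(config: NetworkConfig) -> int:
    """Total number of trainable scalars."""
    return sum(parameter_breakdown(config).values())


def save_weights(path: str | Path, weights: ModelWeights, config: NetworkConfig) -> None:
    """Serialize weights to an .npz archive with a JSON config header."""
    header = {f.name: getattr(config, f.name) for f in fields(config)}
    header["classes"] = list(config.classes)
    header["channel_order"] = "electrode-major"
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **dict(weights.items()),
    )


def load_weights(path: str | Path) -> tuple[ModelWeights, NetworkConfig]:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__config__"].tobytes()).decode())
        header.pop("channel_order", None)
        header["classes"] = tuple(header["classes"])
        config = NetworkConfig(**header)
        weights = ModelWeights(**{k: archive[k] for k, _ in ModelWeights.zeros(config).items()})
    return weights, config
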