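"""Reading, writing and windowing of PSD feature sessions.

The on-disk format is whitespace-delimited ASCII: one line per 62.5 ms frame,
96 power-spectral-density values (8 centro-parietal electrodes x 12 sub-bands
of 2 Hz covering 8-30 Hz), with an optional 97th integer column carrying the
mental-task class label (2 = left-hand imagery, 3 = right-hand imagery,
7 = word generation).  Frames arrive 16 per second.

Rows of a window tensor are ordered electrode-major: row = electrode*12 +
subband, electrodes in file column order, sub-bands ascending from 8-10 Hz to
28-30 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

#: electrode sites in file column order (standard 10-20 names)
ELECTRODES = ("C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4")
N_ELECTRODES = 8
N_SUBBANDS = 12
N_CHANNELS = N_ELECTRODES * N_SUBBANDS  # 96
FRAME_RATE = 16  # frames per second (one frame every 62.5 ms)
CLASS_SET = (2, 3, 7)


class FeatureFileError(ValueError):
    """Raised for malformed or invalid feature files."""


def channel_index(electrode: int, subband: int) -> int:
    """Row index of an (electrode, subband) pair: electrode-major ordering."""
    if not (0 <= electrode < N_ELECTRODES and 0 <= subband < N_SUBBANDS):
        raise ValueError(f"electrode {electrode} / subband {subband} out of range")
    return electrode * N_SUBBANDS + subband


def channel_coords(row: int) -> tuple[int, int]:
    """Inverse of :func:`channel_index`."""
    if not 0 <= row < N_CHANNELS:
        raise ValueError(f"row {row} out of range")
    return divmod(row, N_SUBBANDS)


@dataclass
class FeatureFrame:
    """A single 96-value PSD vector with an optional task label."""

    values: np.ndarray
    label: Optional[int] = None
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite PSD value")
        if np.any(self.values < 0):
            raise ValueError("negative PSD value")
        if self.label is not None and self.label not in CLASS_SET:
            raise ValueError(f"label {self.label} not in {CLASS_SET}")


@dataclass
class Session:
    """An ordered sequence of PSD frames, stored densely.

    ``values`` has shape (n_frames, 96); ``labels`` is None for an unlabelled
    (test-style) session, else an int array of shape (n_frames,).
    """

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, N_CHANNELS)
        if self.values.shape[1] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} columns, got {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite PSD value in session")
        if np.any(self.values < 0):
            raise ValueError("negative PSD value in session")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.values),):
                raise ValueError("labels length does not match frame count")
            bad = set(np.unique(self.labels)) - set(CLASS_SET)
            if bad:
                raise ValueError(f"labels {sorted(bad)} not in {CLASS_SET}")

    @property
    def labelled(self) -> bool:
        return self.labels is not None

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> FeatureFrame:
        label = int(self.labels[i]) if self.labelled else None
        return FeatureFrame(self.values[i], label=label, index=i)

    def __iter__(self) -> Iterator[FeatureFrame]:
        for i in range(len(self)):
            yield self[i]


@dataclass
class WindowTensor:
    """A 96 x W block of consecutive frames — the network's input unit.

    ``channel_order`` records the row convention so models and files cannot
    silently disagree.
    """

    data: np.ndarray
    label: Optional[int] = None
    start: int = 0
    channel_order: str = "electrode-major"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"window must be ({N_CHANNELS}, W), got {self.data.shape}")

    @property
    def width(self) -> int:
        return self.data.shape[1]


def read_feature_file(path: str | Path, labelled: bool) -> Session:
    """Parse an ASCII feature file into a :class:`Session`.

    Each non-blank line must hold 96 floats (``labelled=False``) or 96 floats
    plus an integer class label as the 97th token (``labelled=True``).
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    want = N_CHANNELS + (1 if labelled else 0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != want:
                raise FeatureFileError(
                    f"{path}:{lineno}: expected {want} tokens, found {len(tokens)}"
                )
            try:
                vals = np.array([float(t) for t in tokens[:N_CHANNELS]])
            except ValueError as exc:
                raise FeatureFileError(f"{path}:{lineno}: {exc}") from None
            if not np.all(np.isfinite(vals)):
                raise FeatureFileError(f"{path}:{lineno}: non-finite value")
            if labelled:
                try:
                    lab = int(float(tokens[-1]))
                except ValueError:
                    raise FeatureFileError(
                        f"{path}:{lineno}: unparseable label {tokens[-1]!r}"
                    ) from None
                if lab not in CLASS_SET:
                    raise FeatureFileError(
                        f"{path}:{lineno}: label {lab} not in {CLASS_SET}"
                    )
                labels.append(lab)
            rows.append(vals)
    values = np.array(rows) if rows else np.empty((0, N_CHANNELS))
    return Session(values, labels=np.array(labels, dtype=int) if labelled else None)


def write_feature_file(session: Session, path: str | Path) -> None:
    """Write a session in the ASCII feature format (96 or 97 columns).

    Values are printed with 10 significant digits so a read/write round trip
    preserves at least 6.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(len(session)):
            cols = [f"{v:.10g}" for v in session.values[i]]
            if session.labelled:
                cols.append(str(int(session.labels[i])))
            fh.write(" ".join(cols) + "\n")


def window_session(
    session: Session,
    width: int = 16,
    stride: int = 1,
    label_policy: str = "last",
) -> list[WindowTensor]:
    """Cut a session into fixed-width input windows.

    Window k covers frames ``[k*stride, k*stride + width)``; its rows are the
    96 channels, its columns the ``width`` consecutive frames.  Label policies
    for labelled sessions:

    ``last``
        the label of the final (most recent) frame — the causal convention an
        online BCI would use; the default.
    ``majority``
        the most frequent label in the window (ties to the lowest class code).
    ``pure``
        windows spanning a task switch are dropped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if label_policy not in ("last", "majority", "pure"):
        raise ValueError(f"unknown label_policy {label_policy!r}")
    if width not in (8, 16):
        warnings.warn(f"window width {width} is nonstandard (expected 8 or 16)")
    n = len(session)
    if n < width:
        warnings.warn(f"session of {n} frames shorter than window width {width}")
        return []
    out: list[WindowTensor] = []
    for start in range(0, n - width + 1, stride):
        block = session.values[start : start + width].T
        label: Optional[int] = None
        if session.labelled:
            labs = session.labels[start : start + width]
            if label_policy == "last":
                label = int(labs[-1])
            elif label_policy == "majority":
                classes, counts = np.unique(labs, return_counts=True)
                label = int(classes[np.argmax(counts)])
            else:  # pure
                if len(np.unique(labs)) > 1:
                    continue
                label = int(labs[0])
        out.append(WindowTensor(block, label=label, start=start))
    return out


def session_windows_arrays(
    session: Session, width: int = 16, stride: int = 1
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Vectorised windowing for training: (n_windows, 96, W) plus last-frame labels.

    Equivalent to ``window_session(..., label_policy='last')`` but returns a
    zero-copy view, which matters when a 4-minute session yields ~3800
    overlapping windows.
    """
    n = len(session)
    if n < width:
        return np.empty((0, N_CHANNELS, width)), (
            np.empty(0, dtype=int) if session.labelled else None
        )
    sw = np.lib.stride_tricks.sliding_window_view(session.values, width, axis=0)
    # sliding view is (n-width+1, 96, width) with window axis last
    x = sw[::stride]
    y = session.labels[width - 1 :: stride][: len(x)] if session.labelled else None
    return x, y


def stack_windows(windows: Sequence[WindowTensor]) -> tuple[np.ndarray, np.ndarray]:
    """Stack WindowTensors into (n, 96, W) data and (n,) label arrays."""
    x = np.stack([w.data for w in windows])
    y = np.array([-1 if w.label is None else w.label for w in windows])
    return x, y
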