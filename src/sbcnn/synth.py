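"""Synthetic PSD session generator.

Emulates the structure of a cued mental-task recording: ~4-minute sessions of
96-channel PSD frames at 16 frames/s, with the subject switching between
three tasks every 15 s on cue.  The generative law is log-normal band power
with AR(1) temporal correlation — PSD positivity and slow drift are the only
structural facts the downstream classifier relies on; this is a stand-in, not
a model of real EEG.

Class separability is injected as class-conditional offsets on the log-power
of physiologically chosen channels: hand-movement imagery attenuates mu/low-
beta power over the contralateral sensorimotor sites (event-related
desynchronization), word generation modulates alpha over the parietal sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import (
    CLASS_SET,
    ELECTRODES,
    FRAME_RATE,
    N_CHANNELS,
    N_ELECTRODES,
    N_SUBBANDS,
    Session,
    channel_index,
)

# sub-band indices: band s covers (8+2s) .. (10+2s) Hz
MU_BANDS = (0, 1)        # 8-12 Hz
LOW_BETA_BANDS = (2, 3)  # 12-16 Hz

_ELEC = {name: i for i, name in enumerate(ELECTRODES)}


def default_class_effects(
    erd: float = 0.6, beta_frac: float = 0.5, parietal: float = 0.5
) -> dict[int, np.ndarray]:
    """Per-class 96-vectors of mean log-power offsets.

    Left-hand imagery (class 2) suppresses the right sensorimotor sites
    (C4, CP2); right-hand imagery (class 3) the left (C3, CP1); word
    generation (class 7) raises alpha over the parietal sites (P3, Pz, P4).
    Magnitudes are in log-power units (an offset of 0.6 is a ~45% power
    change).
    """
    effects = {c: np.zeros(N_CHANNELS) for c in CLASS_SET}

    def _erd(cls: int, sites: tuple[str, ...]) -> None:
        for site in sites:
            e = _ELEC[site]
            for s in MU_BANDS:
                effects[cls][channel_index(e, s)] -= erd
            for s in LOW_BETA_BANDS:
                effects[cls][channel_index(e, s)] -= erd * beta_frac

    _erd(2, ("C4", "CP2"))
    _erd(3, ("C3", "CP1"))
    for site in ("P3", "Pz", "P4"):
        for s in MU_BANDS:
            effects[7][channel_index(_ELEC[site], s)] += parietal
    return effects


def default_baseline() -> np.ndarray:
    """Mean log power per channel.

    Band power in physical units is well below 1 (tens of uV^2/Hz expressed
    in V^2-scale units, here ~0.05 after the upstream scaling), declining
    gently with frequency.  The absolute scale matters: the classifier's
    convolution layers are linear, so O(1) positive inputs would push a large
    DC component into the sigmoid perceptron layer and saturate it.
    """
    per_band = -3.0 - 0.08 * np.arange(N_SUBBANDS)
    return np.tile(per_band, N_ELECTRODES)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic acquisition.

    Defaults mirror the emulated protocol: 8 electrodes x 12 sub-bands,
    16 frames/s, 4-minute sessions, a task switch every 15 s (240 frames).
    """

    n_electrodes: int = N_ELECTRODES
    n_subbands: int = N_SUBBANDS
    frame_rate: int = FRAME_RATE
    session_minutes: float = 4.0
    block_seconds: float = 15.0
    class_set: tuple[int, ...] = CLASS_SET
    class_effects: Optional[dict[int, np.ndarray]] = None
    baseline: Optional[np.ndarray] = None
    noise_sigma: float = 0.35
    ar_coeff: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.class_effects is None:
            self.class_effects = default_class_effects()
        if self.baseline is None:
            self.baseline = default_baseline()

    @property
    def n_channels(self) -> int:
        return self.n_electrodes * self.n_subbands

    @property
    def n_frames(self) -> int:
        return int(round(self.session_minutes * 60 * self.frame_rate))

    @property
    def block_frames(self) -> int:
        return int(round(self.block_seconds * self.frame_rate))


def block_label_schedule(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame labels: uniform random block sequence with no immediate repeat."""
    n, block = config.n_frames, config.block_frames
    if n <= 0 or block <= 0:
        raise ValueError("degenerate config: zero-length session or block")
    classes = list(config.class_set)
    labels = np.empty(n, dtype=int)
    prev = None
    for start in range(0, n, block):
        choices = [c for c in classes if c != prev]
        cls = int(rng.choice(choices))
        labels[start : start + block] = cls
        prev = cls
    return labels


def generate_session(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> Session:
    """Draw one labelled session.

    Log power = baseline + class effect + AR(1) noise with stationary
    standard deviation ``noise_sigma``; PSD = exp(log power), hence strictly
    positive.  The same config (and seed) always yields the same session.
    """
    if config.n_frames <= 0:
        raise ValueError("degenerate config: zero-length session")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = block_label_schedule(config, rng)

    n, ch = config.n_frames, config.n_channels
    eps = rng.standard_normal((n, ch))
    noise = np.empty((n, ch))
    a = config.ar_coeff
    innov = config.noise_sigma * np.sqrt(1.0 - a * a)
    noise[0] = config.noise_sigma * eps[0]
    for t in range(1, n):
        noise[t] = a * noise[t - 1] + innov * eps[t]

    log_power = config.baseline[None, :] + noise
    for cls in config.class_set:
        mask = labels == cls
        log_power[mask] += config.class_effects[cls][None, :]
    return Session(np.exp(log_power), labels=labels)


def generate_dataset(
    config: GeneratorConfig, n_train_sessions: int = 3, n_test_sessions: int = 1
) -> tuple[list[Session], list[Session]]:
    """Independent sessions from the same law: default 3 train + 1 test.

    Per-session streams are spawned from the config seed, so sessions are
    mutually independent yet the whole dataset is reproducible.
    """
    if n_train_sessions < 1 or n_test_sessions < 1:
        raise ValueError("session counts must be >= 1")
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(n_train_sessions + n_test_sessions)
    sessions = [generate_session(config, np.random.default_rng(s)) for s in children]
    return sessions[:n_train_sessions], sessions[n_train_sessions:]
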