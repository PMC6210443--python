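"""One-factor hyperparameter scan with ceiling-rounded perturbations.

A base hyperparameter x (first/second convolution kernel size, or the width
of the first perceptron layer) is perturbed by a relative factor delta in
{-0.50, -0.25, +0.25, +0.50} and rounded *up* to the nearest integer:

    modified = ceil(x * (1 + delta))

Each perturbed configuration is retrained (one parameter changed at a time,
seeds matched to the base run so initialization noise cancels) and scored by
its accuracy-progress change: the mean difference, modified minus base, of
test-accuracy checkpoints over matched iterations, in percentage points
rounded to the nearest integer.  Configurations that fail to train are
recorded as failures and the scan continues.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .net import NetworkConfig
from .training import LRSchedule, train

logger = logging.getLogger(__name__)

SCANNABLE = ("conv1_size", "conv2_size", "pl1_outputs")
DEFAULT_DELTAS = (-0.50, -0.25, 0.25, 0.50)
#: scan bases: kernel sizes 5 and 3; the wider (200-output) perceptron layer
DEFAULT_BASES = {"conv1_size": 5, "conv2_size": 3, "pl1_outputs": 200}


def modified_param(x: int, delta: float) -> int:
    """Perturbed integer parameter value: ceil(x * (1 + delta))."""
    if x < 1:
        raise ValueError("base value must be >= 1")
    if 1.0 + delta <= 0:
        raise ValueError(f"delta {delta} would zero out the parameter")
    value = math.ceil(x * (1.0 + delta))
    if value < 1:
        raise ValueError(f"modified value {value} < 1 for x={x}, delta={delta}")
    return value


@dataclass
class ParmodSpec:
    """One scanned parameter: its name, base value and relative deltas."""

    name: str
    base: Optional[int] = None
    deltas: tuple[float, ...] = DEFAULT_DELTAS

    def __post_init__(self) -> None:
        if self.name not in SCANNABLE:
            raise ValueError(f"parameter {self.name!r} not scannable (use {SCANNABLE})")
        if self.base is None:
            self.base = DEFAULT_BASES[self.name]
        if self.base < 1:
            raise ValueError("base must be a positive integer")
        for d in self.deltas:
            if not -1.0 < d < 1.0:
                raise ValueError(f"delta {d} outside (-1, 1)")


@dataclass
class ScanRow:
    parameter: str
    delta: float
    modified_value: int
    change_pct: Optional[int]  # None if this cell failed to train
    error: Optional[str] = None

    @property
    def label(self) -> str:
        sign = "+" if self.delta > 0 else "−"
        pct = int(round(abs(self.delta) * 100))
        return f"{sign}{pct}% {self.parameter} ({self.modified_value})"


def progress_change(base_curve: Sequence[float], mod_curve: Sequence[float]) -> int:
    """Mean checkpoint-accuracy difference (modified - base), rounded % points."""
    n = min(len(base_curve), len(mod_curve))
    if n == 0:
        raise ValueError("empty learning curves")
    diff = np.asarray(mod_curve[:n]) - np.asarray(base_curve[:n])
    return int(round(100.0 * float(diff.mean())))


def run_scan(
    base_config: NetworkConfig,
    specs: Sequence[ParmodSpec],
    train_sessions,
    test_sessions,
    schedule: Optional[LRSchedule] = None,
    solver: str = "adagrad",
    max_iter: int = 1000,
    eval_every: int = 100,
    batch_size: int = 64,
    seeds: Sequence[int] = (0,),
    eval_subsample: Optional[int] = 2048,
) -> list[ScanRow]:
    """Train the base and each single-parameter modification; tabulate changes.

    The change for a cell is averaged over ``seeds`` (each seed shared
    between its base and modified run) before integer rounding.
    """
    schedule = schedule or LRSchedule()

    def _run(config: NetworkConfig, seed: int):
        return train(
            train_sessions, test_sessions, config, schedule, solver=solver,
            max_iter=max_iter, batch_size=batch_size, eval_every=eval_every,
            seed=seed, eval_subsample=eval_subsample,
        )

    base_curves = {s: _run(base_config, s).test_accuracy for s in seeds}
    rows: list[ScanRow] = []
    for spec in specs:
        for delta in spec.deltas:
            try:
                value = modified_param(spec.base, delta)
                config = replace(base_config, **{spec.name: value})
                changes = []
                for s in seeds:
                    mod_curve = _run(config, s).test_accuracy
                    n = min(len(mod_curve), len(base_curves[s]))
                    changes.append(
                        100.0
                        * float(
                            np.mean(
                                np.asarray(mod_curve[:n])
                                - np.asarray(base_curves[s][:n])
                            )
                        )
                    )
                rows.append(
                    ScanRow(spec.name, delta, value, int(round(float(np.mean(changes)))))
                )
            except Exception as exc:  # noqa: BLE001 — per-cell failures are data
                logger.warning("scan cell %s delta=%+.2f failed: %s", spec.name, delta, exc)
                value = -1
                try:
                    value = modified_param(spec.base, delta)
                except Exception:
                    pass
                rows.append(ScanRow(spec.name, delta, value, None, error=str(exc)))
    return rows


def write_scan_csv(rows: Sequence[ScanRow], path: str | Path) -> None:
    """Two-column table: modification label, rounded accuracy-progress change %."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["modification", "accuracy_progress_change_pct"])
        for row in rows:
            writer.writerow(
                [row.label, "FAILED" if row.change_pct is None else f"{row.change_pct}%"]
            )
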