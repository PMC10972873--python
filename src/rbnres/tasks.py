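"""Synthetic input signals and task assembly.

Two benchmark tasks probe a reservoir's computation:

* **memory** — the input is i.i.d. white noise u(t) on [0, 1] and the target
  is the same stream delayed by |delta| steps, T(t) = u(t - |delta|), with
  delta in {-2, -6, -10, -14, -18}; larger |delta| demands longer retention
  of input information inside a network of memoryless neurons.
* **prediction** — the input is the discrete Mackey-Glass map

      x_{t+1} = a x_t + b x_{t-tau} / (c + x_{t-tau}^d),

  with a = 0.9, b = 0.2, c = 0.9, d = 10, x_0 = 0.1, and the target is the
  series 10 steps ahead.  tau switches the signal from periodic (tau = 5)
  through intermediate (15) to chaotic (28).

Inputs and targets are min-max normalised to [0, 1] (the readout is a
sigmoid; Pearson correlation is affine-invariant, so scores are unaffected).
Each task carries a washout plus an alignment margin excluded from fitting,
and disjoint train/test index ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MGParams",
    "TaskData",
    "white_noise",
    "mackey_glass",
    "make_memory_task",
    "make_prediction_task",
    "PREDICTION_HORIZON",
]

PREDICTION_HORIZON = 10

MEMORY_DELTAS = (-2, -6, -10, -14, -18)
PREDICTION_TAUS = (5, 15, 28)


@dataclass(frozen=True)
class MGParams:
    """Constants of the discrete Mackey-Glass map (mg_* to avoid clashing
    with the balance b and the readout bias c)."""

    tau: int
    mg_a: float = 0.9
    mg_b: float = 0.2
    mg_c: float = 0.9
    mg_d: float = 10.0
    x0: float = 0.1

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@dataclass(frozen=True)
class TaskData:
    """A paired input/target series with fitting index ranges.

    ``target`` is NaN at indices where the defining shift leaves it
    undefined; ``train_range`` and ``test_range`` are disjoint and exclude
    the washout and the alignment margin.
    """

    kind: str  # "memory" | "prediction"
    difficulty: int  # delta (negative) or tau (positive)
    input: np.ndarray
    target: np.ndarray
    washout: int
    train_range: range
    test_range: range

    def __post_init__(self) -> None:
        if self.kind not in ("memory", "prediction"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if len(self.input) != len(self.target):
            raise ValueError("input and target must have equal length")
        for rng in (self.train_range, self.test_range):
            if np.isnan(self.target[list(rng)]).any():
                raise ValueError("fitting range covers undefined target values")


def white_noise(length: int, seed) -> np.ndarray:
    """I.i.d. uniform noise on [0, 1), deterministic in seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return np.random.default_rng(seed).random(length)


def mackey_glass(params: MGParams, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Orbit of the discrete Mackey-Glass map.

    The pre-history is constant: x_t = x0 for all t <= 0.  Returns
    ``(raw, normalized)`` where ``raw[0] = x0`` and ``raw[t]`` follows the
    recurrence, and ``normalized`` is the affine min-max rescaling of the
    same orbit onto [0, 1].
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    x = np.empty(length)
    x[0] = params.x0
    for t in range(length - 1):
        x_del = x[t - params.tau] if t - params.tau >= 0 else params.x0
        x[t + 1] = params.mg_a * x[t] + params.mg_b * x_del / (
            params.mg_c + x_del**params.mg_d
        )
        if not np.isfinite(x[t + 1]):
            raise FloatingPointError(f"Mackey-Glass orbit diverged at step {t + 1}")
    span = x.max() - x.min()
    normalized = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    return x, normalized


def _ranges(first_usable: int, last_usable: int, n_test: int, what: str):
    """Train/test ranges over [first_usable, last_usable): test is the fixed
    tail of ``n_test`` indices, train absorbs the alignment margin."""
    n_usable = last_usable - first_usable
    if n_usable < n_test + 1:
        raise ValueError(
            f"{what}: only {n_usable} usable fitting indices, need > {n_test}"
        )
    split = last_usable - n_test
    return range(first_usable, split), range(split, last_usable)


def make_memory_task(
    delta: int,
    length: int = 2600,
    washout: int = 100,
    n_test: int = 500,
    seed=0,
) -> TaskData:
    """White-noise memory task: T(t) = u(t - |delta|).

    The first ``washout + |delta|`` indices are excluded from fitting; the
    test range is the last ``n_test`` indices, the train range everything in
    between (so harder delays have proportionally fewer training pairs).
    """
    if delta >= 0:
        raise ValueError("delta must be a negative integer")
    d = -delta
    if d >= length - washout:
        raise ValueError(f"|delta|={d} leaves no usable pairs at length {length}")
    u = white_noise(length, seed)
    target = np.full(length, np.nan)
    target[d:] = u[:-d]
    train, test = _ranges(washout + d, length, n_test, f"memory delta={delta}")
    return TaskData(
        kind="memory", difficulty=delta, input=u, target=target,
        washout=washout, train_range=train, test_range=test,
    )


def make_prediction_task(
    tau: int,
    length: int = 2600,
    washout: int = 100,
    n_test: int = 500,
    seed=None,
) -> TaskData:
    """Mackey-Glass prediction task: T(t) = u(t + 10).

    ``u`` is the normalised orbit; the last 10 indices have no target and
    are excluded from fitting.  The orbit is deterministic, so ``seed`` is
    accepted for interface uniformity and ignored.
    """
    h = PREDICTION_HORIZON
    if length <= washout + h:
        raise ValueError(f"length {length} too short for washout {washout} + horizon {h}")
    _, u = mackey_glass(MGParams(tau=tau), length)
    target = np.full(length, np.nan)
    target[:-h] = u[h:]
    train, test = _ranges(washout, length - h, n_test, f"prediction tau={tau}")
    return TaskData(
        kind="prediction", difficulty=tau, input=u, target=target,
        washout=washout, train_range=train, test_range=test,
    )
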