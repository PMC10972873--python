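"""Sigmoid readout training and scoring.

The only trained component of the reservoir system is a single output unit

    y(t) = sigmoid( W_out . x_readout(t) + c )

fitted to the task target by full-batch gradient descent on the mean squared
error, using the ADAM update rule (alpha = 0.001, 4000 epochs by default).
Performance is the Pearson correlation Corr(y, T) on the held-out test
range: ~0 for a reservoir that carries no usable input information, 1 for a
perfect readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import driven_run
from .network import Reservoir, balance_of_sigma_star
from .tasks import TaskData

__all__ = [
    "ReadoutModel",
    "TrainConfig",
    "PerformanceRecord",
    "DegenerateTargetError",
    "UndefinedCorrelationError",
    "train_readout",
    "evaluate",
    "pearson",
    "run_task_on_reservoir",
]


class DegenerateTargetError(ValueError):
    """Raised when the training target is constant."""


class UndefinedCorrelationError(ValueError):
    """Raised when either series in a correlation is constant."""


@dataclass
class ReadoutModel:
    """Trained readout: one weight per readout neuron plus a bias."""

    weights: np.ndarray
    bias: float

    def predict(self, rows: np.ndarray) -> np.ndarray:
        """Sigmoid output for each row of readout-half states."""
        z = rows.astype(float) @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 4000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class PerformanceRecord:
    """One (reservoir, task) evaluation, keyed by grid point and seed."""

    N: int
    K: int
    sigma_star: float
    b: float
    task: str
    difficulty: int
    seed: int
    correlation: float
    final_loss: float
    initial_loss: float


def train_readout(
    readout_states: np.ndarray, target: np.ndarray, cfg: TrainConfig
) -> tuple[ReadoutModel, np.ndarray]:
    """Fit the sigmoid readout by full-batch ADAM on the MSE loss.

    ``readout_states`` is the (T, M) matrix of readout-half bit rows aligned
    with ``target``.  Weights are initialised from a small centred normal
    scaled by 1/sqrt(M) (seeded by ``cfg.seed``); the bias starts at zero.
    Returns the model and the per-epoch loss trace.
    """
    X = np.asarray(readout_states, dtype=float)
    t = np.asarray(target, dtype=float)
    if X.shape[0] != t.size:
        raise ValueError(
            f"{X.shape[0]} state rows vs {t.size} target values"
        )
    if np.all(t == t[0]):
        raise DegenerateTargetError("training target is constant")

    M = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    theta = np.zeros(M + 1)
    theta[:M] = rng.normal(0.0, 1.0, M) / np.sqrt(M)

    m = np.zeros(M + 1)
    v = np.zeros(M + 1)
    losses = np.empty(cfg.epochs)
    b1, b2, eps, lr = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps, cfg.learning_rate
    T = t.size
    for epoch in range(cfg.epochs):
        z = X @ theta[:M] + theta[M]
        y = 1.0 / (1.0 + np.exp(-z))
        err = y - t
        losses[epoch] = float(np.mean(err**2))
        gz = (2.0 / T) * err * y * (1.0 - y)
        grad = np.empty(M + 1)
        grad[:M] = X.T @ gz
        grad[M] = gz.sum()
        m = b1 * m + (1.0 - b1) * grad
        v = b2 * v + (1.0 - b2) * grad**2
        m_hat = m / (1.0 - b1 ** (epoch + 1))
        v_hat = v / (1.0 - b2 ** (epoch + 1))
        theta = theta - lr * m_hat / (np.sqrt(v_hat) + eps)
    return ReadoutModel(weights=theta[:M], bias=float(theta[M])), losses


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, raising if either series is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("correlation undefined for constant series")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(
    model: ReadoutModel, readout_states: np.ndarray, target: np.ndarray, index_range
) -> float:
    """Corr(y, T) of the model's output against the target over a range."""
    idx = list(index_range)
    if not idx:
        raise ValueError("evaluation range is empty")
    y = model.predict(np.asarray(readout_states)[idx])
    return pearson(y, np.asarray(target, dtype=float)[idx])


def run_task_on_reservoir(
    reservoir: Reservoir,
    task: TaskData,
    cfg: TrainConfig,
    active_fraction: float = 0.2,
    init_seed=0,
    readout_states: np.ndarray | None = None,
    b: float | None = None,
) -> PerformanceRecord:
    """Drive the reservoir with the task input, train, and score.

    The readout is fitted on the train range and the reported correlation is
    computed on the held-out test range only.  ``readout_states`` may be
    passed to reuse an already-collected trajectory (e.g. when several
    delays share one input series); it must come from the same reservoir,
    input and initial state.  ``b`` overrides the analytic balance in the
    record (used by exact zero-balance probes, whose sign counts are not
    those implied by sigma_star).
    """
    if readout_states is None:
        readout_states, _ = driven_run(
            reservoir, task.input, active_fraction=active_fraction, seed=init_seed
        )
    idx = list(task.train_range)
    model, losses = train_readout(readout_states[idx], task.target[idx], cfg)
    try:
        corr = evaluate(model, readout_states, task.target, task.test_range)
    except UndefinedCorrelationError:
        # a constant output (e.g. an extinguished reservoir feeding the
        # readout all-zero rows) carries no input information: score 0
        corr = 0.0
    spec = reservoir.spec
    return PerformanceRecord(
        N=spec.N,
        K=spec.K,
        sigma_star=spec.sigma_star,
        b=balance_of_sigma_star(spec.sigma_star) if b is None else b,
        task=task.kind,
        difficulty=task.difficulty,
        seed=spec.seed,
        correlation=corr,
        final_loss=float(losses[-1]),
        initial_loss=float(losses[0]),
    )
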