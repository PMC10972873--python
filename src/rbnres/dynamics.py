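"""Synchronous Boolean dynamics of a reservoir.

Every neuron is a zero-threshold Heaviside unit updated in parallel:

    x_i(t) = theta( u_i(t) + sum_j w_ij x_j(t-1) ),   theta(z) = 1 iff z > 0,

where ``u_i(t) = input_scale * u(t)`` for the input half and 0 otherwise.
The convention ``theta(0) = 0`` makes the all-zero state absorbing in free
runs, which is what allows the "extinguished" attractor category to exist.
A continuous weight law makes exact ties measure-zero, so the convention is
immaterial for generic reservoirs.

The scalar summary of a run is the mean activity

    A(t) = (1/N) sum_i x_i(t),

always an integer multiple of 1/N; traces store the integer active counts so
that downstream attractor classification can compare values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Reservoir

__all__ = ["ActivityTrace", "initial_state", "step", "free_run", "driven_run"]

#: retain full bit-state history only up to this many neurons by default
STATE_HISTORY_CAP = 4096


@dataclass
class ActivityTrace:
    """Mean-activity trace A(t), stored as integer active counts over N."""

    counts: np.ndarray  # (D,) int64, number of active neurons per step
    N: int

    @property
    def values(self) -> np.ndarray:
        """A(t) as floats in [0, 1] (integer multiples of 1/N)."""
        return self.counts / self.N

    @property
    def D(self) -> int:
        return len(self.counts)

    def window(self, t0: int) -> "ActivityTrace":
        """The steady sub-trace from step ``t0`` onwards."""
        if t0 >= self.D:
            raise ValueError(f"t0={t0} beyond trace length {self.D}")
        return ActivityTrace(counts=self.counts[t0:], N=self.N)


def initial_state(N: int, active_fraction: float, seed) -> np.ndarray:
    """Random binary state with exactly ``round(active_fraction * N)`` ones.

    An exact count (rather than Bernoulli draws) keeps small-N ensembles
    reproducible at the nominal activity level.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    n_on = int(np.rint(active_fraction * N))
    rng = np.random.default_rng(seed)
    state = np.zeros(N, dtype=np.uint8)
    state[rng.permutation(N)[:n_on]] = 1
    return state


def step(reservoir: Reservoir, state: np.ndarray, input_value: float = 0.0) -> np.ndarray:
    """One synchronous update of all N neurons."""
    N = reservoir.spec.N
    if len(state) != N:
        raise ValueError(f"state has length {len(state)}, reservoir has N={N}")
    field = np.einsum("nk,nk->n", reservoir.weights, state[reservoir.sources].astype(float))
    if input_value != 0.0:
        field[: reservoir.n_input] += reservoir.spec.input_scale * input_value
    return (field > 0.0).astype(np.uint8)


def free_run(
    reservoir: Reservoir,
    D: int = 2000,
    active_fraction: float = 0.2,
    seed=0,
    keep_states: bool = False,
    state_window: tuple[int, int] | None = None,
):
    """Run the reservoir without input for ``D`` update steps.

    Returns ``(states, trace)`` where ``trace.counts[t]`` is the active count
    after update ``t + 1`` (the random initial state is not part of the
    trace).  ``states`` is ``None`` unless requested: ``keep_states=True``
    retains the full (D, N) bit history (refused above
    ``STATE_HISTORY_CAP`` neurons to bound memory — pass a ``state_window``
    ``(lo, hi)`` instead to keep only steps ``lo <= t < hi``).

    A state equal to its predecessor (including the absorbing all-zero
    state) can never change again under the deterministic update, so the
    remaining trace is filled without further simulation.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    N = reservoir.spec.N
    if keep_states and state_window is None and N > STATE_HISTORY_CAP:
        raise ValueError(
            f"full state history refused for N={N} > {STATE_HISTORY_CAP}; "
            "pass state_window=(lo, hi)"
        )
    if keep_states:
        lo, hi = state_window if state_window is not None else (0, D)
        states = np.zeros((hi - lo, N), dtype=np.uint8)
    else:
        states = None

    counts = np.zeros(D, dtype=np.int64)
    x = initial_state(N, active_fraction, seed)
    for t in range(D):
        x_new = step(reservoir, x)
        counts[t] = int(x_new.sum())
        if states is not None and lo <= t < hi:
            states[t - lo] = x_new
        if np.array_equal(x_new, x):  # fixed point (incl. all-zero): absorb
            counts[t:] = counts[t]
            if states is not None:
                for u in range(max(t + 1, lo), hi):
                    states[u - lo] = x_new
            break
        x = x_new
    return states, ActivityTrace(counts=counts, N=N)


def driven_run(
    reservoir: Reservoir,
    input_series: np.ndarray,
    active_fraction: float = 0.2,
    seed=0,
):
    """Drive the reservoir with a scalar input series.

    Returns ``(readout_states, trace)``: one row per input step, restricted
    to the readout half, with row ``t`` the state after consuming
    ``input_series[t]``.  A zero input series reproduces the free-run
    trajectory for the same seed exactly.
    """
    u = np.asarray(input_series, dtype=float)
    if u.size == 0:
        raise ValueError("input series is empty")
    if not np.all(np.isfinite(u)):
        raise ValueError("input series must be finite-valued")
    N = reservoir.spec.N
    readout = reservoir.readout_set
    rows = np.zeros((u.size, readout.size), dtype=np.uint8)
    counts = np.zeros(u.size, dtype=np.int64)
    x = initial_state(N, active_fraction, seed)
    for t in range(u.size):
        x = step(reservoir, x, input_value=u[t])
        rows[t] = x[readout]
        counts[t] = int(x.sum())
    return rows, ActivityTrace(counts=counts, N=N)
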