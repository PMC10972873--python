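"""Attractor taxonomy of steady activity traces.

The steady window of a free run (t > 1000 by default) is sorted into four
mutually exclusive categories, in this precedence order:

* **extinguished** — the activity is exactly zero at every step (the
  all-zero state is absorbing under the zero-threshold update);
* **fixed** — the activity is constant and nonzero;
* **cyclic** — the activity repeats with the minimal period p in
  [2, floor(L/2)] (a candidate period must be observed at least twice
  within the window);
* **irregular** — none of the above.  The dynamics being deterministic and
  finite, every orbit is eventually periodic with period up to 2^N; a window
  of a few thousand steps is vanishingly short on that scale, so "irregular"
  is an operational label for periods the window cannot resolve.

Activity values are integer multiples of 1/N by construction, so all
comparisons are exact integer-count comparisons, never float tolerances.

For small networks (N <= 12 by default) :func:`exact_cycle_oracle` finds the
true transient length and state-space period by first-recurrence detection
over full states, providing an independent check of the window classifier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dynamics import ActivityTrace, step
from .network import Reservoir

__all__ = [
    "AttractorLabel",
    "AttractorHistogram",
    "OracleScopeError",
    "CATEGORIES",
    "classify_attractor",
    "attractor_statistics",
    "exact_cycle_oracle",
]

CATEGORIES = ("extinguished", "fixed", "cyclic", "irregular")

ORACLE_N_CAP = 12


class OracleScopeError(ValueError):
    """Raised when the exhaustive cycle oracle is asked for too large an N."""


@dataclass(frozen=True)
class AttractorLabel:
    category: str
    period: int | None = None  # minimal activity period, present iff cyclic

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "cyclic") != (self.period is not None):
            raise ValueError("period is present exactly when category is cyclic")
        if self.period is not None and self.period < 2:
            raise ValueError("cyclic period must be >= 2")


@dataclass(frozen=True)
class AttractorHistogram:
    """Category counts and percentages over an ensemble of R runs."""

    counts: dict
    percentages: dict
    R: int


def classify_attractor(trace: ActivityTrace, t0: int = 1000) -> AttractorLabel:
    """Classify the steady window of an activity trace.

    The window is ``A(t0 .. D-1)``; comparisons use the underlying integer
    active counts, so equality is exact.
    """
    c = trace.window(t0).counts
    L = c.size
    if L < 4:
        raise ValueError(f"steady window of length {L} < 4")
    if not c.any():
        return AttractorLabel("extinguished")
    if (c == c[0]).all():
        return AttractorLabel("fixed")
    for p in range(2, L // 2 + 1):
        if (c[: L - p] == c[p:]).all():
            return AttractorLabel("cyclic", period=p)
    return AttractorLabel("irregular")


def attractor_statistics(labels) -> AttractorHistogram:
    """Exact category counts and percentages over a nonempty label list."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    tally = Counter(lbl.category for lbl in labels)
    R = len(labels)
    counts = {cat: tally.get(cat, 0) for cat in CATEGORIES}
    percentages = {cat: 100.0 * n / R for cat, n in counts.items()}
    return AttractorHistogram(counts=counts, percentages=percentages, R=R)


def exact_cycle_oracle(
    reservoir: Reservoir, init: np.ndarray, n_cap: int = ORACLE_N_CAP
) -> tuple[int, int]:
    """Exact (transient length, state period) by first-recurrence detection.

    Iterates the free dynamics from ``init``, hashing full states, until a
    state repeats — guaranteed within 2^N steps.  Only offered for
    ``N <= n_cap`` so the hash table stays small.
    """
    N = reservoir.spec.N
    if N > n_cap:
        raise OracleScopeError(f"oracle limited to N <= {n_cap}, got N={N}")
    seen: dict[bytes, int] = {}
    x = np.asarray(init, dtype=np.uint8)
    t = 0
    while True:
        key = x.tobytes()
        if key in seen:
            first = seen[key]
            return first, t - first
        seen[key] = t
        x = step(reservoir, x)
        t += 1
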