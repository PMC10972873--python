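"""Order/disorder scoring of steady activity via BiEntropy.

The steady part of a mean-activity trace is mean-centred and clipped to a
bit string (strictly above the mean -> 1, else 0).  BiEntropy then scores
the string: 0 for perfectly periodic, approaching 1 for totally irregular.
It is the weighted average of the Shannon entropies of the string's
successive binary derivatives

    d_0 = the string,  d_{k+1} = XOR of adjacent bits of d_k,

with p_k the fraction of ones in d_k, H(p) the binary entropy, and

    H_b = sum_k w_k H(p_k) / sum_k w_k,     k = 0 .. n-2,

where w_k = 2^k ("power" variant) or w_k = log2(k + 2) ("logarithmic"
variant, appropriate for long strings where 2^k weights reduce to the last
derivative alone).

Ensembles of per-reservoir BiEntropies are summarised by their mean and
*population* variance (1/R normalisation); grid regions whose variance
exceeds a small threshold mark the order-disorder transition (critical
region) and, when a second disjoint region appears closer to perfect
balance, a re-entrance of criticality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .dynamics import ActivityTrace

__all__ = [
    "binarize_steady",
    "bientropy",
    "ensemble_entropy",
    "EntropyEnsemble",
    "VarianceRegions",
    "find_variance_regions",
]

VARIANCE_THRESHOLD = 1e-4  # default threshold defining the critical region


def binarize_steady(trace: ActivityTrace, t0: int = 1000) -> np.ndarray:
    """Binarize the steady window A(t0..D-1) about its mean.

    Bit t is 1 iff the activity lies *strictly* above the window mean;
    values equal to the mean map to 0, so a constant signal yields the
    all-zero string (BiEntropy 0, maximally ordered).  The result is
    invariant to adding any constant to the window.
    """
    if t0 >= trace.D:
        raise ValueError(f"t0={t0} beyond trace length {trace.D}")
    window = trace.counts[t0:]
    if window.size < 4:
        raise ValueError(f"steady window of length {window.size} < 4")
    return (window > window.mean()).astype(np.uint8)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0)


def bientropy(bits, variant: str = "power") -> float:
    """BiEntropy of a bit string, in [0, 1].

    Exactly 0 when every binary derivative is constant (e.g. all-zeros or
    all-ones strings).  The power variant weights
    derivative k by 2^k (computed in normalised form so arbitrary lengths
    do not overflow); the logarithmic variant by log2(k + 2).
    """
    b = np.asarray(bits)
    if b.size < 4:
        raise ValueError(f"bit string of length {b.size} < 4")
    if not np.isin(b, (0, 1)).all():
        raise ValueError("bit string must contain only 0s and 1s")
    b = b.astype(np.uint8)
    n = b.size
    p = np.empty(n - 1)
    d = b
    for k in range(n - 1):
        p[k] = d.mean()
        d = d[:-1] ^ d[1:]
    if variant == "power":
        # w_k = 2^k, rescaled by 2^(n-2) so the largest weight is 1
        k = np.arange(n - 1)
        w = np.exp2(k - (n - 2.0))
    elif variant == "logarithmic":
        w = np.log2(np.arange(n - 1) + 2.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(np.dot(w, _binary_entropy(p)) / w.sum())


def ensemble_entropy(values) -> tuple[float, float]:
    """Mean and population variance (1/R) of per-reservoir BiEntropies."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty BiEntropy ensemble")
    mean = float(v.mean())
    return mean, float(((v - mean) ** 2).mean())


@dataclass(frozen=True)
class EntropyEnsemble:
    """Per-grid-point BiEntropy ensemble over R reservoirs."""

    grid_point: tuple  # (N, K, sigma_star, b)
    values: np.ndarray
    mean: float
    variance: float
    R: int

    @classmethod
    def from_values(cls, grid_point, values) -> "EntropyEnsemble":
        v = np.asarray(values, dtype=float)
        mean, var = ensemble_entropy(v)
        return cls(grid_point=tuple(grid_point), values=v, mean=mean,
                   variance=var, R=v.size)


@dataclass(frozen=True)
class VarianceRegions:
    """Above-threshold variance intervals along a one-sign balance axis.

    ``intervals`` holds ``(start, stop, label)`` index triples (stop
    exclusive) into ``axis``; the run adjacent to the ordered phase (largest
    |b|, i.e. smallest |sigma_star|) is labelled ``"critical"``, any further
    disjoint run closer to b = 0 is labelled ``"re-entrant"``.
    """

    axis: np.ndarray
    variance: np.ndarray
    threshold: float
    intervals: tuple  # of (start, stop, label)


def find_variance_regions(
    axis_grid,
    variances,
    threshold: float = VARIANCE_THRESHOLD,
    axis: str = "sigma_star",
) -> VarianceRegions:
    """Extract maximal above-threshold runs of the ensemble variance.

    ``axis_grid`` is a one-sign grid, strictly monotone in magnitude, of
    ``sigma_star`` (ordered phase at *small* |sigma_star|) or ``b`` values
    (ordered phase at *large* |b|).  Grids may be supplied in either
    direction; internally they are oriented from the ordered phase toward
    perfect balance before labelling.
    """
    g = np.abs(np.asarray(axis_grid, dtype=float))
    v = np.asarray(variances, dtype=float)
    if g.size != v.size:
        raise ValueError("axis and variance grids differ in length")
    diffs = np.diff(g)
    if np.all(diffs > 0):
        ascending = True
    elif np.all(diffs < 0):
        ascending = False
    else:
        raise ValueError("axis grid must be strictly monotone in magnitude")
    if axis == "sigma_star":
        ordered_first = ascending
    elif axis == "b":
        ordered_first = not ascending
    else:
        raise ValueError(f"unknown axis kind {axis!r}")

    order = np.arange(g.size) if ordered_first else np.arange(g.size)[::-1]
    above = v[order] > threshold
    runs: list[tuple[int, int, str]] = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            label = "critical" if not runs else "re-entrant"
            lo, hi = order[i], order[j]
            runs.append((int(min(lo, hi)), int(max(lo, hi)) + 1, label))
            i = j + 1
        else:
            i += 1
    return VarianceRegions(
        axis=np.asarray(axis_grid, dtype=float),
        variance=v,
        threshold=threshold,
        intervals=tuple(runs),
    )
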