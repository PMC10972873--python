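"""Construction of random Boolean network (RBN) reservoirs.

A reservoir is a directed random graph on ``N`` binary threshold neurons in
which every neuron receives exactly ``K`` incoming synapses from distinct,
randomly chosen other neurons.  Synaptic weights are drawn from a normal law
``N(mu, sigma)`` with ``|mu| = 1`` fixed and ``sigma = |sigma_star|``, so the
single signed control parameter ``sigma_star = sigma / mu`` (the coefficient
of variation of the weight distribution) determines the excitatory-inhibitory
balance

    b = (S+ - S-) / S,

the normalised difference between the counts of positive and negative
synapses among the ``S = N * K`` total.  Because the update threshold is zero,
free-running dynamics are invariant to a positive rescaling of all weights;
only ``sigma_star``, ``K`` and ``N`` matter.

Half of the neurons (the first ``floor(N/2)`` ids) receive the scalar input
stream; the complementary half is exposed to the trained readout, so input
information must propagate through the recurrent graph before it can be
read out.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, ndtr, ndtri

__all__ = [
    "ReservoirSpec",
    "Reservoir",
    "BalanceSummary",
    "InfeasibleDegreeError",
    "build_reservoir",
    "build_zero_balance_reservoir",
    "balance_of_sigma_star",
    "balance_of_sigma_star_printed",
    "sigma_star_of_balance",
    "summarize_balance",
    "save_reservoir",
    "load_reservoir",
]

#: supported |sigma_star| sweep range; values outside merely warn
SIGMA_STAR_RANGE = (1e-2, 1e3)


class InfeasibleDegreeError(ValueError):
    """Raised when K distinct non-self sources cannot be chosen (K >= N)."""


@dataclass(frozen=True)
class ReservoirSpec:
    """Parameters fully determining one reservoir.

    Attributes
    ----------
    N : int
        Neuron count (>= 2).
    K : int
        Homogeneous in-degree, ``1 <= K <= N - 1``.
    sigma_star : float
        Signed coefficient of variation sigma/mu of the weight law; its sign
        is the sign of the mean weight (and hence of the balance ``b``).
    input_scale : float
        Magnitude of the nonzero entries of the input weight vector.
    seed : int
        RNG seed; construction is a pure function of the spec.
    """

    N: int
    K: int
    sigma_star: float
    input_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"need at least 2 neurons, got N={self.N}")
        if self.K < 1:
            raise ValueError(f"in-degree must be positive, got K={self.K}")
        if self.K > self.N - 1:
            raise InfeasibleDegreeError(
                f"cannot pick K={self.K} distinct non-self sources among "
                f"N-1={self.N - 1} other neurons"
            )
        if self.sigma_star == 0:
            raise ValueError("sigma_star must be nonzero")
        lo, hi = SIGMA_STAR_RANGE
        if not lo <= abs(self.sigma_star) <= hi:
            warnings.warn(
                f"|sigma_star|={abs(self.sigma_star):g} outside the supported "
                f"sweep range [{lo:g}, {hi:g}]",
                stacklevel=3,
            )
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")

    @property
    def density(self) -> float:
        """Connection density d = K/N."""
        return self.K / self.N


@dataclass
class Reservoir:
    """A realised reservoir: graph, weights, and the input/readout split.

    ``sources[i, :]`` are the K distinct presynaptic neuron ids of neuron
    ``i`` and ``weights[i, :]`` the matching synaptic weights, so the field
    on neuron i is ``sum_k weights[i, k] * x[sources[i, k]]``.
    """

    spec: ReservoirSpec
    sources: np.ndarray  # (N, K) int64
    weights: np.ndarray  # (N, K) float64

    @property
    def input_set(self) -> np.ndarray:
        """Ids of the floor(N/2) neurons receiving the input stream."""
        return np.arange(self.spec.N // 2)

    @property
    def readout_set(self) -> np.ndarray:
        """Ids of the ceil(N/2) neurons exposed to the readout."""
        return np.arange(self.spec.N // 2, self.spec.N)

    @property
    def n_input(self) -> int:
        return self.spec.N // 2

    def in_edges(self, i: int) -> list[tuple[int, float]]:
        """The (source id, weight) pairs feeding neuron ``i``."""
        return list(zip(self.sources[i].tolist(), self.weights[i].tolist()))


@dataclass(frozen=True)
class BalanceSummary:
    """Synapse-sign census of one reservoir against the analytic balance."""

    S: int
    S_plus: int
    S_minus: int
    b_empirical: float
    b_analytic: float


def balance_of_sigma_star(sigma_star):
    """Excitatory-inhibitory balance implied by the weight law at ``sigma_star``.

    A weight drawn from ``N(sign(s), |s|)`` is positive with probability
    ``Phi(1/|s|)`` when ``s > 0``, so the expected sign imbalance is

        b = sign(s) * (2 * Phi(1/|s|) - 1) = erf(1 / (sqrt(2) * s)).

    Odd in the sign of ``sigma_star``, strictly decreasing in its magnitude;
    ``|b| -> 1`` as ``|s| -> 0`` and ``b -> 0`` as ``|s| -> inf``.  Accepts
    scalars or arrays; zero anywhere raises.
    """
    s = np.asarray(sigma_star, dtype=float)
    if np.any(s == 0):
        raise ValueError("sigma_star must be nonzero")
    b = np.sign(s) * (2.0 * ndtr(1.0 / np.abs(s)) - 1.0)
    return float(b) if np.isscalar(sigma_star) else b


def balance_of_sigma_star_printed(sigma_star):
    """Alternative conversion ``b = erf(1 / (2 sigma_star))``.

    Provided for reference only: it is *not* the expected sign imbalance of
    the sampling process (that is :func:`balance_of_sigma_star`) and is not
    used anywhere in the analyses.
    """
    s = np.asarray(sigma_star, dtype=float)
    if np.any(s == 0):
        raise ValueError("sigma_star must be nonzero")
    b = erf(1.0 / (2.0 * s))
    return float(b) if np.isscalar(sigma_star) else b


def sigma_star_of_balance(b):
    """Inverse of :func:`balance_of_sigma_star` (b in (-1, 1), nonzero)."""
    barr = np.asarray(b, dtype=float)
    if np.any((barr <= -1) | (barr >= 1) | (barr == 0)):
        raise ValueError("balance must lie in (-1, 1) and be nonzero")
    s = np.sign(barr) / ndtri((np.abs(barr) + 1.0) / 2.0)
    return float(s) if np.isscalar(b) else s


def _sample_sources(rng: np.random.Generator, N: int, K: int) -> np.ndarray:
    """K distinct non-self sources per neuron, as an (N, K) int array.

    For small N (or K close to N) a per-row draw without replacement is used;
    otherwise vectorised rejection resampling of the offending rows, which
    converges in a handful of rounds when K << N.
    """
    if N < 64 or K > (N - 1) // 2:
        sources = np.empty((N, K), dtype=np.int64)
        for i in range(N):
            s = rng.choice(N - 1, size=K, replace=False)
            s[s >= i] += 1
            sources[i] = np.sort(s)
        return sources

    sources = rng.integers(0, N, size=(N, K), dtype=np.int64)
    row_ids = np.arange(N)[:, None]
    while True:
        srt = np.sort(sources, axis=1)
        bad = (sources == row_ids).any(axis=1) | (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        sources[idx] = rng.integers(0, N, size=(idx.size, K), dtype=np.int64)
    return np.sort(sources, axis=1)


def build_reservoir(spec: ReservoirSpec) -> Reservoir:
    """Construct the reservoir determined by ``spec``.

    Deterministic in ``spec`` (including its seed).  Draw order is fixed and
    documented: first the graph (all source sets), then all weights in one
    ``(N, K)`` block, so that the topology for a given seed is independent of
    ``sigma_star``.
    """
    rng = np.random.default_rng(spec.seed)
    sources = _sample_sources(rng, spec.N, spec.K)
    mu = 1.0 if spec.sigma_star > 0 else -1.0
    weights = rng.normal(loc=mu, scale=abs(spec.sigma_star), size=(spec.N, spec.K))
    return Reservoir(spec=spec, sources=sources, weights=weights)


def build_zero_balance_reservoir(spec: ReservoirSpec) -> Reservoir:
    """Reservoir with *exactly* equal excitatory and inhibitory synapse counts.

    Finite ``sigma_star`` sampling can never reach ``b = 0`` exactly; this
    probe assigns signs to the sampled weight magnitudes in exactly equal
    counts (random placement), for use in symmetry-dip experiments.  Requires
    ``S = N * K`` even.
    """
    S = spec.N * spec.K
    if S % 2:
        raise ValueError("exact zero balance needs an even synapse count N*K")
    rng = np.random.default_rng(spec.seed)
    sources = _sample_sources(rng, spec.N, spec.K)
    mu = 1.0 if spec.sigma_star > 0 else -1.0
    magnitudes = np.abs(rng.normal(loc=mu, scale=abs(spec.sigma_star), size=S))
    signs = np.ones(S)
    signs[: S // 2] = -1.0
    rng.shuffle(signs)
    weights = (magnitudes * signs).reshape(spec.N, spec.K)
    return Reservoir(spec=spec, sources=sources, weights=weights)


def summarize_balance(reservoir: Reservoir) -> BalanceSummary:
    """Count positive/negative synapses and compare with the analytic balance.

    Exactly-zero weights (probability zero under the continuous law, possible
    in contrived inputs) count in S but in neither S+ nor S-.
    """
    w = reservoir.weights
    S = w.size
    S_plus = int((w > 0).sum())
    S_minus = int((w < 0).sum())
    return BalanceSummary(
        S=S,
        S_plus=S_plus,
        S_minus=S_minus,
        b_empirical=(S_plus - S_minus) / S,
        b_analytic=balance_of_sigma_star(reservoir.spec.sigma_star),
    )


def save_reservoir(reservoir: Reservoir, prefix) -> None:
    """Serialise to ``<prefix>.json`` (header) + ``<prefix>.edges.csv``.

    The edge table has columns (target, source, weight) with weights printed
    at full round-trip precision, so :func:`load_reservoir` is bit-exact.
    """
    prefix = str(prefix)
    spec = reservoir.spec
    header = {
        "N": spec.N,
        "K": spec.K,
        "sigma_star": spec.sigma_star,
        "input_scale": spec.input_scale,
        "seed": spec.seed,
        "n_edges": int(reservoir.weights.size),
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(header, fh, indent=1)
    N, K = reservoir.sources.shape
    targets = np.repeat(np.arange(N), K)
    with open(prefix + ".edges.csv", "w") as fh:
        fh.write("target,source,weight\n")
        for t, s, w in zip(targets, reservoir.sources.ravel(), reservoir.weights.ravel()):
            fh.write(f"{t},{s},{float(w)!r}\n")


def load_reservoir(prefix) -> Reservoir:
    """Inverse of :func:`save_reservoir`."""
    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        header = json.load(fh)
    spec = ReservoirSpec(
        N=header["N"],
        K=header["K"],
        sigma_star=header["sigma_star"],
        input_scale=header["input_scale"],
        seed=header["seed"],
    )
    data = np.genfromtxt(
        prefix + ".edges.csv", delimiter=",", skip_header=1, dtype=float
    ).reshape(-1, 3)
    sources = data[:, 1].astype(np.int64).reshape(spec.N, spec.K)
    weights = data[:, 2].reshape(spec.N, spec.K)
    return Reservoir(spec=spec, sources=sources, weights=weights)
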