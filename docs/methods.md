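# Methods

## Model

The reservoir is a random Boolean network of `N` zero-threshold Heaviside
neurons updated synchronously:

    x_i(t) = theta( u_i(t) + sum_j w_ij x_j(t-1) ),    theta(z) = 1 iff z > 0.

Each neuron receives exactly `K` recurrent synapses from distinct,
uniformly chosen other neurons (no self-loops, no multi-edges).  Weights
are i.i.d. normal `N(mu, sigma)` with `|mu| = 1` fixed and
`sigma = |sigma_star|`; the single signed control parameter
`sigma_star = sigma/mu` carries the sign of the mean.  Because the
threshold is zero, free-running trajectories are invariant under any
positive rescaling of all weights, so only the *ratio* `sigma_star`
matters — fixing `|mu| = 1` is a normalisation, not an assumption.

A scalar input stream `u(t)` is injected into the first `floor(N/2)`
neurons with weight `input_scale` (default 1); the complementary half
feeds the readout

    y(t) = sigmoid( W_out . x_readout(t) + c ),

the only trained component.  Input information must therefore traverse the
recurrent graph before it is readable.

## The balance b

The excitatory–inhibitory balance is the normalised sign census of the
`S = N K` synapses, `b = (S+ - S-)/S`.  Under the weight law a synapse is
positive with probability `Phi(1/|sigma_star|)` (sign of `sigma_star`
attached), so

    b = sign(sigma_star) * (2 Phi(1/|sigma_star|) - 1)
      = erf( 1 / (sqrt(2) sigma_star) ).

This is the expected sign imbalance of the actual sampling process; it is
odd in `sigma_star`, saturates at ±1 as `|sigma_star| -> 0`, and vanishes
as `|sigma_star| -> inf`.  It reproduces the anchor `sigma_star = -10 <->
b ≈ -0.08`.  An alternative conversion `erf(1/(2 sigma_star))` circulates
in the literature on this model; it is inconsistent with the sampling
process (it implies, e.g., `-10 -> -0.056`) and is provided in the API
only as `balance_of_sigma_star_printed`, unused in any analysis here.

Because finite `sigma_star` can never produce `b = 0` exactly, the
symmetry-dip probe constructs it directly: weight magnitudes are sampled
as usual and signs are assigned in exactly equal counts at random
positions (`build_zero_balance_reservoir`, requiring `S` even).

## Free-run protocol and order metrics

Each reservoir runs without input for `D = 2000` steps from a random state
with exactly `round(0.2 N)` active neurons.  The mean activity
`A(t) = (1/N) sum_i x_i(t)` is recorded as integer active counts, so all
downstream equality tests are exact.  The steady window is `t > 1000`.

**BiEntropy.** The steady window is mean-centred and clipped to bits
(strictly above the mean -> 1; ties -> 0, so constant signals give the
all-zero, maximally ordered string).  BiEntropy is the weighted mean of
the Shannon entropies of the successive binary derivatives of the string,
with weights `2^k` (power variant) or `log2(k+2)` (logarithmic variant).
The logarithmic variant is the sweep default: for 1000-bit windows the
power variant puts half its weight on the 2-bit final derivative, whose
entropy vanishes with probability 1/2 on irregular strings, capping its
score near 0.63 where the logarithmic variant reaches ~0.99.  The power
variant remains selectable and is the reference for the short golden
strings (`0101 -> 1/7`, `1011 -> 0.94970`).

**Ensembles.** Per grid point `(N, K, sigma_star)`, `R` independent
reservoirs are run once each; the ensemble mean and *population* variance
(`1/R` normalisation) of the per-run BiEntropies are recorded.  Regions of
the one-sign balance axis where the variance exceeds `1e-4` mark the
order–disorder transition; the run adjacent to the ordered phase is
labelled *critical*, any further disjoint run closer to `b = 0`
*re-entrant*.

**Attractor taxonomy.** The steady window is classified in precedence
order: *extinguished* (exactly zero throughout — the all-zero state is
absorbing under `theta(0) = 0`), *fixed* (constant nonzero), *cyclic*
(minimal exact period `p` in `[2, floor(L/2)]`; a period must be observed
at least twice), else *irregular*.  The dynamics are deterministic and
finite, so every orbit is eventually periodic with period up to `2^N`;
"irregular" operationally means "period unresolvable in a 1000-step
window".  For `N <= 12` an exhaustive first-recurrence oracle over full
states provides the exact transient and period, against which the window
classifier is validated (extinguished ⇔ all-zero cycle; cyclic ⇒ activity
period divides state period; irregular impossible when the window covers
two full state periods).

## Tasks and readout training

**Memory.** Input is i.i.d. uniform noise on [0, 1); the target is the
input delayed by `|delta|`, `delta` in {-2, ..., -18}.  Uniform noise is
used because the sigmoid readout's codomain is (0, 1); Pearson correlation
is affine-invariant, so the choice of amplitude is immaterial to scores.

**Prediction.** Input is the discrete Mackey–Glass map
`x_{t+1} = a x_t + b x_{t-tau} / (c + x_{t-tau}^d)` with
`a=0.9, b=0.2, c=0.9, d=10, x0=0.1` and constant pre-history; the target
is the input 10 steps ahead.  `tau = 5` yields a smooth quasi-periodic
orbit (the best lag reproduces the steady window to ~0.003 but never
exactly — the orbit lives on an invariant circle, so exact-period
detection on the quantized series fails by construction), `tau = 28` a
chaotic one (no near-recurrence below ~0.15 at any lag up to 100).  Orbits
are min–max normalised to [0, 1].

Series carry a washout (default 100 steps) plus the alignment margin
(`|delta|` or the 10-step horizon) excluded from fitting; the test range
is a fixed-length tail, the train range everything in between.  Defaults:
2600 generated steps, 500 test points.

**Training.** Full-batch gradient descent on the MSE with the ADAM update
(`alpha = 0.001`, 4000 epochs, `beta = (0.9, 0.999)`, `eps = 1e-8`),
implemented directly in numpy; weights initialise from a centred normal
scaled by `1/sqrt(M)` over the `M` readout neurons, bias at zero, all
seeded.  Performance is the Pearson correlation between the sigmoid output
and the target on the held-out test range only.  A reservoir whose readout
rows are constant (e.g. extinguished dynamics) has an undefined
correlation; such runs are scored 0, the "carries no information" value.

## Sweeps, seeding, reproducibility

Grids are log-spaced in `|sigma_star|` over `[1e-2, 1e3]` per sign
(default 16 points).  All reservoir, initial-state and training seeds are
derived from `(base_seed, domain, grid coordinates, replicate)` via
`numpy.random.SeedSequence`, making every sweep a pure function of its
configuration.  With an output directory, each grid point's raw records
are checkpointed to a CSV shard and finished shards are skipped on re-run,
so interrupted sweeps resume to identical tables.

**Transition refinement.** An abrupt transition can fall entirely between
two log-spaced grid points: at `N = 1000, K = 16, b < 0` the
ordered-to-chaotic mixture band spans only `sigma_star` in roughly
`[-0.75, -0.6]`, narrower than the factor-2.15 spacing of a 16-point grid.
The dynamics sweep therefore supports `refine_transitions = m`: per
`(N, K, sign)` row it unconditionally adds `m` extra grid points, each at
the geometric midpoint of the adjacent pair with the largest jump in
ensemble-mean BiEntropy.  Refinement is deterministic and not conditioned
on any observed variance value.

## Desk-scale presets

The full protocol (N up to 10,000; R = 100 dynamics ensembles; 20-seed
training sweeps over five delays, three taus and dozens of grid points)
costs many CPU-hours; `full_scale_config()` builds it, but the shipped
analyses and tests use scaled-down presets:

- **fig3-mini** — dynamics, `N=1000`, `K in {16, 1}`, `b < 0`, 16-point
  grid + 4 refinement points, `R = 30`.
- **fig4-mini** — attractor statistics, `N=1000`, `K=8`, both signs,
  12 points, `R = 20`.
- **fig5-mini** — memory task, `N=1000`, `K=4` at `b = +0.1`
  (`sigma_star ≈ 8.0`, on the K=4 high-performance plateau), `R = 10`,
  series of 1620 steps (washout 100, ~1200 training pairs, 300 test),
  1500 ADAM epochs.
- **fig7-mini** — best-K summary, `K in {1, 2, 3, 4, 8, 16}`, `b > 0`,
  coarse 5-point grid, `R = 5`, delays {-2, -18}.

These sizes preserve the qualitative structure (phase transition, K=1
orderliness, difficulty ordering, the b=0 dip) at minutes of compute; they
do not reproduce full-scale figure values, and quantities that require
`N = 10,000` self-averaging (e.g. the precise `b_opt ≈ 0.2` for `K = 16`)
are out of reach of the presets.

## Known limitations

- The b = 0 symmetry-dip control is evaluated at the hardest delay
  (`delta = -18`), the setting at which `b_opt` is defined.  At very short
  delays a desk-scale `N = 1000` network at exact balance retains residual
  correlation (~0.15 at `delta = -2`): a handful of neurons whose
  recurrent field straddles the threshold transmit the instantaneous
  input even when excitation and inhibition cancel in count.
- Attractor labels depend on the window convention: periods above
  `floor(L/2)` are reported irregular, and exact-count comparison means a
  single active neuron's difference breaks a period.
- The synthetic tasks probe memory and prediction of scalar streams only;
  nothing here speaks to classification tasks or structured topologies
  (scale-free, small-world), which are outside the model family.
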