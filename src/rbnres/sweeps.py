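"""Parameter-sweep orchestration.

Drives the full experimental protocol over grids of (N, K, sigma_star):

* **dynamics sweeps** — for each grid point, an ensemble of R free-running
  reservoirs; per run the steady activity is binarized, BiEntropy-scored and
  attractor-classified; ensembles are summarised by mean/variance BiEntropy
  (population normalisation) and category percentages, and above-threshold
  variance regions (critical / re-entrant) are extracted per (N, K, sign).
* **task sweeps** — for each grid point and task difficulty, R reservoirs
  are driven, a sigmoid readout trained per reservoir, and the held-out
  Pearson correlation aggregated to mean +/- sd.
* **b_opt selection** — per (N, K, sign, task), the grid point maximising
  mean correlation at the hardest difficulty (delta = -18 for memory,
  tau = 28 for prediction), with ties broken toward smaller |b|; the best-K
  summary reports performance at b_opt for every difficulty.

Every reservoir seed is derived deterministically from (base seed, domain,
grid coordinates, replicate index) through ``numpy.random.SeedSequence``, so
sweeps are exactly reproducible and resumable: with an output directory,
each grid point's raw records are checkpointed to a CSV shard and finished
shards are skipped on re-run.

Scaled-down presets (``fig3-mini``, ``fig4-mini``, ``fig5-mini``,
``fig7-mini``) encode desk-scale versions of the full protocol;
``full_scale_config`` builds the full-size grids (hours of compute).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attractors import CATEGORIES, classify_attractor
from .dynamics import driven_run, free_run
from .entropy import (
    VARIANCE_THRESHOLD,
    bientropy,
    binarize_steady,
    ensemble_entropy,
    find_variance_regions,
)
from .network import (
    ReservoirSpec,
    balance_of_sigma_star,
    build_reservoir,
    build_zero_balance_reservoir,
    sigma_star_of_balance,
)
from .readout import TrainConfig, run_task_on_reservoir
from .tasks import make_memory_task, make_prediction_task

__all__ = [
    "SweepConfig",
    "CoverageError",
    "sigma_grid",
    "derive_seeds",
    "run_dynamics_sweep",
    "run_task_sweep",
    "run_zero_balance_probe",
    "variance_regions_from_summary",
    "select_b_opt",
    "summarize_best_K",
    "preset",
    "full_scale_config",
    "PRESETS",
]

HARDEST = {"memory": -18, "prediction": 28}

# seed-derivation domains, so dynamics/task/probe streams never collide
_DOM_DYNAMICS = 1
_DOM_TASK = 2
_DOM_ZERO_B = 3
_DOM_INPUT = 4


class CoverageError(ValueError):
    """Raised when a selection needs grid rows that the table lacks."""


@dataclass(frozen=True)
class SweepConfig:
    """Grids, ensemble sizes and protocol constants of one sweep."""

    N_list: tuple = (100, 1000, 10000)
    K_list: tuple = (1, 2, 3, 4, 8, 16)
    signs: tuple = (-1, 1)
    sigma_points: int = 16          # log-spaced |sigma_star| magnitudes per sign
    sigma_range: tuple = (1e-2, 1e3)
    R_dynamics: int = 100
    R_task: int = 20
    D: int = 2000                   # free-run duration
    t0: int = 1000                  # steady-window start
    active_fraction: float = 0.2
    bientropy_variant: str = "logarithmic"
    variance_threshold: float = VARIANCE_THRESHOLD
    deltas: tuple = (-2, -6, -10, -14, -18)
    taus: tuple = (5, 15, 28)
    task_length: int = 2600
    washout: int = 100
    n_test: int = 500
    epochs: int = 4000
    learning_rate: float = 0.001
    input_scale: float = 1.0
    base_seed: int = 0
    refine_transitions: int = 0     # extra bisection points per (N, K, sign) row

    def __post_init__(self) -> None:
        if not (self.N_list and self.K_list and self.signs):
            raise ValueError("grids must be nonempty")
        if self.sigma_points < 1:
            raise ValueError("need at least one sigma_star point")
        if self.R_dynamics < 1 or self.R_task < 1:
            raise ValueError("ensemble sizes must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        for key in ("N_list", "K_list", "signs", "sigma_range", "deltas", "taus"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SweepConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs, seed=seed
        )


def sigma_grid(cfg: SweepConfig, sign: int) -> np.ndarray:
    """Signed, log-spaced sigma_star magnitudes for one sign (ascending |.|)."""
    lo, hi = cfg.sigma_range
    mags = np.logspace(np.log10(lo), np.log10(hi), cfg.sigma_points)
    return sign * mags


def derive_seeds(base_seed: int, *key: int, n: int = 2) -> tuple[int, ...]:
    """Deterministic child seeds (< 2^31) for a sweep coordinate."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) & 0xFFFFFFFF for k in key]])
    return tuple(int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64))


def _shard_path(out_dir, kind: str, tag: str) -> Path | None:
    if out_dir is None:
        return None
    p = Path(out_dir) / kind
    p.mkdir(parents=True, exist_ok=True)
    return p / f"{tag}.csv"


def _dynamics_grid_point(cfg, N, K, s_idx, g_key, sigma, out_dir) -> pd.DataFrame:
    """One checkpointed ensemble of R_dynamics free runs at a grid point."""
    tag = f"N{N}_K{K}_s{s_idx}_g{g_key}"
    path = _shard_path(out_dir, "dynamics", tag)
    if path is not None and path.exists():
        return pd.read_csv(path)
    rows = []
    b = balance_of_sigma_star(sigma)
    for r in range(cfg.R_dynamics):
        res_seed, init_seed = derive_seeds(
            cfg.base_seed, _DOM_DYNAMICS, N, K, s_idx, g_key, r
        )
        spec = ReservoirSpec(
            N=N, K=K, sigma_star=float(sigma),
            input_scale=cfg.input_scale, seed=res_seed,
        )
        reservoir = build_reservoir(spec)
        _, trace = free_run(
            reservoir, D=cfg.D, active_fraction=cfg.active_fraction, seed=init_seed
        )
        bits = binarize_steady(trace, t0=cfg.t0)
        h = bientropy(bits, variant=cfg.bientropy_variant)
        label = classify_attractor(trace, t0=cfg.t0)
        rows.append(
            dict(N=N, K=K, sigma_star=float(sigma), b=b, r=r, H_b=h,
                 category=label.category, period=label.period if label.period else 0)
        )
    shard = pd.DataFrame(rows)
    if path is not None:
        shard.to_csv(path, index=False)
    return shard


def run_dynamics_sweep(cfg: SweepConfig, out_dir=None):
    """Free-run ensembles over the whole (N, K, sign, sigma_star) grid.

    Returns ``(records, summary)``: raw per-run rows
    (N, K, sigma_star, b, r, H_b, category, period) and per-grid-point
    aggregates (mean/var BiEntropy, category percentages).  With ``out_dir``
    the raw rows are checkpointed per grid point and finished shards are
    skipped when the sweep is re-run.

    With ``cfg.refine_transitions > 0`` each (N, K, sign) row additionally
    receives that many bisection points: an abrupt order-disorder transition
    can fall entirely between two log-spaced grid points, so the adjacent
    pair with the largest jump in ensemble-mean BiEntropy is repeatedly
    split at its geometric midpoint.  Refinement is unconditional (always
    the stated number of extra points) and deterministic.
    """
    shards = []
    for N in cfg.N_list:
        for K in cfg.K_list:
            for s_idx, sign in enumerate(cfg.signs):
                grid = list(sigma_grid(cfg, sign))
                row_shards = [
                    _dynamics_grid_point(cfg, N, K, s_idx, g_idx, sigma, out_dir)
                    for g_idx, sigma in enumerate(grid)
                ]
                means = [float(sh["H_b"].mean()) for sh in row_shards]
                for it in range(cfg.refine_transitions):
                    jumps = np.abs(np.diff(means))
                    j = int(np.argmax(jumps))
                    mid = sign * float(
                        np.sqrt(abs(grid[j]) * abs(grid[j + 1]))
                    )
                    shard = _dynamics_grid_point(
                        cfg, N, K, s_idx, 1000 + it, mid, out_dir
                    )
                    grid.insert(j + 1, mid)
                    row_shards.insert(j + 1, shard)
                    means.insert(j + 1, float(shard["H_b"].mean()))
                shards.extend(row_shards)
    records = pd.concat(shards, ignore_index=True)
    summary = summarize_dynamics(records)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "dynamics_summary.csv", index=False)
    return records, summary


def summarize_dynamics(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate raw dynamics rows to per-grid-point ensemble statistics."""
    out = []
    for (N, K, sigma), grp in records.groupby(["N", "K", "sigma_star"], sort=False):
        mean, var = ensemble_entropy(grp["H_b"].to_numpy())
        row = dict(
            N=int(N), K=int(K), sigma_star=float(sigma),
            b=float(grp["b"].iloc[0]), R=len(grp),
            mean_Hb=mean, var_Hb=var,
        )
        for cat in CATEGORIES:
            row[f"pct_{cat}"] = 100.0 * float((grp["category"] == cat).mean())
        out.append(row)
    return pd.DataFrame(out)


def variance_regions_from_summary(
    summary: pd.DataFrame, N: int, K: int, sign: int, threshold: float | None = None
):
    """Critical / re-entrant variance regions for one (N, K, sign) row set."""
    sel = summary[
        (summary["N"] == N) & (summary["K"] == K)
        & (np.sign(summary["sigma_star"]) == sign)
    ].sort_values("sigma_star", key=np.abs)
    if sel.empty:
        raise CoverageError(f"no dynamics rows for N={N}, K={K}, sign={sign}")
    return find_variance_regions(
        sel["sigma_star"].to_numpy(),
        sel["var_Hb"].to_numpy(),
        threshold=VARIANCE_THRESHOLD if threshold is None else threshold,
        axis="sigma_star",
    )


def _task_factory(kind: str, difficulty: int, cfg: SweepConfig, input_seed: int):
    if kind == "memory":
        return make_memory_task(
            difficulty, length=cfg.task_length, washout=cfg.washout,
            n_test=cfg.n_test, seed=input_seed,
        )
    return make_prediction_task(
        difficulty, length=cfg.task_length, washout=cfg.washout, n_test=cfg.n_test
    )


def run_task_sweep(cfg: SweepConfig, out_dir=None, tasks: tuple = ("memory", "prediction")):
    """Train-and-score ensembles over the grid for the configured tasks.

    All memory difficulties share one white-noise input per sweep, so each
    reservoir is driven once and re-fitted per delay; prediction inputs
    differ per tau.  Returns ``(records, summary)`` with per-record rows and
    per (grid point, task, difficulty) mean/sd aggregates.  An empty task
    roster yields empty tables.
    """
    (input_seed,) = derive_seeds(cfg.base_seed, _DOM_INPUT, n=1)
    roster: list[tuple[str, tuple]] = []
    if "memory" in tasks and cfg.deltas:
        roster.append(("memory", tuple(cfg.deltas)))
    if "prediction" in tasks and cfg.taus:
        roster.append(("prediction", tuple(cfg.taus)))

    shards = []
    for N in cfg.N_list:
        for K in cfg.K_list:
            for s_idx, sign in enumerate(cfg.signs):
                for g_idx, sigma in enumerate(sigma_grid(cfg, sign)):
                    for kind, diffs in roster:
                        tag = f"{kind}_N{N}_K{K}_s{s_idx}_g{g_idx}"
                        path = _shard_path(out_dir, "tasks", tag)
                        if path is not None and path.exists():
                            shards.append(pd.read_csv(path))
                            continue
                        task_set = {
                            d: _task_factory(kind, d, cfg, input_seed) for d in diffs
                        }
                        rows = []
                        for r in range(cfg.R_task):
                            res_seed, init_seed, fit_seed = derive_seeds(
                                cfg.base_seed, _DOM_TASK, N, K, s_idx, g_idx, r, n=3
                            )
                            spec = ReservoirSpec(
                                N=N, K=K, sigma_star=float(sigma),
                                input_scale=cfg.input_scale, seed=res_seed,
                            )
                            reservoir = build_reservoir(spec)
                            shared_states = None
                            for d, task in task_set.items():
                                if kind == "memory":
                                    if shared_states is None:
                                        shared_states, _ = driven_run(
                                            reservoir, task.input,
                                            active_fraction=cfg.active_fraction,
                                            seed=init_seed,
                                        )
                                    states = shared_states
                                else:
                                    states, _ = driven_run(
                                        reservoir, task.input,
                                        active_fraction=cfg.active_fraction,
                                        seed=init_seed,
                                    )
                                rec = run_task_on_reservoir(
                                    reservoir, task, cfg.train_config(seed=fit_seed),
                                    readout_states=states,
                                )
                                rows.append(dataclasses.asdict(rec))
                        shard = pd.DataFrame(rows)
                        if path is not None:
                            shard.to_csv(path, index=False)
                        shards.append(shard)
    if not shards:
        empty_cols = ["N", "K", "sigma_star", "b", "task", "difficulty",
                      "seed", "correlation", "final_loss", "initial_loss"]
        records = pd.DataFrame(columns=empty_cols)
        return records, summarize_performance(records)
    records = pd.concat(shards, ignore_index=True)
    summary = summarize_performance(records)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "task_summary.csv", index=False)
    return records, summary


def summarize_performance(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and population sd of Corr(y, T) per grid point x task."""
    cols = ["N", "K", "sigma_star", "b", "task", "difficulty",
            "mean_corr", "sd_corr", "R"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    out = []
    keys = ["N", "K", "sigma_star", "task", "difficulty"]
    for key, grp in records.groupby(keys, sort=False):
        c = grp["correlation"].to_numpy()
        out.append(dict(
            N=int(key[0]), K=int(key[1]), sigma_star=float(key[2]),
            b=float(grp["b"].iloc[0]), task=key[3], difficulty=int(key[4]),
            mean_corr=float(c.mean()), sd_corr=float(c.std()), R=len(c),
        ))
    return pd.DataFrame(out, columns=cols)


def run_zero_balance_probe(
    cfg: SweepConfig, N: int, K: int, kind: str, difficulty: int,
    magnitude_sigma: float = 1e3,
) -> pd.DataFrame:
    """Task records for reservoirs with *exactly* b = 0.

    Finite sigma_star cannot reach perfect balance; these reservoirs assign
    signs to sampled weight magnitudes in exactly equal counts, probing the
    symmetry dip at b = 0.
    """
    (input_seed,) = derive_seeds(cfg.base_seed, _DOM_INPUT, n=1)
    task = _task_factory(kind, difficulty, cfg, input_seed)
    rows = []
    for r in range(cfg.R_task):
        res_seed, init_seed, fit_seed = derive_seeds(
            cfg.base_seed, _DOM_ZERO_B, N, K, r, n=3
        )
        spec = ReservoirSpec(
            N=N, K=K, sigma_star=magnitude_sigma,
            input_scale=cfg.input_scale, seed=res_seed,
        )
        reservoir = build_zero_balance_reservoir(spec)
        states, _ = driven_run(
            reservoir, task.input, active_fraction=cfg.active_fraction, seed=init_seed
        )
        rec = run_task_on_reservoir(
            reservoir, task, cfg.train_config(seed=fit_seed),
            readout_states=states, b=0.0,
        )
        rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows)


def select_b_opt(
    summary: pd.DataFrame, N: int, K: int, sign: int, task: str
) -> tuple[float, float]:
    """(b_opt, sigma_star_opt) maximising mean correlation at the hardest
    difficulty for one (N, K, sign, task); ties go to smaller |b|."""
    hardest = HARDEST[task]
    sel = summary[
        (summary["N"] == N) & (summary["K"] == K) & (summary["task"] == task)
        & (summary["difficulty"] == hardest)
        & (np.sign(summary["sigma_star"]) == sign)
    ]
    if sel.empty:
        raise CoverageError(
            f"no rows at hardest difficulty {hardest} for "
            f"(N={N}, K={K}, sign={sign}, task={task})"
        )
    best = sel.sort_values(
        ["mean_corr", "b"],
        ascending=[False, True],
        key=lambda s: np.abs(s) if s.name == "b" else s,
    ).iloc[0]
    return float(best["b"]), float(best["sigma_star"])


def summarize_best_K(summary: pd.DataFrame) -> pd.DataFrame:
    """Performance at b_opt for every (K, sign, task, difficulty) present."""
    out = []
    for (N, K, task), grp in summary.groupby(["N", "K", "task"], sort=False):
        for sign in (-1, 1):
            if not (np.sign(grp["sigma_star"]) == sign).any():
                continue
            b_opt, sigma_opt = select_b_opt(summary, int(N), int(K), sign, task)
            at_opt = grp[grp["sigma_star"] == sigma_opt]
            for _, row in at_opt.iterrows():
                out.append(dict(
                    N=int(N), K=int(K), sign=sign, task=task,
                    difficulty=int(row["difficulty"]), b_opt=b_opt,
                    sigma_star_opt=sigma_opt,
                    mean_corr=float(row["mean_corr"]),
                    sd_corr=float(row["sd_corr"]),
                ))
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# scaled-down presets

def _fig3_mini(base_seed: int) -> SweepConfig:
    """Order-disorder map, negative balance: N=1000, K in {1, 16}, R=30,
    with 4 bisection points to resolve the abrupt K=16 transition."""
    return SweepConfig(
        N_list=(1000,), K_list=(16, 1), signs=(-1,), sigma_points=16,
        R_dynamics=30, refine_transitions=4, base_seed=base_seed,
    )


def _fig4_mini(base_seed: int) -> SweepConfig:
    """Attractor statistics vs b at K=8, both signs, reduced ensemble."""
    return SweepConfig(
        N_list=(1000,), K_list=(8,), signs=(-1, 1), sigma_points=12,
        R_dynamics=20, base_seed=base_seed,
    )


def _fig5_mini(base_seed: int) -> SweepConfig:
    """Memory-task curve at the K=4 near-balanced operating point.

    Desk-scale protocol: N=1000, b = +0.1 (sigma_star ~ 8.9, on the K=4
    high-performance plateau), 10 reservoirs per delay, shortened series
    (washout 100, train 1202-1218 pairs, test 300) and 1500 ADAM epochs.
    """
    return SweepConfig(
        N_list=(1000,), K_list=(4,), signs=(1,), sigma_points=1,
        sigma_range=(abs(sigma_star_of_balance(0.1)),) * 2,
        R_task=10, task_length=1620, washout=100, n_test=300,
        epochs=1500, base_seed=base_seed,
    )


def _fig7_mini(base_seed: int) -> SweepConfig:
    """Best-K summary, memory task: coarse b grid, K in {1..16} subset."""
    return SweepConfig(
        N_list=(1000,), K_list=(1, 2, 3, 4, 8, 16), signs=(1,),
        sigma_points=5, sigma_range=(1e-1, 1e2),
        R_task=5, deltas=(-2, -18), taus=(),
        task_length=1620, washout=100, n_test=300, epochs=1500,
        base_seed=base_seed,
    )


PRESETS = {
    "fig3-mini": _fig3_mini,
    "fig4-mini": _fig4_mini,
    "fig5-mini": _fig5_mini,
    "fig7-mini": _fig7_mini,
}


def preset(name: str, base_seed: int = 0) -> SweepConfig:
    """A named scaled-down sweep configuration."""
    try:
        return PRESETS[name](base_seed)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


def full_scale_config(base_seed: int = 0) -> SweepConfig:
    """The full-size protocol grids (hours of compute; opt-in only)."""
    return SweepConfig(base_seed=base_seed)


def save_manifest(cfg: SweepConfig, out_dir) -> None:
    """Record the exact configuration next to a sweep's outputs."""
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1)
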