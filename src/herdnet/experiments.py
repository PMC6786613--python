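"""Batch replication, the factorial parameter sweeps, and the
capacity-shift experiment.

The headline experimental battery runs the full model 100 times at every
combination of carrying capacity {5,000..50,000 step 5,000} and disaster
frequency {5,10,15,20}% (5,000 runs); the inequality baseline repeats the
grid with networks and deaths disabled; the sensitivity-analysis sweep uses
disaster frequencies {1,5,10,15}% (4,000 runs). Per-combination seeds are
derived from (base seed, capacity, frequency) so replicates are reproducible
and independent of execution order, and identical combinations share seeds
across experiments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import RunResult, init_world, run_simulation, step_world, _finalize
from .params import SimParams, inequality_variant

DEFAULT_CAPACITIES: tuple[int, ...] = tuple(range(5_000, 50_001, 5_000))
DEFAULT_PROBS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
REGRESSION_PROBS: tuple[float, ...] = (0.01, 0.05, 0.10, 0.15)

RUN_COLUMNS = [
    "carrying_capacity",
    "disaster_prob",
    "replicate",
    "seed",
    "final_gini",
    "largest_network_size",
    "largest_network_duration",
    "end_population",
]

__all__ = [
    "DEFAULT_CAPACITIES",
    "DEFAULT_PROBS",
    "REGRESSION_PROBS",
    "RUN_COLUMNS",
    "derive_run_seeds",
    "run_batch",
    "sweep",
    "gini_sweep",
    "aggregate_sweep",
    "CapacityShiftResult",
    "capacity_shift_run",
    "capacity_shift_batch",
]


def derive_run_seeds(entropy, n_runs: int) -> list[int]:
    """Derive ``n_runs`` independent 32-bit run seeds from an entropy key
    (an int, or a sequence of ints such as (base_seed, capacity, ...))."""
    ss = np.random.SeedSequence(entropy)
    return [int(s) for s in ss.generate_state(n_runs, np.uint32)]


def _combo_entropy(base_seed: int, capacity: float, prob: float) -> list[int]:
    # an unbounded capacity gets a sentinel entropy word
    cap_word = int(round(capacity)) if np.isfinite(capacity) else 2**48
    return [int(base_seed), cap_word, int(round(prob * 1_000_000))]


def _result_row(
    result: RunResult, capacity: float, prob: float, replicate: int
) -> dict:
    return {
        "carrying_capacity": capacity,
        "disaster_prob": prob,
        "replicate": replicate,
        "seed": result.seed,
        "final_gini": result.final_gini,
        "largest_network_size": result.largest_network_size,
        "largest_network_duration": result.largest_network_duration,
        "end_population": result.end_population,
    }


def run_batch(
    params: SimParams, n_runs: int, base_seed: int
) -> list[RunResult]:
    """``n_runs`` independent replicates of ``params``.

    Run *i* uses the *i*-th derived seed, so replicates are reproducible
    from ``base_seed`` alone and independent of execution order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = derive_run_seeds(
        _combo_entropy(base_seed, params.carrying_capacity, params.disaster_prob),
        n_runs,
    )
    return [run_simulation(params, seed=s) for s in seeds]


def sweep(
    capacities: Sequence[float] = DEFAULT_CAPACITIES,
    probs: Sequence[float] = DEFAULT_PROBS,
    n_runs: int = 100,
    base_seed: int = 0,
    params: SimParams | None = None,
) -> pd.DataFrame:
    """Full-factorial sweep over carrying capacity and disaster frequency.

    Returns one row per (combination, replicate) with the per-run dependent
    variables (columns ``RUN_COLUMNS``).
    """
    if len(capacities) == 0 or len(probs) == 0:
        raise ValueError("capacity and probability grids must be non-empty")
    base = params if params is not None else SimParams()
    rows = []
    for cap in capacities:
        for prob in probs:
            combo = base.replace(carrying_capacity=cap, disaster_prob=prob)
            for rep, result in enumerate(run_batch(combo, n_runs, base_seed)):
                rows.append(_result_row(result, cap, prob, rep))
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


def gini_sweep(
    capacities: Sequence[float] = DEFAULT_CAPACITIES,
    probs: Sequence[float] = DEFAULT_PROBS,
    n_runs: int = 100,
    base_seed: int = 0,
    params: SimParams | None = None,
) -> pd.DataFrame:
    """The inequality baseline: the same sweep with household interaction
    and deaths disabled, so the final Gini index reflects inequality before
    redistribution."""
    base = inequality_variant(params if params is not None else SimParams())
    return sweep(capacities, probs, n_runs=n_runs, base_seed=base_seed, params=base)


def aggregate_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-combination replicate means of the dependent variables."""
    metrics = [
        "final_gini",
        "largest_network_size",
        "largest_network_duration",
        "end_population",
    ]
    out = (
        table.groupby(["carrying_capacity", "disaster_prob"], as_index=False)[metrics]
        .mean()
        .assign(n_runs=table.groupby(["carrying_capacity", "disaster_prob"]).size().values)
    )
    return out


@dataclass(frozen=True)
class CapacityShiftResult:
    """Outcome of one capacity-shift run."""

    result: RunResult
    triggered: bool
    n_elevated_steps: int


def capacity_shift_run(
    params: SimParams | None = None,
    seed: int | None = None,
    low_capacity: float = 10_000.0,
    high_capacity: float = 50_000.0,
    trigger_size: int = 20,
) -> CapacityShiftResult:
    """One run in which carrying capacity is raised while a large network
    exists.

    Capacity starts at ``low_capacity``; at the end of any step where some
    patron holds at least ``trigger_size`` clients it becomes
    ``high_capacity``, reverting as soon as no network of that size remains.
    A run in which the trigger never fires is an ordinary low-capacity run.
    """
    if not low_capacity < high_capacity:
        raise ValueError("low_capacity must be below high_capacity")
    if trigger_size < 1:
        raise ValueError("trigger_size must be >= 1")
    base = params if params is not None else SimParams()
    base = base.replace(carrying_capacity=low_capacity)
    world = init_world(base, seed=seed)
    triggered = False
    n_elevated = 0
    for _ in range(base.n_steps):
        step_world(world)
        if world.n_clients[world.alive].size and int(
            world.n_clients[world.alive].max()
        ) >= trigger_size:
            world.capacity = float(high_capacity)
            triggered = True
        else:
            world.capacity = float(low_capacity)
        if world.capacity == high_capacity:
            n_elevated += 1
    return CapacityShiftResult(
        result=_finalize(world), triggered=triggered, n_elevated_steps=n_elevated
    )


def capacity_shift_batch(
    n_runs: int = 20,
    base_seed: int = 0,
    params: SimParams | None = None,
    low_capacity: float = 10_000.0,
    high_capacity: float = 50_000.0,
    trigger_size: int = 20,
) -> pd.DataFrame:
    """Replicated capacity-shift experiment (defaults: 20 runs starting at
    capacity 10,000, elevated to 50,000 on a 20-client network, disaster
    frequency 10%). Returns one row per run."""
    base = params if params is not None else SimParams(disaster_prob=0.10)
    seeds = derive_run_seeds(
        _combo_entropy(base_seed, low_capacity, base.disaster_prob) + [int(high_capacity), int(trigger_size)],
        n_runs,
    )
    rows = []
    for rep, s in enumerate(seeds):
        shift = capacity_shift_run(
            base,
            seed=s,
            low_capacity=low_capacity,
            high_capacity=high_capacity,
            trigger_size=trigger_size,
        )
        row = _result_row(shift.result, low_capacity, base.disaster_prob, rep)
        row["triggered"] = shift.triggered
        row["n_elevated_steps"] = shift.n_elevated_steps
        rows.append(row)
    return pd.DataFrame(rows, columns=RUN_COLUMNS + ["triggered", "n_elevated_steps"])
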