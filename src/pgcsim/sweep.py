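"""Phase sweep over adhesion strength and boundary mode.

For every (ε, boundary) condition the sweep runs ``n_seeds``
independent simulations, restricts to the steady-state window, and
computes the positioning observables: spatial density across the
channel width, positional variance, cluster-size distribution,
fraction of cells in large clusters, mean largest-cluster size and the
fraction of frames in which all cells form one cluster.  Seeds are the
independent statistical unit; per-run seeds derive deterministically
from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clusters as cl
from .params import ModelParameters
from .simulation import Trajectory, run_simulation

__all__ = ["SweepResult", "condition_seeds", "run_condition", "run_phase_sweep"]


@dataclass
class ConditionResult:
    """Per-seed observables of one (ε, boundary) condition."""

    epsilon: float
    boundary_mode: str
    seeds: list[int]
    variance: np.ndarray  # per seed
    fraction_large: np.ndarray
    largest_mean: np.ndarray
    single_cluster_fraction: np.ndarray
    profile: cl.DensityProfile
    size_counts: np.ndarray  # pooled over frames and seeds, index = size
    trajectories: list[Trajectory] = field(default_factory=list)


@dataclass
class SweepResult:
    summary: pd.DataFrame
    conditions: dict[tuple[float, str], ConditionResult]


def condition_seeds(master_seed: int, condition_index: int, n_seeds: int) -> list[int]:
    """Deterministic per-run seeds: SeedSequence([master, condition, k])."""
    return [
        int(np.random.SeedSequence([master_seed, condition_index, k]).generate_state(1)[0]
            & 0x7FFFFFFF)
        for k in range(n_seeds)
    ]


def run_condition(
    params: ModelParameters,
    seeds: Sequence[int],
    linking_distance: float = cl.DEFAULT_LINKING_DISTANCE,
    min_size: int = cl.DEFAULT_MIN_CLUSTER_SIZE,
    n_bins: int = cl.DEFAULT_N_BINS,
    keep_trajectories: bool = False,
) -> ConditionResult:
    window = (params.t_steady_start, params.t_steady_end)
    n = params.n_particles
    variance = np.empty(len(seeds))
    frac_large = np.empty(len(seeds))
    largest = np.empty(len(seeds))
    single = np.empty(len(seeds))
    size_counts = np.zeros(n + 1, dtype=int)
    steady = []
    kept = []
    for k, seed in enumerate(seeds):
        traj = run_simulation(params.replace(seed=int(seed)))
        sub = cl.steady_state_frames(traj, *window)
        steady.append(sub)
        labelings = cl.label_trajectory(sub, linking_distance)
        variance[k] = cl.positional_variance(sub).value
        frac_large[k] = cl.fraction_in_large_clusters(labelings, min_size, n_boot=50).value
        sizes = cl.largest_cluster_sizes(labelings)
        largest[k] = sizes.mean()
        single[k] = np.mean(sizes == n)
        size_counts += cl.cluster_size_distribution(labelings)
        if keep_trajectories:
            kept.append(traj)
    profile = cl.density_profile(steady, n_bins=n_bins)
    return ConditionResult(
        params.adhesion_epsilon,
        params.boundary_mode,
        [int(s) for s in seeds],
        variance,
        frac_large,
        largest,
        single,
        profile,
        size_counts,
        kept,
    )


def run_phase_sweep(
    epsilons: Sequence[float],
    boundary_modes: Sequence[str],
    n_seeds: int,
    base_params: Optional[ModelParameters] = None,
    master_seed: int = 0,
    linking_distance: float = cl.DEFAULT_LINKING_DISTANCE,
    min_size: int = cl.DEFAULT_MIN_CLUSTER_SIZE,
    n_bins: int = cl.DEFAULT_N_BINS,
    keep_trajectories: bool = False,
) -> SweepResult:
    """Run the (ε, boundary) grid and tabulate steady-state observables.

    The summary table has one row per condition and observable with
    seed-mean value, standard error over seeds, and n_seeds.
    """
    if base_params is None:
        base_params = ModelParameters()
    rows = []
    conditions: dict[tuple[float, str], ConditionResult] = {}
    cond_index = 0
    for mode in boundary_modes:
        for eps in epsilons:
            params = base_params.replace(adhesion_epsilon=float(eps), boundary_mode=mode)
            seeds = condition_seeds(master_seed, cond_index, n_seeds)
            cond = run_condition(
                params, seeds, linking_distance, min_size, n_bins, keep_trajectories
            )
            conditions[(float(eps), mode)] = cond
            for name, values in (
                ("positional_variance", cond.variance),
                ("fraction_in_large_clusters", cond.fraction_large),
                ("largest_cluster_mean", cond.largest_mean),
                ("single_cluster_fraction", cond.single_cluster_fraction),
            ):
                stderr = (
                    float(np.std(values, ddof=1) / np.sqrt(len(values)))
                    if len(values) > 1
                    else float("nan")
                )
                rows.append(
                    {
                        "epsilon": float(eps),
                        "boundary": mode,
                        "observable": name,
                        "value": float(np.mean(values)),
                        "stderr": stderr,
                        "n_seeds": n_seeds,
                    }
                )
            cond_index += 1
    return SweepResult(pd.DataFrame(rows), conditions)
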