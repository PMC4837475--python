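"""Steady-state cluster and positioning observables.

Clusters are single-linkage connected components: two cells belong to
the same cluster iff they are joined by a chain of pairwise
(minimal-image) distances not exceeding the linking distance.  The
default linking distance of 1.2 d sits just beyond the adhesive
potential minimum at 1 d, so touching cells link while second-shell
neighbours do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .simulation import ParticleState, Trajectory, minimal_image

__all__ = [
    "ClusterLabeling",
    "DensityProfile",
    "ScalarEstimate",
    "DEFAULT_LINKING_DISTANCE",
    "DEFAULT_MIN_CLUSTER_SIZE",
    "DEFAULT_N_BINS",
    "label_clusters",
    "label_trajectory",
    "cluster_size_distribution",
    "cluster_sizes",
    "largest_cluster_sizes",
    "fraction_in_large_clusters",
    "density_profile",
    "positional_variance",
    "steady_state_frames",
]

DEFAULT_LINKING_DISTANCE = 1.2  # d; just beyond the adhesive minimum at 1 d
DEFAULT_MIN_CLUSTER_SIZE = 3  # separates pairs from multi-cell aggregates at N=14
DEFAULT_N_BINS = 20  # 0.25 d bins across the 5 d width


@dataclass
class ClusterLabeling:
    """Partition of the particles of one frame into clusters."""

    frame_time: float
    labels: np.ndarray
    linking_distance: float
    periodic_length: float

    @property
    def n_particles(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        """Cluster sizes, one entry per cluster."""
        return np.bincount(self.labels)[np.unique(self.labels)]


@dataclass
class DensityProfile:
    """Probability density of particle x positions across the width."""

    bin_edges: np.ndarray
    density: np.ndarray
    stderr: np.ndarray
    n_frames: int
    n_seeds: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ScalarEstimate:
    """A pooled scalar observable with its uncertainty."""

    value: float
    stderr: float
    n: int


def _positions_of(state_or_positions) -> np.ndarray:
    if isinstance(state_or_positions, ParticleState):
        return state_or_positions.positions
    return np.asarray(state_or_positions, dtype=float)


def label_clusters(
    state, linking_distance: float, periodic_length: float
) -> ClusterLabeling:
    """Single-linkage connected components under the minimal-image metric.

    ``state`` may be a :class:`ParticleState` or an (N, 2) position
    array; y displacements use the minimal image over
    ``periodic_length``.  Labels are renumbered in order of first
    occurrence.
    """
    if linking_distance <= 0:
        raise ValueError("linking_distance must be > 0")
    pos = _positions_of(state)
    time = state.time if isinstance(state, ParticleState) else 0.0
    n = pos.shape[0]
    dx = pos[:, 0][:, None] - pos[:, 0][None, :]
    dy = minimal_image(pos[:, 1][:, None] - pos[:, 1][None, :], periodic_length)
    adj = (dx * dx + dy * dy) <= linking_distance**2
    np.fill_diagonal(adj, False)
    _, raw = connected_components(csr_matrix(adj), directed=False)
    # canonical labels: order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return ClusterLabeling(time, labels, float(linking_distance), float(periodic_length))


def label_trajectory(
    trajectory: Trajectory,
    linking_distance: float = DEFAULT_LINKING_DISTANCE,
    window: tuple[float, float] | None = None,
) -> list[ClusterLabeling]:
    """Label every frame (optionally restricted to a time window)."""
    traj = trajectory if window is None else trajectory.window(*window)
    length = traj.parameters.channel_length
    return [label_clusters(traj.frame(i), linking_distance, length) for i in range(traj.n_frames)]


def cluster_sizes(labeling: ClusterLabeling) -> np.ndarray:
    return labeling.sizes()


def cluster_size_distribution(labelings: Sequence[ClusterLabeling]) -> np.ndarray:
    """Frequency of each cluster size, pooled over frames.

    Returns counts indexed by size 1..N (index 0 unused, set to 0).
    Frames with differing particle counts are rejected.
    """
    labelings = list(labelings)
    if not labelings:
        raise ValueError("need at least one frame")
    n = labelings[0].n_particles
    counts = np.zeros(n + 1, dtype=int)
    for lab in labelings:
        if lab.n_particles != n:
            raise ValueError("mixed particle counts across frames")
        for s in lab.sizes():
            counts[s] += 1
    return counts


def largest_cluster_sizes(labelings: Sequence[ClusterLabeling]) -> np.ndarray:
    return np.array([lab.sizes().max() for lab in labelings])


def fraction_in_large_clusters(
    labelings: Sequence[ClusterLabeling],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> ScalarEstimate:
    """Mean fraction of cells residing in clusters of size >= min_size.

    The standard error comes from a bootstrap over frames.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    labelings = list(labelings)
    if not labelings:
        raise ValueError("need at least one frame")
    fracs = np.empty(len(labelings))
    for k, lab in enumerate(labelings):
        sizes = lab.sizes()
        fracs[k] = sizes[sizes >= min_size].sum() / lab.n_particles
    if rng is None:
        rng = np.random.default_rng(0)
    idx = rng.integers(0, len(fracs), size=(n_boot, len(fracs)))
    boot = fracs[idx].mean(axis=1)
    return ScalarEstimate(float(fracs.mean()), float(boot.std(ddof=1)), len(fracs))


def _as_trajectories(trajectories) -> list[Trajectory]:
    if isinstance(trajectories, Trajectory):
        return [trajectories]
    return list(trajectories)


def density_profile(
    trajectories: Union[Trajectory, Sequence[Trajectory]],
    n_bins: int = DEFAULT_N_BINS,
    window: tuple[float, float] | None = None,
) -> DensityProfile:
    """Histogram of x positions, normalised to a probability density.

    For several trajectories (independent seeds) the profile is the
    seed mean and the per-bin standard error is taken over seeds; for a
    single trajectory it is taken over frames.
    """
    trajs = _as_trajectories(trajectories)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    width = trajs[0].parameters.channel_width
    edges = np.linspace(0.0, width, n_bins + 1)
    per_seed = []
    n_frames_total = 0
    for traj in trajs:
        sub = traj if window is None else traj.window(*window)
        x = sub.positions[:, :, 0].ravel()
        dens, _ = np.histogram(x, bins=edges, density=True)
        per_seed.append(dens)
        n_frames_total += sub.n_frames
    per_seed_arr = np.stack(per_seed)
    if len(trajs) > 1:
        density = per_seed_arr.mean(axis=0)
        stderr = per_seed_arr.std(axis=0, ddof=1) / np.sqrt(len(trajs))
    else:
        sub = trajs[0] if window is None else trajs[0].window(*window)
        per_frame = np.stack(
            [np.histogram(sub.positions[i, :, 0], bins=edges, density=True)[0]
             for i in range(sub.n_frames)]
        )
        density = per_seed_arr[0]
        stderr = per_frame.std(axis=0, ddof=1) / np.sqrt(sub.n_frames)
    return DensityProfile(edges, density, stderr, n_frames_total, len(trajs))


def positional_variance(
    trajectories: Union[Trajectory, Sequence[Trajectory]],
    window: tuple[float, float] | None = None,
) -> ScalarEstimate:
    """Variance of the pooled x positions (d²).

    With several seeds, the value is the seed mean of per-seed pooled
    variances and the standard error is taken over seeds (seeds are the
    independent unit); a single trajectory yields stderr = nan.
    """
    trajs = _as_trajectories(trajectories)
    per_seed = []
    for traj in trajs:
        sub = traj if window is None else traj.window(*window)
        per_seed.append(np.var(sub.positions[:, :, 0]))
    vals = np.array(per_seed)
    if len(vals) > 1:
        stderr = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    else:
        stderr = float("nan")
    return ScalarEstimate(float(vals.mean()), stderr, len(vals))


def steady_state_frames(
    trajectory: Trajectory, t_start: float | None = None, t_end: float | None = None
) -> Trajectory:
    """Frames within the steady-state window (defaults from parameters).

    Raises if the window selects no frames.
    """
    p = trajectory.parameters
    if t_start is None:
        t_start = p.t_steady_start
    if t_end is None:
        t_end = p.t_steady_end
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    return trajectory.window(t_start, t_end)
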