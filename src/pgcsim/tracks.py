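"""Quantification of cell tracks: speeds, contact episodes, positions.

Tracks are tidy tables with columns ``track_id, time_min, x_um, y_um``
(one row per cell per frame), the format produced both by manual
marking of microscopy movies and by the simulator/synthetic generator.
A *contact episode* is a maximal run of consecutive common-grid frames
during which two cells — or a cell and a barrier polyline — are within
a contact distance; its duration is last minus first marked time, so an
episode of k frames at interval Δ lasts (k−1)Δ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .simulation import Trajectory, minimal_image

__all__ = [
    "TRACK_COLUMNS",
    "ContactEpisode",
    "BarrierGeometry",
    "DurationSummary",
    "DEFAULT_CELL_CONTACT_UM",
    "DEFAULT_BARRIER_CONTACT_UM",
    "DEFAULT_MIN_FRAMES",
    "validate_track_table",
    "trajectory_to_track_table",
    "instantaneous_speeds",
    "estimate_mean_speed",
    "estimate_persistence_time",
    "resample_tracks",
    "detect_cell_cell_contacts",
    "detect_barrier_contacts",
    "summarize_durations",
    "episodes_to_frame",
    "normalize_positions",
    "denormalize_positions",
]

TRACK_COLUMNS = ("track_id", "time_min", "x_um", "y_um")

# contact rules: one cell diameter (11 μm) plus margin for centre-centre
# cell contact; half a diameter for centre-to-barrier contact
DEFAULT_CELL_CONTACT_UM = 12.0
DEFAULT_BARRIER_CONTACT_UM = 6.0
DEFAULT_MIN_FRAMES = 2  # suppress single-frame grazing


@dataclass
class ContactEpisode:
    """One maximal contact run between two cells or a cell and a barrier."""

    kind: str  # "cell_cell" | "cell_barrier"
    members: tuple
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("episode end before start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BarrierGeometry:
    """Barrier boundary as a polyline in the track coordinate frame."""

    vertices: np.ndarray
    contact_distance: float = DEFAULT_BARRIER_CONTACT_UM

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("barrier polyline needs at least two 2D vertices")
        if not np.any(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1) > 0):
            raise ValueError("degenerate barrier polyline")

    @classmethod
    def vertical_line(
        cls, x_um: float, y_range: tuple[float, float] = (-1e6, 1e6),
        contact_distance: float = DEFAULT_BARRIER_CONTACT_UM,
    ) -> "BarrierGeometry":
        return cls(np.array([[x_um, y_range[0]], [x_um, y_range[1]]]), contact_distance)

    def as_linestring(self) -> shapely.LineString:
        return shapely.LineString(self.vertices)

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Point-to-polyline distances, vectorised over (M, 2) points."""
        line = self.as_linestring()
        pts = shapely.points(np.asarray(points, dtype=float))
        return shapely.distance(pts, line)


@dataclass
class DurationSummary:
    median: float
    iqr: float
    mean: float
    n: int


# ---------------------------------------------------------------------------
# track tables


def validate_track_table(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, monotone times, unique (track_id, time)."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table is missing column(s): {missing}")
    for tid, grp in tracks.groupby("track_id", sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {tid!r}: times not strictly increasing")
    return tracks


def trajectory_to_track_table(
    trajectory: Trajectory,
    unwrap: bool = True,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Convert a simulated trajectory to a μm track table.

    Lengths are scaled by the cell diameter.  With ``unwrap`` the
    periodic y coordinate is unwrapped (cumulative minimal-image
    increments) so finite-difference speeds are not corrupted by seam
    crossings.
    """
    traj = trajectory if window is None else trajectory.window(*window)
    p = traj.parameters
    d_um = p.cell_diameter_um
    rows = []
    for i in range(p.n_particles):
        x = traj.positions[:, i, 0]
        y = traj.positions[:, i, 1]
        if unwrap and traj.n_frames > 1:
            dy = minimal_image(np.diff(y), p.channel_length)
            y = np.concatenate(([y[0]], y[0] + np.cumsum(dy)))
        rows.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "time_min": traj.times,
                    "x_um": x * d_um,
                    "y_um": y * d_um,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def instantaneous_speeds(track: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-interval speeds of a single track, and their mean.

    Speed over each consecutive pair is Euclidean displacement divided
    by the time gap; the mean is time-gap weighted (total path length
    over total time), so mixed frame intervals are handled correctly.
    """
    t = track["time_min"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times not strictly increasing")
    disp = np.hypot(
        np.diff(track["x_um"].to_numpy(dtype=float)),
        np.diff(track["y_um"].to_numpy(dtype=float)),
    )
    speeds = disp / dt
    mean = float(disp.sum() / dt.sum())
    return speeds, mean


def estimate_mean_speed(tracks: pd.DataFrame) -> float:
    """Time-weighted mean speed pooled over all tracks, μm/min."""
    validate_track_table(tracks)
    total_path = 0.0
    total_time = 0.0
    for _, grp in tracks.groupby("track_id", sort=False):
        if len(grp) < 2:
            continue
        t = grp["time_min"].to_numpy(dtype=float)
        disp = np.hypot(
            np.diff(grp["x_um"].to_numpy(dtype=float)),
            np.diff(grp["y_um"].to_numpy(dtype=float)),
        )
        total_path += disp.sum()
        total_time += t[-1] - t[0]
    if total_time == 0:
        raise ValueError("no track has two or more points")
    return total_path / total_time


def estimate_persistence_time(
    tracks: pd.DataFrame, max_lag_min: float = 200.0, min_corr: float = 0.05
) -> float:
    """Directional persistence time (min) from step-direction decorrelation.

    Pools ⟨cos Δθ⟩ over all tracks and time origins at each lag, then
    fits exp(−t/τ).  Lags where the correlation has decayed below
    ``min_corr`` are excluded from the fit.
    """
    from scipy.optimize import curve_fit

    validate_track_table(tracks)
    num: dict[int, float] = {}
    cnt: dict[int, int] = {}
    intervals = []
    for _, grp in tracks.groupby("track_id", sort=False):
        if len(grp) < 3:
            continue
        t = grp["time_min"].to_numpy(dtype=float)
        dx = np.diff(grp["x_um"].to_numpy(dtype=float))
        dy = np.diff(grp["y_um"].to_numpy(dtype=float))
        ang = np.arctan2(dy, dx)
        intervals.append(np.median(np.diff(t)))
        max_lag = min(len(ang) - 1, int(max_lag_min / intervals[-1]))
        for lag in range(1, max_lag + 1):
            c = np.cos(ang[lag:] - ang[:-lag]).sum()
            num[lag] = num.get(lag, 0.0) + c
            cnt[lag] = cnt.get(lag, 0) + len(ang) - lag
    if not num:
        raise ValueError("tracks too short to estimate persistence")
    interval = float(np.median(intervals))
    lags = np.array(sorted(num))
    corr = np.array([num[k] / cnt[k] for k in lags])
    keep = corr > min_corr
    if keep.sum() < 3:
        keep = np.ones_like(corr, dtype=bool)
    tvals = lags[keep] * interval
    popt, _ = curve_fit(
        lambda t, tau: np.exp(-t / tau), tvals, corr[keep], p0=[60.0],
        bounds=(1e-6, np.inf), maxfev=10_000,
    )
    return float(popt[0])


def resample_tracks(
    tracks: pd.DataFrame, interval: Optional[float] = None
) -> tuple[pd.DataFrame, float]:
    """Linearly interpolate all tracks onto one common time grid.

    The grid step defaults to the coarsest per-track median frame
    interval, so no track is extrapolated beyond its own sampling;
    each track contributes only grid points inside its own time span.
    Returns the resampled table and the grid step.
    """
    validate_track_table(tracks)
    groups = {tid: grp for tid, grp in tracks.groupby("track_id", sort=False)}
    if interval is None:
        interval = max(
            float(np.median(np.diff(grp["time_min"].to_numpy(dtype=float))))
            for grp in groups.values()
            if len(grp) > 1
        )
    t0 = min(float(grp["time_min"].iloc[0]) for grp in groups.values())
    t1 = max(float(grp["time_min"].iloc[-1]) for grp in groups.values())
    # one global grid shared by every track, so common frames carry
    # bit-identical time values
    grid = t0 + np.arange(int(np.floor((t1 - t0) / interval + 1e-9)) + 1) * interval
    out = []
    for tid, grp in groups.items():
        t = grp["time_min"].to_numpy(dtype=float)
        inside = (grid >= t[0] - 1e-9 * interval) & (grid <= t[-1] + 1e-9 * interval)
        sub = grid[inside]
        if sub.size == 0:
            continue
        out.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "time_min": sub,
                    "x_um": np.interp(sub, t, grp["x_um"].to_numpy(dtype=float)),
                    "y_um": np.interp(sub, t, grp["y_um"].to_numpy(dtype=float)),
                }
            )
        )
    return pd.concat(out, ignore_index=True), float(interval)


# ---------------------------------------------------------------------------
# contact detection


def _runs_to_episodes(
    times: np.ndarray, mask: np.ndarray, min_frames: int, kind: str, members: tuple
) -> list[ContactEpisode]:
    episodes = []
    start = None
    for k, flag in enumerate(itertools.chain(mask, [False])):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= min_frames:
                episodes.append(
                    ContactEpisode(kind, members, float(times[start]), float(times[k - 1]))
                )
            start = None
    return episodes


def detect_cell_cell_contacts(
    tracks: pd.DataFrame,
    contact_distance: float = DEFAULT_CELL_CONTACT_UM,
    min_frames: int = DEFAULT_MIN_FRAMES,
    interval: Optional[float] = None,
) -> list[ContactEpisode]:
    """Episodes during which two cells are within ``contact_distance``.

    Tracks are first resampled onto a common grid; for every pair,
    frames in the shared time range with separation <= the threshold
    are marked and maximal runs of at least ``min_frames`` marked
    frames become episodes.
    """
    resampled, step = resample_tracks(tracks, interval)
    groups = {tid: grp.set_index("time_min") for tid, grp in resampled.groupby("track_id", sort=False)}
    episodes: list[ContactEpisode] = []
    ids = list(groups)
    for a, b in itertools.combinations(ids, 2):
        ga, gb = groups[a], groups[b]
        common = ga.index.intersection(gb.index)
        if len(common) == 0:
            continue
        pa = ga.loc[common, ["x_um", "y_um"]].to_numpy(dtype=float)
        pb = gb.loc[common, ["x_um", "y_um"]].to_numpy(dtype=float)
        dist = np.hypot(pa[:, 0] - pb[:, 0], pa[:, 1] - pb[:, 1])
        mask = dist <= contact_distance
        episodes.extend(
            _runs_to_episodes(common.to_numpy(dtype=float), mask, min_frames, "cell_cell", (a, b))
        )
    return episodes


def detect_barrier_contacts(
    tracks: pd.DataFrame,
    barrier: BarrierGeometry,
    min_frames: int = DEFAULT_MIN_FRAMES,
    interval: Optional[float] = None,
) -> list[ContactEpisode]:
    """Episodes during which a cell is within the barrier contact distance."""
    resampled, step = resample_tracks(tracks, interval)
    episodes: list[ContactEpisode] = []
    for tid, grp in resampled.groupby("track_id", sort=False):
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        dist = barrier.distances(pts)
        mask = dist <= barrier.contact_distance
        episodes.extend(
            _runs_to_episodes(
                grp["time_min"].to_numpy(dtype=float), mask, min_frames, "cell_barrier", (tid,)
            )
        )
    return episodes


def summarize_durations(episodes: Iterable) -> DurationSummary:
    """Median, interquartile range, mean and count of episode durations.

    Accepts episodes or plain durations.
    """
    durations = np.array(
        [e.duration if isinstance(e, ContactEpisode) else float(e) for e in episodes],
        dtype=float,
    )
    if durations.size == 0:
        raise ValueError("no episodes to summarise")
    q1, med, q3 = np.percentile(durations, [25, 50, 75])
    return DurationSummary(float(med), float(q3 - q1), float(durations.mean()), durations.size)


def episodes_to_frame(episodes: Sequence[ContactEpisode]) -> pd.DataFrame:
    rows = [
        {
            "kind": e.kind,
            "member_a": e.members[0],
            "member_b": e.members[1] if len(e.members) > 1 else "",
            "start_min": e.start,
            "end_min": e.end,
            "duration_min": e.duration,
        }
        for e in episodes
    ]
    return pd.DataFrame(
        rows, columns=["kind", "member_a", "member_b", "start_min", "end_min", "duration_min"]
    )


# ---------------------------------------------------------------------------
# cross-sectional positions


def normalize_positions(x, region: tuple[float, float]):
    """Affine map of a cross-sectional coordinate onto [0, 1].

    ``region`` gives the border coordinates (lo, hi); 0 maps to lo and
    1 to hi.  Invertible via :func:`denormalize_positions`.
    """
    lo, hi = float(region[0]), float(region[1])
    if hi == lo:
        raise ValueError("degenerate region: zero width")
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def denormalize_positions(u, region: tuple[float, float]):
    lo, hi = float(region[0]), float(region[1])
    if hi == lo:
        raise ValueError("degenerate region: zero width")
    return lo + np.asarray(u, dtype=float) * (hi - lo)
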