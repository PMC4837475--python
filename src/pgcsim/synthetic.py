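"""Synthetic inputs with known ground truth for the analysis modules.

Two generators emulate the measured data without any download: (a)
persistent-random-walk cell tracks — constant speed, direction
diffusing with rate 1/persistence_time, optional manual-marking jitter
— with contact episodes *planted* at scheduled times so detector
precision and recall can be scored against exact truth; (b)
cross-sectional cell-position tables with a chosen lateral law
(centre-peaked, uniform, or wall-biased), mirroring the phenotypes the
channel model produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .tracks import (
    BarrierGeometry,
    ContactEpisode,
    validate_track_table,
)

__all__ = [
    "PlannedContact",
    "SyntheticTrackSpec",
    "SyntheticPositionSpec",
    "generate_prw_tracks",
    "plant_contact_truth",
    "generate_position_table",
]

LATERAL_LAWS = ("central_gaussian", "uniform", "wall_biased")


@dataclass
class PlannedContact:
    """One scheduled contact: a cell pair, or a cell and the barrier."""

    kind: str  # "cell_cell" | "cell_barrier"
    members: tuple
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in ("cell_cell", "cell_barrier"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        n_expected = 2 if self.kind == "cell_cell" else 1
        if len(self.members) != n_expected:
            raise ValueError(f"{self.kind} contact needs {n_expected} member(s)")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class SyntheticTrackSpec:
    """Parameters of the track generator.

    Defaults emulate the measured cells: speed 0.6 μm/min, persistence
    60 min, 1-min frames, and sub-pixel marking jitter of 0.5 μm.
    """

    n_tracks: int = 6
    speed_um_min: float = 0.6
    persistence_time_min: float = 60.0
    frame_interval_min: float = 1.0
    duration_min: float = 240.0
    arena_um: tuple[float, float] = (600.0, 600.0)
    positional_noise_sd_um: float = 0.5
    start_separation_um: float = 120.0
    planted_episodes: Sequence[PlannedContact] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.positional_noise_sd_um < 0:
            raise ValueError("positional noise sd must be >= 0")
        for p in self.planted_episodes:
            if p.start < 0 or p.start + p.duration > self.duration_min:
                raise ValueError("planted episode does not fit within duration")


@dataclass
class SyntheticPositionSpec:
    """Parameters of the cross-sectional position generator.

    The default region is the 5 x 36 cell-diameter chamber in μm.
    """

    n_cells: int = 14
    region_width_um: float = 55.0
    region_height_um: float = 396.0
    lateral_distribution: str = "central_gaussian"
    scale_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.scale_um <= 0:
            raise ValueError("scale_um must be > 0")
        if self.lateral_distribution not in LATERAL_LAWS:
            raise ValueError(
                f"lateral_distribution must be one of {LATERAL_LAWS}"
            )


def _base_prw_tracks(spec: SyntheticTrackSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Persistent random walks with billiard reflection at the arena edge."""
    n_frames = int(round(spec.duration_min / spec.frame_interval_min)) + 1
    times = np.arange(n_frames) * spec.frame_interval_min
    w, h = spec.arena_um
    margin = min(spec.start_separation_um, w / 4, h / 4)
    starts = np.empty((spec.n_tracks, 2))
    placed = 0
    attempts = 0
    while placed < spec.n_tracks:
        attempts += 1
        if attempts > 20_000 * spec.n_tracks:
            raise RuntimeError(
                "could not place track starts with the requested separation; "
                "enlarge the arena or reduce start_separation_um"
            )
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if placed and np.any(
            np.linalg.norm(starts[:placed] - cand, axis=1) < spec.start_separation_um
        ):
            continue
        starts[placed] = cand
        placed += 1

    dt = spec.frame_interval_min
    sig = math.sqrt(2.0 * dt / spec.persistence_time_min) if np.isfinite(
        spec.persistence_time_min
    ) else 0.0
    rows = []
    for k in range(spec.n_tracks):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        pos = starts[k].copy()
        xs = np.empty(n_frames)
        ys = np.empty(n_frames)
        xs[0], ys[0] = pos
        for f in range(1, n_frames):
            pos = pos + spec.speed_um_min * dt * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            # billiard reflection keeps tracks inside the arena
            if pos[0] < 0 or pos[0] > w:
                pos[0] = np.clip(2.0 * np.clip(pos[0], 0, w) - pos[0], 0, w)
                theta = math.pi - theta
            if pos[1] < 0 or pos[1] > h:
                pos[1] = np.clip(2.0 * np.clip(pos[1], 0, h) - pos[1], 0, h)
                theta = -theta
            xs[f], ys[f] = pos
            theta += sig * rng.standard_normal()
        rows.append(
            pd.DataFrame({"track_id": k, "time_min": times, "x_um": xs, "y_um": ys})
        )
    return pd.concat(rows, ignore_index=True)


def _smooth_weight(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """1 on [start, end], cosine ramps of width ``ramp`` on both sides."""
    w = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    w[inside] = 1.0
    if ramp > 0:
        pre = (t >= start - ramp) & (t < start)
        w[pre] = 0.5 * (1.0 + np.cos(math.pi * (start - t[pre]) / ramp))
        post = (t > end) & (t <= end + ramp)
        w[post] = 0.5 * (1.0 + np.cos(math.pi * (t[post] - end) / ramp))
    return w


def plant_contact_truth(
    tracks: pd.DataFrame,
    schedule: Sequence[PlannedContact],
    barrier: Optional[BarrierGeometry] = None,
    hold_distance_cell_um: float = 6.0,
    hold_distance_barrier_um: float = 3.0,
    ramp_intervals: int = 3,
) -> tuple[pd.DataFrame, list[ContactEpisode]]:
    """Steer tracks to realise a contact schedule; return exact truth.

    For each scheduled window the second member (or the sole member,
    for barrier contacts) is blended along a smooth approach/retreat
    ramp onto a hold position a fixed small distance from its partner
    (or from the barrier), so speeds stay finite and physical during
    planted windows.  Overlapping windows that share a member are
    rejected as infeasible.
    """
    validate_track_table(tracks)
    if not schedule:
        return tracks.copy(), []
    out = tracks.copy()
    groups = {tid: grp.index.to_numpy() for tid, grp in out.groupby("track_id", sort=False)}
    intervals = [
        float(np.median(np.diff(out.loc[idx, "time_min"].to_numpy(dtype=float))))
        for idx in groups.values()
        if len(idx) > 1
    ]
    ramp = ramp_intervals * max(intervals)
    # feasibility: steered members must not appear in overlapping windows
    windows: dict = {}
    for ep in schedule:
        steered = ep.members[-1] if ep.kind == "cell_cell" else ep.members[0]
        for s, e in windows.get(steered, []):
            if ep.start - ramp < e and ep.start + ep.duration + ramp > s:
                raise ValueError(
                    f"infeasible schedule: overlapping steering windows for track {steered!r}"
                )
        windows.setdefault(steered, []).append(
            (ep.start - ramp, ep.start + ep.duration + ramp)
        )
    truth: list[ContactEpisode] = []
    for ep in schedule:
        end = ep.start + ep.duration
        if ep.kind == "cell_cell":
            a, b = ep.members
            ia, ib = groups[a], groups[b]
            ta = out.loc[ia, "time_min"].to_numpy(dtype=float)
            tb = out.loc[ib, "time_min"].to_numpy(dtype=float)
            ax = np.interp(tb, ta, out.loc[ia, "x_um"].to_numpy(dtype=float))
            ay = np.interp(tb, ta, out.loc[ia, "y_um"].to_numpy(dtype=float))
            bx = out.loc[ib, "x_um"].to_numpy(dtype=float)
            by = out.loc[ib, "y_um"].to_numpy(dtype=float)
            k0 = int(np.argmin(np.abs(tb - ep.start)))
            off = np.array([bx[k0] - ax[k0], by[k0] - ay[k0]])
            norm = np.linalg.norm(off)
            unit = off / norm if norm > 0 else np.array([1.0, 0.0])
            tgt_x = ax + unit[0] * hold_distance_cell_um
            tgt_y = ay + unit[1] * hold_distance_cell_um
            w = _smooth_weight(tb, ep.start, end, ramp)
            out.loc[ib, "x_um"] = (1 - w) * bx + w * tgt_x
            out.loc[ib, "y_um"] = (1 - w) * by + w * tgt_y
            truth.append(ContactEpisode("cell_cell", (a, b), ep.start, end))
        else:
            if barrier is None:
                raise ValueError("barrier geometry required for cell_barrier planting")
            (a,) = ep.members
            ia = groups[a]
            ta = out.loc[ia, "time_min"].to_numpy(dtype=float)
            pts = out.loc[ia, ["x_um", "y_um"]].to_numpy(dtype=float)
            line = barrier.as_linestring()
            import shapely

            nearest = np.array(
                [
                    line.interpolate(line.project(shapely.Point(p))).coords[0]
                    for p in pts
                ]
            )
            off = pts - nearest
            norms = np.linalg.norm(off, axis=1)
            units = np.where(
                norms[:, None] > 0, off / np.maximum(norms, 1e-12)[:, None], [1.0, 0.0]
            )
            tgt = nearest + units * hold_distance_barrier_um
            w = _smooth_weight(ta, ep.start, end, ramp)
            out.loc[ia, "x_um"] = (1 - w) * pts[:, 0] + w * tgt[:, 0]
            out.loc[ia, "y_um"] = (1 - w) * pts[:, 1] + w * tgt[:, 1]
            truth.append(ContactEpisode("cell_barrier", (a,), ep.start, end))
    return out, truth


def generate_prw_tracks(
    spec: SyntheticTrackSpec, barrier: Optional[BarrierGeometry] = None
) -> tuple[pd.DataFrame, list[ContactEpisode]]:
    """Generate persistent-random-walk tracks with planted contact truth.

    Deterministic given the spec (the seed covers starts, headings,
    angular noise and marking jitter).  Returns the track table and the
    exact episode list the detectors should recover.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_prw_tracks(spec, rng)
    planted, truth = plant_contact_truth(base, list(spec.planted_episodes), barrier)
    if spec.positional_noise_sd_um > 0:
        jitter = rng.normal(0.0, spec.positional_noise_sd_um, size=(len(planted), 2))
        planted["x_um"] = planted["x_um"] + jitter[:, 0]
        planted["y_um"] = planted["y_um"] + jitter[:, 1]
    return planted, truth


def generate_position_table(
    spec: SyntheticPositionSpec,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Cross-sectional cell positions with the requested lateral law.

    Returns the position table and the region bounds (0, width) of the
    lateral axis.  ``central_gaussian`` draws from a normal truncated
    to the region and centred on it; ``wall_biased`` draws from an
    equal mixture of half-normals peaked at the two borders — the
    wall-accumulation phenotype.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.region_width_um
    n = spec.n_cells
    law = spec.lateral_distribution
    if law == "uniform":
        x = rng.uniform(0.0, w, size=n)
    elif law == "central_gaussian":
        a, b = (0.0 - w / 2) / spec.scale_um, (w - w / 2) / spec.scale_um
        x = truncnorm.rvs(
            a, b, loc=w / 2, scale=spec.scale_um, size=n, random_state=rng
        )
    else:  # wall_biased
        side = rng.integers(0, 2, size=n)
        mag = np.abs(rng.normal(0.0, spec.scale_um, size=n))
        mag = np.minimum(mag, w / 2)  # keep draws inside the region
        x = np.where(side == 0, mag, w - mag)
    y = rng.uniform(0.0, spec.region_height_um, size=n)
    df = pd.DataFrame({"cell_id": np.arange(n), "x_um": x, "y_um": y})
    return df, (0.0, w)
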