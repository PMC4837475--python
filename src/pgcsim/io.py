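"""File formats, configuration and run manifests.

All artefacts are plain delimited text or JSON.  Trajectories are CSV
tables (frame_time_min, particle_id, x_d, y_d, theta_rad) with the full
parameter set embedded as '#'-prefixed JSON header lines, so a file is
self-describing and writer→reader round-trips are exact.  Every CLI
invocation writes a JSON manifest recording the resolved parameters,
seeds and paths, from which the run can be replayed.
"""

from __future__ import annotations

import dataclasses
import datetime
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ConfigError, ModelParameters
from .simulation import EVENT_DTYPE, Trajectory
from .tracks import TRACK_COLUMNS, validate_track_table

__all__ = [
    "ConfigBundle",
    "RunManifest",
    "load_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_track_table",
    "read_track_table",
    "read_barrier",
    "write_manifest",
    "read_manifest",
]

_TRAJ_MAGIC = "# pgcsim-trajectory v1"


@dataclass
class ConfigBundle:
    """Resolved model parameters plus free-form analysis settings."""

    model: ModelParameters
    analysis: dict[str, Any] = field(default_factory=dict)


def load_config(path: Optional[str | Path]) -> ConfigBundle:
    """Read a YAML config: flat model keys, optional ``analysis`` mapping.

    Missing keys take the measured-system defaults; unknown keys and
    out-of-range values raise :class:`ConfigError` naming the key.
    ``path=None`` yields the full default parameter set.
    """
    if path is None:
        return ConfigBundle(ModelParameters())
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping of parameter keys")
    analysis = data.pop("analysis", {}) or {}
    if not isinstance(analysis, dict):
        raise ConfigError("'analysis' section must be a mapping")
    return ConfigBundle(ModelParameters.from_dict(data), analysis)


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Write the fully resolved parameter set as flat YAML."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# trajectory store


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as self-describing delimited text.

    Reflection events, if any, go to a sidecar ``<path>.events.csv``.
    """
    path = Path(path)
    n_frames, n, _ = traj.positions.shape
    frame_time = np.repeat(traj.times, n)
    particle_id = np.tile(np.arange(n), n_frames)
    table = pd.DataFrame(
        {
            "frame_time_min": frame_time,
            "particle_id": particle_id,
            "x_d": traj.positions[:, :, 0].ravel(),
            "y_d": traj.positions[:, :, 1].ravel(),
            "theta_rad": traj.angles.ravel(),
        }
    )
    buf = _io.StringIO()
    buf.write(_TRAJ_MAGIC + "\n")
    buf.write("# params: " + json.dumps(traj.parameters.to_dict()) + "\n")
    buf.write(
        "# meta: "
        + json.dumps(
            {"save_interval": traj.save_interval, "n_reflections": int(traj.n_reflections)}
        )
        + "\n"
    )
    # %.17g guarantees binary round-trip of float64 through text
    table.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())
    if traj.events.size:
        ev = pd.DataFrame(
            {
                "time_min": traj.events["time"],
                "particle_id": traj.events["particle"],
                "side": np.where(traj.events["side"] == 0, "left", "right"),
            }
        )
        ev.to_csv(
            path.with_name(path.name + ".events.csv"), index=False, float_format="%.17g"
        )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (exact)."""
    path = Path(path)
    params_dict: dict[str, Any] | None = None
    meta: dict[str, Any] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRAJ_MAGIC:
            raise ValueError(f"{path} is not a pgcsim trajectory file")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line[1:].strip()
            if body.startswith("params:"):
                params_dict = json.loads(body[len("params:"):])
            elif body.startswith("meta:"):
                meta = json.loads(body[len("meta:"):])
        table = pd.read_csv(fh, float_precision="round_trip")
    if params_dict is None:
        raise ValueError(f"{path}: missing parameter header")
    params = ModelParameters.from_dict(params_dict)
    n = params.n_particles
    times = table["frame_time_min"].to_numpy(dtype=float)[::n]
    n_frames = times.size
    positions = np.empty((n_frames, n, 2))
    positions[:, :, 0] = table["x_d"].to_numpy(dtype=float).reshape(n_frames, n)
    positions[:, :, 1] = table["y_d"].to_numpy(dtype=float).reshape(n_frames, n)
    angles = table["theta_rad"].to_numpy(dtype=float).reshape(n_frames, n)
    events = np.empty(0, dtype=EVENT_DTYPE)
    ev_path = path.with_name(path.name + ".events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path, float_precision="round_trip")
        events = np.empty(len(ev), dtype=EVENT_DTYPE)
        events["time"] = ev["time_min"].to_numpy(dtype=float)
        events["particle"] = ev["particle_id"].to_numpy(dtype=int)
        events["side"] = (ev["side"] == "right").to_numpy(dtype=int)
    return Trajectory(
        params,
        times,
        positions,
        angles,
        float(meta.get("save_interval", params.save_interval)),
        events,
        int(meta.get("n_reflections", 0)),
    )


# ---------------------------------------------------------------------------
# track tables and barriers


def write_track_table(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write exactly the four standard columns."""
    validate_track_table(tracks)
    tracks.loc[:, list(TRACK_COLUMNS)].to_csv(path, index=False)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a track table; extra columns are tolerated and preserved."""
    df = pd.read_csv(path)
    return validate_track_table(df)


def read_barrier(path: str | Path, contact_distance: float):
    """Read a barrier polyline file with columns x_um, y_um."""
    from .tracks import BarrierGeometry

    df = pd.read_csv(path)
    return BarrierGeometry(df[["x_um", "y_um"]].to_numpy(dtype=float), contact_distance)


# ---------------------------------------------------------------------------
# manifests


@dataclass
class RunManifest:
    """Record of one CLI invocation, sufficient to replay it."""

    command: str
    argv: list[str]
    parameters: dict[str, Any]
    seed: Any
    inputs: list[str]
    outputs: list[str]
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
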